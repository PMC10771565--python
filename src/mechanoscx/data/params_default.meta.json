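{
  "description": "Provenance and pinned behavioural values of the shipped calibrated defaults (params_default.yaml).",
  "calibration": {
    "method": "log-uniform random screening, mean-field ODE screen, SSA ensemble confirmation (constraint_search)",
    "selection": "most constraints passed, ties broken by largest minimum normalised margin (SSA-confirmed)",
    "stages": [
      {"seed": 20260926, "bounds_span_fold": 4.0, "n_samples": 2000, "n_confirm": 10, "n_reps_confirm": 200},
      {"seed": 20260927, "bounds_span_fold": 2.0, "n_samples": 3000, "n_confirm": 15, "n_reps_confirm": 200}
    ],
    "note": "stage bounds were centred on a hand-chosen starting guess, then on the stage-1 winner; the shipped set is the stage-2 winner"
  },
  "constraint_margins_ode": {
    "C1_peak_window": 0.125,
    "C2_return": 0.025,
    "C3_ordering": 0.0312,
    "C4_pp2": 0.1122,
    "C5_pattern": 0.0315
  },
  "constraint_margins_ssa_seed123_200reps": {
    "C1_peak_window": 0.0417,
    "C2_return": 0.025,
    "C3_ordering": 0.0327,
    "C4_pp2": 0.1135,
    "C5_pattern": 0.0299
  },
  "pp2_scx_reduction_ode": 0.312,
  "robustness_fold2_n200_seed0_strict": {
    "peak_in_window": 0.745,
    "returns_to_baseline": 0.625,
    "additive_ordering": 1.0,
    "pp2_reduces_scx": 1.0
  },
  "search_acceptance_span10_n500_seed0_core_constraints": 0.006
}
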