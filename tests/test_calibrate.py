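"""Constraint evaluation, screening calibration, readout fitting."""

import numpy as np
import pytest

from mechanoscx import (ConstraintSet, FitSpec, bounds_around,
                        constraint_search, default_parameter_metadata,
                        evaluate_constraints, fit_to_readouts,
                        generate_wb_readouts, standard_conditions)
from mechanoscx.calibrate import ANALYTE_SPECIES


class TestEvaluateConstraints:
    def test_decoupled_network_fails_ordering(self, decoupled):
        res = evaluate_constraints(decoupled, mode="ode")
        assert not res["C3_ordering"].passed
        assert res["C3_ordering"].margin < 0

    def test_shipped_defaults_pass_everything(self, defaults):
        res = evaluate_constraints(defaults, mode="ode")
        assert all(v.passed for v in res.values())
        pinned = default_parameter_metadata()["constraint_margins_ode"]
        for name, margin in pinned.items():
            assert res[name].margin == pytest.approx(margin, abs=1e-3)

    def test_zero_margin_is_strict_inequality(self, defaults):
        cs = ConstraintSet(ordering_margin=0.0)
        res = evaluate_constraints(defaults, cs, mode="ode")
        assert res["C3_ordering"].passed
        # margin grows by exactly the removed requirement
        base = evaluate_constraints(defaults, ConstraintSet(), mode="ode")
        assert res["C3_ordering"].margin == pytest.approx(
            base["C3_ordering"].margin + 0.10)

    def test_ssa_mode_reproducible(self, defaults):
        a = evaluate_constraints(defaults, mode="ssa", seed=3, n_reps=20)
        b = evaluate_constraints(defaults, mode="ssa", seed=3, n_reps=20)
        assert all(a[k].margin == b[k].margin for k in a)

    def test_constraint_set_validation(self):
        with pytest.raises(ValueError):
            ConstraintSet(window=(12.0, 60.0))
        with pytest.raises(ValueError):
            ConstraintSet(pp2_inhibition=1.5)


class TestConstraintSearch:
    def test_degenerate_search_returns_defaults(self, defaults):
        bounds = {k: (v, v) for k, v in defaults.rates().items()}
        res = constraint_search(bounds, n_samples=1, seed=0, base=defaults,
                                n_confirm=1, n_reps_confirm=20)
        assert res.best_params.rates() == pytest.approx(defaults.rates())
        row = res.samples.iloc[0]
        assert row["C1_peak_window_pass"] and row["C2_return_pass"] \
            and row["C3_ordering_pass"]
        assert res.acceptance_fraction == 1.0

    def test_seeded_search_reproducible(self, defaults):
        bounds = bounds_around(defaults, span=2.0)
        a = constraint_search(bounds, n_samples=5, seed=7, base=defaults,
                              n_confirm=2, n_reps_confirm=10)
        b = constraint_search(bounds, n_samples=5, seed=7, base=defaults,
                              n_confirm=2, n_reps_confirm=10)
        assert a.samples.equals(b.samples)
        assert a.best_params.rates() == b.best_params.rates()

    def test_hopeless_bounds_warn_not_raise(self, decoupled, defaults):
        # couplings at ~0 cannot separate the groups
        tiny = {k: (1e-9, 2e-9) for k in ("k_fP", "k_yM", "k_yP",
                                          "k_sE", "k_sP")}
        res = constraint_search(tiny, n_samples=3, seed=0, base=defaults,
                                n_confirm=1, n_reps_confirm=5)
        assert res.warning
        assert res.acceptance_fraction == 0.0

    def test_invalid_bounds_rejected(self, defaults):
        with pytest.raises(ValueError):
            constraint_search({"k_fP": (0.0, 1.0)}, n_samples=1,
                              base=defaults)
        with pytest.raises(ValueError):
            constraint_search({"nope": (0.1, 1.0)}, n_samples=1,
                              base=defaults)


class TestFitToReadouts:
    def test_noise_free_truth_has_zero_loss(self, defaults):
        conds = standard_conditions(defaults, include_pp2=False)
        readouts = generate_wb_readouts(defaults, conds, n_reps=2,
                                        noise_cv=0.0, seed=0,
                                        analytes=tuple(ANALYTE_SPECIES))
        spec = FitSpec(base=defaults, n_initial=5, n_refine=0)
        fit = fit_to_readouts(readouts, spec, seed=0)
        # the base point (the truth) is always evaluated first; every
        # sampled competitor can only tie or lose
        assert fit.loss < 1e-10
        assert fit.params.rates() == pytest.approx(defaults.rates())

    def test_zero_refine_budget_returns_best_initial(self, defaults):
        conds = standard_conditions(defaults, include_pp2=False)
        readouts = generate_wb_readouts(defaults, conds, n_reps=2,
                                        noise_cv=0.0, seed=0,
                                        analytes=tuple(ANALYTE_SPECIES))
        spec = FitSpec(base=defaults, n_initial=3, n_refine=0)
        fit = fit_to_readouts(readouts, spec, seed=1)
        assert fit.n_evaluations == 4    # base + 3 samples

    def test_missing_analyte_reported(self, defaults):
        conds = standard_conditions(defaults, include_pp2=False)
        readouts = generate_wb_readouts(defaults, conds, n_reps=2,
                                        noise_cv=0.0, seed=0,
                                        analytes=("SCX", "p-Fyn"))
        spec = FitSpec(base=defaults)
        with pytest.raises(ValueError, match="p-ERK"):
            fit_to_readouts(readouts, spec, seed=0)

    def test_missing_control_rejected(self, defaults):
        conds = [c for c in standard_conditions(defaults, include_pp2=False)
                 if c.name != "control"]
        with pytest.raises(ValueError):
            generate_wb_readouts(defaults, conds, noise_cv=0.0, seed=0)


def test_bounds_around_symmetric_in_log(defaults):
    b = bounds_around(defaults, span=9.0, names=("k_fP",))
    lo, hi = b["k_fP"]
    assert hi / lo == pytest.approx(9.0)
    assert np.sqrt(lo * hi) == pytest.approx(defaults.k_fP)
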