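# Methods

## Model

The network couples two stimuli to Scleraxis (SCX) transcription-factor
copy number in a single periodontal ligament stem cell.  Species: four
conserved kinase pools (FAK, Fyn, ERK, p38; each `N = 1000` molecules
split between inactive and active forms), the MGF ligand pool, and SCX.
Eleven elementary reactions: activation/deactivation conversions for each
pool (mass-action in the source form, conserving the pool total),
zeroth-order SCX production with linear contributions from active ERK and
p38, first-order SCX degradation, and first-order MGF clearance.

Assumptions worth stating explicitly:

* **Hill-type mechanotransduction.**  The integrin-mediated pressure
  input enters only through `H(P) = P^h/(K^h + P^h)`.  Defaults
  `K = 100 kPa`, `h = 2` put the 120 kPa stimulus just above
  half-saturation (`H(120) ≈ 0.59`), inside the experimentally probed
  90–150 kPa range.  No integrin conformational mechanism is modelled.
* **Envelope pressure.**  Cyclic loading (0.1 Hz to a peak amplitude) is
  abstracted to its piecewise-constant envelope: the network's rates are
  per hour, so 10-second cycles are unresolvable and only the envelope
  matters.  A time-averaged amplitude can be used instead by supplying a
  protocol with that amplitude.
* **Linear stimulus coupling.**  Activation rates are affine in their
  drivers (`H(P)`, `MGF/M_ref`, active-fraction of the upstream kinase).
  These are the simplest forms consistent with the qualitative activation
  pattern; nothing in the available data constrains higher-order forms.
* **Fyn→FAK crosstalk.**  FAK activation is multiplied by
  `1 + w·FYN_a/N_fyn` (default `w = 2`; 0 disables the edge).  The edge is
  included by default because Src-family inhibition measurably lowers
  phospho-FAK, which a three-axis model without crosstalk cannot produce.
* **JNK is omitted** (no variation observed in any group), and the two
  MGF preparations (humanised and Goldspink peptide) are modelled
  identically, as one MGF condition.
* **Simultaneous onset.**  MGF bolus (100 copies) and the pressure
  envelope both start at t = 0; the model timeline treats stimulus onset
  as the time origin.  PP2-treated conditions are initialised at their own
  inhibited pre-stimulus steady state (the inhibitor is applied before
  stimulation).
* **No mechanistic MGF-mRNA dose response.**  The biphasic pressure dose
  response of MGF transcription (maximum at 120 kPa, 24 h) is emulated
  statistically in the synthetic-data generator only.

## Simulation

`simulate_ssa` implements the Gillespie direct method.  Pressure is
piecewise constant, so propensities are constant between reaction events
and protocol breakpoints; at a breakpoint the pending exponential waiting
time is discarded and the clock advanced to the boundary, which is exact
for piecewise-constant propensities (the memoryless property).  Output
grids are sampled last-value-carried-forward, right-continuous at jump
times.  The inner loop is numba-compiled; a 200-replicate, 48-h ensemble
of the default model runs in well under a second.

`simulate_ode` integrates the mean-field rate equations (counts treated
as continuous; the active fraction of each pool is the integrated
variable, so conservation is exact) with LSODA at `rtol = atol = 1e-9`,
restarting at protocol breakpoints.  It reproduces the closed-form
exponential relaxation of the birth–death subnetwork to ~1e-9 relative
error, comfortably inside the 1e-6 documentation tolerance.

**Reproducibility contract.**  One `numpy.random.Generator` per
trajectory.  An ensemble with master seed `s` gives replicate `i` the
generator `default_rng(SeedSequence(s).spawn(n)[i])`.  Identical inputs
give bit-identical trajectories, summaries and CSV artifacts.

Initial states are the analytic pre-stimulus steady state of the
condition (rounded to integers for the SSA), so no burn-in is needed.
The SCX baseline is the full basal balance
`(k_s0 + k_sE·ERK_a* + k_sP·P38_a*) / gamma_s`; with zero basal kinase
activity this reduces to `k_s0/gamma_s`.

## Summary statistics

`summarize_timecourse` reports the peak time (argmax of the ensemble mean
on the grid; earliest grid time on ties), the 12–24 h window mean (the
group-comparison statistic), and the return time: the first grid time
after the peak at which the mean is within `tolerance` (default 10%) of
baseline.  "Baseline" defaults to the analytic pre-stimulus steady state;
a time-matched control trajectory can be used instead
(`baseline_mode="control"`), which matters if control itself drifts —
with the shipped defaults it does not, and the two modes agree.

## Calibration

No rate constants for this cascade have been measured, so the shipped
defaults are defined behaviourally.  `constraint_search` samples rates
log-uniformly within bounds, screens each candidate with the mean-field
model against the constraint set (C1 peak in 12–24 h under pressure+MGF;
C2 return within 10% of baseline by 40 h; C3 the four group orderings
with ≥10% margins; C4 ≥20% PP2 reversal; C5 activation-pattern fidelity),
and confirms the leaders with 200-replicate SSA ensembles.  Candidates
are ranked by number of constraints passed, ties broken by the largest
minimum normalised margin, so the selected set sits as centrally as
possible in the feasible region.

The shipped set is the winner of a two-stage search (stage 1: ×4 bounds
around a hand-chosen starting guess, 2000 samples, seed 20260926;
stage 2: ×2 bounds around the stage-1 winner, 3000 samples, seed
20260927), recorded with its margins in
`src/mechanoscx/data/params_default.meta.json`.  A 50-seed audit of
200-replicate ensembles puts the SCX peak at 12.0–14.5 h and the return
at 38.0–40.0 h.

A structural remark: a linear two-state pool always relaxes toward
activation faster than it decays (rise rate = activation + deactivation,
fall rate = deactivation alone), so a late peak requires slow
deactivation somewhere, which in turn slows the return to baseline.  A
peak in 12–24 h together with a return by 40 h therefore confines the
feasible region to peaks around 13–14 h.  This is a property of the
model class, not a tuning accident.

`fit_to_readouts` is the quantitative analogue: it minimises the sum of
squared log-fold-change residuals between model predictions (mean-field
12–24 h window means, fold vs control) and a readout table, by
log-uniform random search plus Nelder–Mead refinement in log-rate space.
Only the seven stimulus coupling rates are freed by default: basal and
decay rates set timescales, which endpoint fold changes cannot constrain.
`parameter_recovery` closes the loop — generate noisy synthetic readouts
from known parameters, refit from a neutral starting point (bounds'
geometric middle, ×100 bounds), and score the recovered *fold changes*.
Raw rates are structurally non-identifiable from this readout design, so
they are deliberately not the recovery target.

## Synthetic data

`generate_wb_readouts` emulates reference-normalised band-intensity
tables: the planted expectation per (group, analyte) is the model's
window-mean fold change vs control; replicates are multiplied by
mean-corrected lognormal noise (`exp(N(-s²/2, s))`, `s² = ln(1+cv²)`), so
the planted value is exactly the expectation.  Defaults: CV 0.15 (typical
densitometry variability) and n = 3 replicates per group (the in-vitro
group size).  The integrin engagement analyte has no model species and is
planted directly as `1 + H(P_peak)` — pressure-specific by construction.

`generate_qpcr_mgf` emulates 2^−ΔCT relative-expression tables over
pressure doses {90, 120, 150} kPa and times {0, 12, 24, 36} h, with unity
at time 0 and the planted maximum at (120 kPa, 24 h).  The effect sizes
are generator design choices; only the maximum's location mirrors the
observed pattern.

What the generators do **not** emulate: blot saturation and background
subtraction artefacts, inter-gel normalisation drift, correlated
replicate noise (shared lysates), or biological heterogeneity between
cell isolates.  Passing recovery tests therefore demonstrates that the
analysis pipeline is self-consistent under the stated noise model, not
that it would survive every failure mode of real densitometry.

`two_group_sample_size` evaluates `n = ceil((z_α+z_β)²·2σ²/δ²)`; the
quantiles are supplied directly, avoiding any guess about whether a
stated "β" means the error rate or the power.  The multi-group
formulation that requires a φ lookup table is out of scope.

## Robustness

`robustness_scan` multiplies every rate constant independently by a
log-uniform factor in `[1/fold, fold]` and re-evaluates the conclusions
with the mean-field screen.  Its default constraint set tests the
conclusions strictly (orderings and PP2 reversal with margin 0): the
question is whether the claims survive perturbation, not whether the
calibration safety margins do.  For the shipped defaults at ±2-fold
(n = 200, seed 0): orderings 1.00, PP2 reversal 1.00, peak window 0.745,
return deadline 0.625 — the sign-structural conclusions are insensitive
to rate choices, while the quantitative timing windows are the
rate-sensitive claims.

## Numerical choices and problem sizes

* Output grid 0.5 h over a 48-h horizon; window 12–24 h inclusive.
* Peak ties break to the earliest grid time; grid refinement moves the
  mean-field peak by at most one coarse step.
* Ensembles of 200 replicates for group comparisons (300 in the
  acceptance script, which tightens the argmax of the flat peak region);
  ratios of window means then carry sub-percent standard errors.
* The large-copy SSA/ODE agreement check scales all pool totals, the MGF
  bolus/normalisation and the basal SCX production by ×100 and requires
  the 200-replicate ensemble mean within 5% of the mean-field curve.
* Calibration screens use `rtol = 1e-8`, fitting uses `rtol = 1e-6`
  (speed; fold changes are insensitive at that level).
* Degenerate inputs: an all-zero propensity state advances directly to
  the next breakpoint; a zero-turnover network has baseline 0; empty
  robustness scans report NaN fractions with an explicit zero count.

## Limitations

* Rate constants are behaviourally calibrated, not measured; only
  fold-change-level statements are transferable.
* Single-cell, well-mixed, no spatial structure, no cell-to-cell
  variability beyond intrinsic copy-number noise.
* The MGF-mRNA dose response is emulated, not mechanistic; conclusions
  about *why* 120 kPa outperforms 150 kPa are outside the model.
* The two-state pools ignore multi-site phosphorylation kinetics and
  scaffolding; "active" aggregates all phospho-forms read by a blot.
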