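"""Calibration by constraints and fitting to quantitative readouts.

No measured rate constants exist for this network, so the shipped defaults
are produced by screening log-uniform random parameter sets against the
experimentally stated behaviour: the Scleraxis maximum falls in the
12-24 h window, the level returns to baseline by 40 h, the treatment
groups order control < MGF < pressure+MGF and control < pressure <
pressure+MGF with a margin, PP2 reverses the combined-stimulus increase,
and the kinase activation pattern matches the blots (MGF alone does not
activate FAK; pressure activates all four kinases).  Candidates are
screened with the mean-field ODE and the best are confirmed with SSA
ensembles.

A quantitative analogue (`fit_to_readouts`) minimises squared log-fold-
change residuals against (synthetic) band-intensity tables, and
`parameter_recovery` closes the loop: generate noisy readouts from known
parameters, refit, and score the recovered condition-level fold changes.
Raw rate constants are structurally non-identifiable from endpoint fold
changes, so recovery is assessed on the fold changes themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .analysis import (DEFAULT_WINDOW, KINASE_ACTIVE, compare_conditions,
                       inhibitor_experiment, summarize_timecourse,
                       window_mean)
from .model import Condition, standard_conditions
from .params import RATE_NAMES, ParameterSet
from .simulate import run_ensemble, simulate_ode

__all__ = [
    "ConstraintSet", "ConstraintResult", "CalibrationResult",
    "FitSpec", "FitResult", "RecoveryReport",
    "evaluate_constraints", "constraint_search", "bounds_around",
    "fit_to_readouts", "parameter_recovery",
]

#: Readout analyte -> model species.
ANALYTE_SPECIES: dict[str, str] = {
    "SCX": "SCX",
    "p-FAK": "FAK_a",
    "p-Fyn": "FYN_a",
    "p-ERK": "ERK_a",
    "p-p38": "P38_a",
}


@dataclass(frozen=True)
class ConstraintSet:
    """Behavioural constraints distilled from the reported observations.

    C1: SCX (ensemble/mean-field) peak time inside ``window`` under
    pressure+MGF.  C2: SCX back within ``return_tol`` of its pre-stimulus
    baseline by ``return_deadline``.  C3: window-mean SCX orderings
    control < MGF < pressure+MGF and control < pressure < pressure+MGF,
    each with relative margin ``ordering_margin``.  C4 (optional): PP2
    (Fyn inhibition ``pp2_inhibition``) lowers the pressure+MGF SCX window
    mean by at least ``pp2_margin``.  C5 (optional): activation-pattern
    fidelity - MGF alone leaves window-mean FAK_a within
    ``pattern_fak_tol`` of control while raising FYN_a and ERK_a, and
    pressure raises all four kinases, each by at least
    ``kinase_up_margin``.
    """

    window: tuple[float, float] = (12.0, 24.0)
    return_deadline: float = 40.0
    return_tol: float = 0.10
    ordering_margin: float = 0.10
    pp2_margin: float = 0.20
    pp2_inhibition: float = 0.1
    include_pp2: bool = True
    pattern_fak_tol: float = 0.10
    kinase_up_margin: float = 0.05
    include_pattern: bool = True
    horizon: float = 48.0
    grid_step: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (0 <= lo < hi <= self.horizon):
            raise ValueError(f"window {self.window} must lie inside "
                             f"[0, {self.horizon}] h")
        if not 0 < self.return_deadline <= self.horizon:
            raise ValueError("return_deadline must lie within the horizon")
        for name in ("return_tol", "ordering_margin", "pp2_margin",
                     "pattern_fak_tol", "kinase_up_margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.pp2_inhibition <= 1:
            raise ValueError("pp2_inhibition must lie in [0, 1]")


@dataclass(frozen=True)
class ConstraintResult:
    """Outcome of one constraint: signed margin (>= 0 means satisfied)."""

    name: str
    passed: bool
    margin: float


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.inf if num > 0 else 1.0


def evaluate_constraints(params: ParameterSet,
                         constraints: ConstraintSet | None = None,
                         mode: str = "ode", seed: int = 0,
                         n_reps: int = 200) -> dict[str, ConstraintResult]:
    """Evaluate the calibration constraints for one parameter set.

    ``mode="ode"`` is deterministic; ``mode="ssa"`` uses ``n_reps``
    replicates per condition with master seed ``seed``.  Margins are
    signed and normalised so that 0 is the pass boundary.
    """
    cs = constraints if constraints is not None else ConstraintSet()
    conds = standard_conditions(params, pp2_inhibition=cs.pp2_inhibition)
    by_name = {c.name: c for c in conds}
    need = ["control", "MGF", "pressure", "pressure+MGF"]
    if cs.include_pp2:
        need.append("pressure+MGF+PP2")

    series = {}
    for name in need:
        cond = by_name[name]
        if mode == "ode":
            series[name] = simulate_ode(cond, params, cs.horizon,
                                        grid_step=cs.grid_step,
                                        rtol=1e-8, atol=1e-8)
        elif mode == "ssa":
            series[name] = run_ensemble(cond, params, n_reps=n_reps,
                                        t_end=cs.horizon, seed=seed,
                                        grid_step=cs.grid_step)
        else:
            raise ValueError(f"mode must be 'ode' or 'ssa', got {mode!r}")

    out: dict[str, ConstraintResult] = {}
    lo, hi = cs.window

    tc = summarize_timecourse(series["pressure+MGF"], "SCX", window=cs.window,
                              tolerance=cs.return_tol)
    m1 = min(tc.peak_time - lo, hi - tc.peak_time) / (hi - lo)
    out["C1_peak_window"] = ConstraintResult("C1_peak_window", m1 >= 0, m1)

    rt = tc.return_time
    m2 = ((cs.return_deadline - rt) / cs.return_deadline
          if math.isfinite(rt) else -1.0)
    out["C2_return"] = ConstraintResult("C2_return", m2 >= 0, m2)

    w = {name: window_mean(series[name], "SCX", cs.window) for name in
         ("control", "MGF", "pressure", "pressure+MGF")}
    pairs = [(w["MGF"], w["control"]), (w["pressure"], w["control"]),
             (w["pressure+MGF"], w["pressure"]),
             (w["pressure+MGF"], w["MGF"])]
    m3 = min(_safe_ratio(a, b) - 1.0 - cs.ordering_margin for a, b in pairs)
    out["C3_ordering"] = ConstraintResult("C3_ordering", m3 >= 0, m3)

    if cs.include_pp2:
        w_pp2 = window_mean(series["pressure+MGF+PP2"], "SCX", cs.window)
        reduction = 1.0 - _safe_ratio(w_pp2, w["pressure+MGF"])
        m4 = reduction - cs.pp2_margin
        out["C4_pp2"] = ConstraintResult("C4_pp2", m4 >= 0, m4)

    if cs.include_pattern:
        margins = []
        # MGF alone must not activate FAK beyond the tolerance ...
        fak_excess = _safe_ratio(window_mean(series["MGF"], "FAK_a", cs.window),
                                 window_mean(series["control"], "FAK_a",
                                             cs.window)) - 1.0
        margins.append(cs.pattern_fak_tol - fak_excess)
        # ... while clearly raising Fyn and ERK,
        for sp in ("FYN_a", "ERK_a"):
            r = _safe_ratio(window_mean(series["MGF"], sp, cs.window),
                            window_mean(series["control"], sp, cs.window))
            margins.append(r - 1.0 - cs.kinase_up_margin)
        # and pressure must raise all four kinases.
        for sp in KINASE_ACTIVE:
            r = _safe_ratio(window_mean(series["pressure"], sp, cs.window),
                            window_mean(series["control"], sp, cs.window))
            margins.append(r - 1.0 - cs.kinase_up_margin)
        m5 = min(margins)
        out["C5_pattern"] = ConstraintResult("C5_pattern", m5 >= 0, m5)

    return out


def bounds_around(params: ParameterSet, span: float = 10.0,
                  names: Sequence[str] = RATE_NAMES) -> dict[str, tuple[float, float]]:
    """Log-symmetric bounds covering a total fold range ``span`` around
    each named rate: ``[r / sqrt(span), r * sqrt(span)]``."""
    if span < 1:
        raise ValueError("span must be >= 1")
    s = math.sqrt(span)
    out = {}
    for name in names:
        r = getattr(params, name)
        if r <= 0:
            raise ValueError(f"cannot place log bounds around {name}={r}")
        out[name] = (r / s, r * s)
    return out


@dataclass
class CalibrationResult:
    """Outcome of a constraint-screening search."""

    samples: pd.DataFrame
    best_params: ParameterSet
    best_index: int
    acceptance_fraction: float
    warning: bool
    seed: int
    bounds: dict[str, tuple[float, float]]
    constraint_names: tuple[str, ...]


def _geometric_mid(bounds: Mapping[str, tuple[float, float]]) -> dict[str, float]:
    return {k: math.sqrt(lo * hi) for k, (lo, hi) in bounds.items()}


def constraint_search(bounds: Mapping[str, tuple[float, float]],
                      constraints: ConstraintSet | None = None,
                      n_samples: int = 500, seed: int = 0,
                      base: ParameterSet | None = None,
                      n_confirm: int = 10, n_reps_confirm: int = 200,
                      ) -> CalibrationResult:
    """Log-uniform random screening against the constraint set.

    Samples are drawn independently per rate within ``bounds``, screened
    with the deterministic mean-field model, ranked by (number of
    constraints passed, then smallest margin), and the top ``n_confirm``
    re-evaluated with SSA ensembles.  The best set is the SSA-confirmed
    leader.  Fully reproducible from ``seed``.
    """
    cs = constraints if constraints is not None else ConstraintSet()
    if n_samples < 1:
        raise ValueError("n_samples >= 1 required")
    for name, (lo, hi) in bounds.items():
        if name not in RATE_NAMES:
            raise ValueError(f"unknown rate {name!r} in bounds")
        if not 0 < lo <= hi:
            raise ValueError(f"bounds for {name} must satisfy 0 < lo <= hi")
    if base is None:
        mids = _geometric_mid(dict(bounds))
        missing = set(RATE_NAMES) - set(mids)
        if missing:
            raise ValueError(
                f"no base parameters given and bounds omit {sorted(missing)}")
        base = ParameterSet(**mids)

    rng = np.random.default_rng(seed)
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])

    rows = []
    candidates = []
    cnames: tuple[str, ...] = ()
    for i in range(n_samples):
        draw = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        cand = base.with_rates(dict(zip(names, draw)))
        res = evaluate_constraints(cand, cs, mode="ode")
        cnames = tuple(res)
        row = {"sample": i}
        row.update({f"{k}_margin": v.margin for k, v in res.items()})
        row.update({f"{k}_pass": v.passed for k, v in res.items()})
        row["n_passed"] = sum(v.passed for v in res.values())
        row["min_margin"] = min(v.margin for v in res.values())
        rows.append(row)
        candidates.append(cand)

    samples = pd.DataFrame(rows)
    n_total = len(cnames)
    accepted = samples["n_passed"] == n_total
    acceptance_fraction = float(accepted.mean())

    order = samples.sort_values(["n_passed", "min_margin"],
                                ascending=False, kind="mergesort").index
    top = list(order[:n_confirm])
    best_idx, best_key = top[0], (-1, -math.inf)
    for idx in top:
        res = evaluate_constraints(candidates[idx], cs, mode="ssa",
                                   seed=seed, n_reps=n_reps_confirm)
        key = (sum(v.passed for v in res.values()),
               min(v.margin for v in res.values()))
        samples.loc[idx, "ssa_n_passed"] = key[0]
        samples.loc[idx, "ssa_min_margin"] = key[1]
        if key > best_key:
            best_key, best_idx = key, idx

    return CalibrationResult(
        samples=samples, best_params=candidates[best_idx],
        best_index=int(best_idx),
        acceptance_fraction=acceptance_fraction,
        warning=acceptance_fraction == 0.0, seed=seed,
        bounds={k: tuple(v) for k, v in bounds.items()},
        constraint_names=cnames)


# ---------------------------------------------------------------------------
# quantitative fitting and parameter recovery


@dataclass(frozen=True)
class FitSpec:
    """Specification of a log-fold-change fit.

    ``bounds`` names the free rates (the default frees the seven stimulus
    coupling rates, which set the fold changes; basal and decay rates set
    timescales and are left at their base values).  The loss is the sum of
    squared log residuals between predicted and target fold changes over
    every (non-control group, analyte) pair.
    """

    base: ParameterSet
    bounds: Mapping[str, tuple[float, float]] = None  # type: ignore[assignment]
    analytes: tuple[str, ...] = tuple(ANALYTE_SPECIES)
    window: tuple[float, float] = DEFAULT_WINDOW
    t_end: float = 48.0
    grid_step: float = 0.5
    n_initial: int = 300
    n_refine: int = 600

    def __post_init__(self) -> None:
        if self.bounds is None:
            coupling = ("k_fP", "k_yM", "k_yP", "k_pF", "k_eY", "k_sE", "k_sP")
            object.__setattr__(self, "bounds",
                               bounds_around(self.base, 100.0, coupling))
        unknown = set(self.analytes) - set(ANALYTE_SPECIES)
        if unknown:
            raise ValueError(f"unknown analytes: {sorted(unknown)}")


@dataclass
class FitResult:
    params: ParameterSet
    loss: float
    trace: list[float]
    residuals: pd.DataFrame
    n_evaluations: int


def predicted_folds(params: ParameterSet, groups: Sequence[str],
                    analytes: Sequence[str] = tuple(ANALYTE_SPECIES),
                    window: tuple[float, float] = DEFAULT_WINDOW,
                    t_end: float = 48.0, grid_step: float = 0.5,
                    rtol: float = 1e-6) -> pd.DataFrame:
    """Mean-field window-mean fold changes vs control per (group, analyte)."""
    by_name = {c.name: c for c in standard_conditions(params)}
    unknown = [g for g in groups if g not in by_name]
    if unknown:
        raise ValueError(f"unknown treatment groups: {unknown}")
    species = [ANALYTE_SPECIES[a] for a in analytes]
    means = {}
    for g in set(groups) | {"control"}:
        sol = simulate_ode(by_name[g], params, t_end, grid_step=grid_step,
                           rtol=rtol, atol=rtol)
        means[g] = {sp: window_mean(sol, sp, window) for sp in species}
    rows = []
    for g in groups:
        for a, sp in zip(analytes, species):
            rows.append({"group": g, "analyte": a,
                         "fold": _safe_ratio(means[g][sp],
                                             means["control"][sp])})
    return pd.DataFrame(rows)


def _targets_from_readouts(readouts: pd.DataFrame,
                           analytes: Sequence[str]) -> pd.DataFrame:
    """Geometric-mean intensity per (group, analyte), normalised to control."""
    required = {"group", "replicate", "analyte", "intensity"}
    missing = required - set(readouts.columns)
    if missing:
        raise ValueError(f"readout table lacks columns {sorted(missing)}")
    if "control" not in set(readouts["group"]):
        raise ValueError("readout table must contain a control group")
    absent = set(analytes) - set(readouts["analyte"])
    if absent:
        raise ValueError(f"readout table lacks analytes {sorted(absent)}")
    sub = readouts[readouts["analyte"].isin(analytes)].copy()
    if (sub["intensity"] <= 0).any():
        raise ValueError("intensities must be positive")
    sub["log_i"] = np.log(sub["intensity"])
    g = sub.groupby(["group", "analyte"], as_index=False)["log_i"].mean()
    ctrl = g[g["group"] == "control"].set_index("analyte")["log_i"]
    g["target_fold"] = np.exp(g["log_i"] - g["analyte"].map(ctrl))
    return g[g["group"] != "control"][["group", "analyte", "target_fold"]]


def fit_to_readouts(readouts: pd.DataFrame, spec: FitSpec,
                    seed: int = 0) -> FitResult:
    """Fit free rates to band-intensity fold changes.

    Log-uniform random search over ``spec.bounds`` (plus the base point),
    followed by Nelder-Mead refinement in log-rate space with an
    out-of-bounds penalty; ``spec.n_refine = 0`` returns the best initial
    sample unrefined.  Deterministic given ``seed``.
    """
    targets = _targets_from_readouts(readouts, spec.analytes)
    groups = sorted(set(targets["group"]))
    names = list(spec.bounds)
    log_lo = np.log([spec.bounds[n][0] for n in names])
    log_hi = np.log([spec.bounds[n][1] for n in names])
    tkey = targets.set_index(["group", "analyte"])["target_fold"]

    n_evals = 0

    def loss_of(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        penalty = float(np.sum(np.maximum(x - log_hi, 0) ** 2 +
                               np.maximum(log_lo - x, 0) ** 2))
        xc = np.clip(x, log_lo, log_hi)
        cand = spec.base.with_rates(dict(zip(names, np.exp(xc))))
        pred = predicted_folds(cand, groups, spec.analytes, spec.window,
                               spec.t_end, spec.grid_step)
        pkey = pred.set_index(["group", "analyte"])["fold"]
        resid = np.log(pkey) - np.log(tkey.reindex(pkey.index))
        return float(np.sum(resid ** 2)) + 100.0 * penalty

    rng = np.random.default_rng(seed)
    x_best = np.log([getattr(spec.base, n) for n in names]).clip(log_lo, log_hi)
    best = loss_of(x_best)
    trace = [best]
    for _ in range(spec.n_initial):
        x = rng.uniform(log_lo, log_hi)
        val = loss_of(x)
        if val < best:
            best, x_best = val, x
        trace.append(best)

    if spec.n_refine > 0:
        res = minimize(loss_of, x_best, method="Nelder-Mead",
                       options={"maxfev": spec.n_refine, "xatol": 1e-4,
                                "fatol": 1e-10})
        if res.fun < best:
            best, x_best = float(res.fun), res.x
        trace.append(best)

    xc = np.clip(x_best, log_lo, log_hi)
    fitted = spec.base.with_rates(dict(zip(names, np.exp(xc))))
    pred = predicted_folds(fitted, groups, spec.analytes, spec.window,
                           spec.t_end, spec.grid_step)
    pred = pred.merge(targets, on=["group", "analyte"])
    pred["log_residual"] = np.log(pred["fold"]) - np.log(pred["target_fold"])
    return FitResult(params=fitted, loss=best, trace=trace,
                     residuals=pred, n_evaluations=n_evals)


@dataclass
class RecoveryReport:
    """Planted-vs-recovered condition-level fold changes."""

    table: pd.DataFrame
    median_error: float
    tolerance: float
    recovered: bool
    noise_cv: float
    n_reps: int
    seed: int
    fitted: ParameterSet


def parameter_recovery(true_params: ParameterSet, noise_cv: float = 0.15,
                       n_reps: int = 3, seed: int = 0,
                       tolerance: float = 0.20,
                       spec: FitSpec | None = None) -> RecoveryReport:
    """Generate synthetic readouts from known parameters, refit, and score.

    Fold changes (not raw rates) are the recovery target; the report flags
    ``recovered=False`` when the median relative fold error exceeds
    ``tolerance`` - expected behaviour at large noise, not an exception.
    """
    from .synth import generate_wb_readouts

    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    groups = ["control", "MGF", "pressure", "pressure+MGF"]
    conds = [c for c in standard_conditions(true_params) if c.name in groups]
    analytes = tuple(ANALYTE_SPECIES)
    readouts = generate_wb_readouts(true_params, conds, n_reps=n_reps,
                                    noise_cv=noise_cv, seed=seed,
                                    analytes=analytes)
    if spec is None:
        # the searcher knows the structure but not the coupling strengths:
        # free rates start from the bounds' geometric middle, not the truth
        coupling = ("k_fP", "k_yM", "k_yP", "k_pF", "k_eY", "k_sE", "k_sP")
        bounds = bounds_around(true_params, 100.0, coupling)
        base = true_params.with_rates(_geometric_mid(bounds))
        spec = FitSpec(base=base, bounds=bounds, analytes=analytes)
    fit = fit_to_readouts(readouts, spec, seed=seed)

    planted = predicted_folds(true_params, [g for g in groups if g != "control"],
                              analytes, spec.window, spec.t_end)
    recovered = predicted_folds(fit.params, [g for g in groups if g != "control"],
                                analytes, spec.window, spec.t_end)
    table = planted.merge(recovered, on=["group", "analyte"],
                          suffixes=("_planted", "_fitted"))
    table["rel_error"] = np.abs(table["fold_fitted"] / table["fold_planted"]
                                - 1.0)
    med = float(table["rel_error"].median())
    return RecoveryReport(table=table, median_error=med, tolerance=tolerance,
                          recovered=med <= tolerance, noise_cv=noise_cv,
                          n_reps=n_reps, seed=seed, fitted=fit.params)
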