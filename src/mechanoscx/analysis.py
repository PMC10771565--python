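"""In-silico experiments: time-course summaries, condition comparisons,
Src-family (PP2) inhibition titration and robustness of conclusions.

The summary statistics mirror how the wet-lab results are read: the time
of the Scleraxis maximum, its return to the pre-stimulus level, and the
mean level over the 12-24 h window used when comparing treatment groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Condition, standard_conditions, steady_state
from .params import RATE_NAMES, ParameterSet
from .simulate import (EnsembleSummary, ODESolution, run_ensemble,
                       simulate_ode)

__all__ = [
    "TimeCourseSummary", "ComparisonTable", "RobustnessReport",
    "KINASE_ACTIVE", "DEFAULT_WINDOW",
    "summarize_timecourse", "window_mean", "compare_conditions",
    "inhibitor_experiment", "robustness_scan",
]

#: Active (phosphorylated) form of each modelled kinase.
KINASE_ACTIVE: tuple[str, ...] = ("FAK_a", "FYN_a", "ERK_a", "P38_a")

#: Comparison window (hours) used for group-level summaries.
DEFAULT_WINDOW: tuple[float, float] = (12.0, 24.0)


@dataclass(frozen=True)
class TimeCourseSummary:
    """Peak, window-mean and return-to-baseline summary of one species."""

    species: str
    baseline: float
    peak_time: float
    peak_value: float
    return_time: float  # inf when the level never re-enters the band
    window_mean: float
    window: tuple[float, float]
    tolerance: float


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9 or hi <= lo:
        raise ValueError(f"window {window} outside the simulated grid "
                         f"[{times[0]}, {times[-1]}]")
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def window_mean(series, species: str,
                window: tuple[float, float] = DEFAULT_WINDOW) -> float:
    """Mean of a species' (ensemble or mean-field) level over the window."""
    t = series.grid_times
    return float(series.species_mean(species)[_window_mask(t, window)].mean())


def summarize_timecourse(series, species: str = "SCX",
                         window: tuple[float, float] = DEFAULT_WINDOW,
                         baseline_mode: str = "steady_state",
                         tolerance: float = 0.10,
                         control=None) -> TimeCourseSummary:
    """Summarise a simulated time course.

    Parameters
    ----------
    series
        An :class:`~mechanoscx.simulate.EnsembleSummary` or
        :class:`~mechanoscx.simulate.ODESolution`.
    baseline_mode
        ``"steady_state"`` (default): the analytic pre-stimulus steady
        state of the series' own condition.  ``"control"``: the time-matched
        control series (pass it as ``control=``); the return test then
        compares against the control level point by point.
    tolerance
        Relative band half-width for the return-to-baseline test.

    The peak is the argmax of the (ensemble) mean on the grid, earliest
    grid time on ties; the return time is the first grid time after the
    peak at which the level is within ``tolerance * baseline`` of baseline.
    """
    t = series.grid_times
    m = series.species_mean(species)
    if baseline_mode == "steady_state":
        ss = steady_state(series.params, series.condition.inhibition)
        if species not in ss:
            raise ValueError(f"no analytic baseline for species {species!r}")
        ref = np.full_like(m, ss[species])
    elif baseline_mode == "control":
        if control is None:
            raise ValueError("baseline_mode='control' requires a control series")
        if not np.allclose(control.grid_times, t):
            raise ValueError("control series must share the output grid")
        ref = control.species_mean(species)
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")

    mask = _window_mask(t, window)
    ipk = int(np.argmax(m))
    band = np.abs(m - ref) <= tolerance * ref
    later = np.where(band & (np.arange(len(t)) > ipk))[0]
    return TimeCourseSummary(
        species=species,
        baseline=float(ref.mean()) if baseline_mode == "control" else float(ref[0]),
        peak_time=float(t[ipk]),
        peak_value=float(m[ipk]),
        return_time=float(t[later[0]]) if len(later) else math.inf,
        window_mean=float(m[mask].mean()),
        window=tuple(window),
        tolerance=tolerance,
    )


@dataclass
class ComparisonTable:
    """Per-condition window means, fold changes vs control, and the SCX
    time-course summary."""

    table: pd.DataFrame
    scx_summaries: dict[str, TimeCourseSummary]
    window: tuple[float, float]
    mode: str

    def fold(self, condition: str, species: str = "SCX") -> float:
        row = self.table.loc[self.table["condition"] == condition]
        if row.empty:
            raise KeyError(f"no condition {condition!r} in the table")
        return float(row[f"fold_{species}"].iloc[0])


def _simulate(condition: Condition, params: ParameterSet, mode: str,
              n_reps: int, t_end: float, seed: int, grid_step: float):
    if mode == "ode":
        return simulate_ode(condition, params, t_end, grid_step=grid_step)
    if mode == "ssa":
        return run_ensemble(condition, params, n_reps=n_reps, t_end=t_end,
                            seed=seed, grid_step=grid_step)
    raise ValueError(f"mode must be 'ode' or 'ssa', got {mode!r}")


def compare_conditions(params: ParameterSet,
                       conditions: Sequence[Condition] | None = None,
                       n_reps: int = 200, t_end: float = 48.0, seed: int = 0,
                       mode: str = "ssa", grid_step: float = 0.5,
                       window: tuple[float, float] = DEFAULT_WINDOW,
                       ) -> ComparisonTable:
    """Simulate each condition and tabulate window means and fold changes.

    A condition named ``"control"`` must be present; fold changes are
    window means divided by the control's (control therefore has fold 1 in
    every column).  Each condition reuses the same master seed so that
    conditions differ only through their treatment, not their noise draw.
    """
    if conditions is None:
        conditions = standard_conditions(params, include_pp2=False)
    names = [c.name for c in conditions]
    if "control" not in names:
        raise ValueError("conditions must include one named 'control'")

    rows = []
    summaries: dict[str, TimeCourseSummary] = {}
    series_by_name = {}
    for cond in conditions:
        series = _simulate(cond, params, mode, n_reps, t_end, seed, grid_step)
        series_by_name[cond.name] = series
        summaries[cond.name] = summarize_timecourse(series, "SCX",
                                                    window=window)
        row = {"condition": cond.name}
        for sp in ("SCX",) + KINASE_ACTIVE:
            row[f"mean_{sp}"] = window_mean(series, sp, window)
        rows.append(row)

    df = pd.DataFrame(rows)
    ctrl = df.loc[df["condition"] == "control"].iloc[0]
    for sp in ("SCX",) + KINASE_ACTIVE:
        denom = ctrl[f"mean_{sp}"]
        df[f"fold_{sp}"] = df[f"mean_{sp}"] / denom if denom > 0 else np.nan
    return ComparisonTable(table=df, scx_summaries=summaries,
                           window=tuple(window), mode=mode)


def inhibitor_experiment(params: ParameterSet, base_condition: Condition,
                         inhibition_grid: Sequence[float] = (1.0, 0.5, 0.1, 0.0),
                         n_reps: int = 200, seed: int = 0, mode: str = "ssa",
                         t_end: float = 48.0, grid_step: float = 0.5,
                         window: tuple[float, float] = DEFAULT_WINDOW,
                         ) -> pd.DataFrame:
    """Titrate Fyn inhibition (PP2 dose surrogate) on a base condition.

    ``inhibition_grid`` runs from 1 (uninhibited) downward.  Each level
    re-runs the base condition with the Fyn activation propensity scaled,
    using the same master seed.  Returns one row per level with the window
    means of SCX and the active kinases.
    """
    grid = list(inhibition_grid)
    if any(not 0.0 <= g <= 1.0 for g in grid):
        raise ValueError("inhibition levels must lie in [0, 1]")
    if grid != sorted(grid, reverse=True):
        raise ValueError("inhibition_grid must be sorted descending from 1")
    rows = []
    for level in grid:
        cond = Condition(base_condition.name, base_condition.mgf_initial,
                         base_condition.protocol, level)
        series = _simulate(cond, params, mode, n_reps, t_end, seed, grid_step)
        row = {"inhibition": level}
        for sp in ("SCX",) + KINASE_ACTIVE:
            row[f"mean_{sp}"] = window_mean(series, sp, window)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RobustnessReport:
    """Pass fractions of the headline conclusions under random rate
    perturbations."""

    n_perturbations: int
    fold_range: float
    seed: int
    pass_fraction: dict[str, float]
    details: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frac in self.pass_fraction.items():
            if not (0.0 <= frac <= 1.0) and not math.isnan(frac):
                raise ValueError(f"pass fraction for {name!r} outside [0,1]")


#: Conclusion names understood by :func:`robustness_scan`.
CONCLUSIONS: tuple[str, ...] = (
    "peak_in_window", "returns_to_baseline", "additive_ordering",
    "pp2_reduces_scx",
)


def robustness_scan(params: ParameterSet, fold_range: float = 2.0,
                    n_perturbations: int = 200, seed: int = 0,
                    conclusions: Sequence[str] = CONCLUSIONS,
                    constraints=None) -> RobustnessReport:
    """Re-evaluate the headline conclusions under random rate perturbations.

    Each perturbation multiplies every rate constant independently by a
    factor drawn log-uniformly from ``[1/fold_range, fold_range]``;
    conclusions are re-checked with the mean-field screen.  The report
    gives the fraction of perturbed models for which each conclusion
    still holds.

    The default constraint set here tests the conclusions *strictly*
    (orderings and the PP2 reversal with margin 0) rather than with the
    calibration margins: robustness asks whether the claims survive, not
    whether the safety margins do.
    """
    from .calibrate import ConstraintSet, evaluate_constraints

    if fold_range < 1:
        raise ValueError(f"fold_range must be >= 1, got {fold_range!r}")
    unknown = set(conclusions) - set(CONCLUSIONS)
    if unknown:
        raise ValueError(f"unknown conclusions: {sorted(unknown)}")
    cs = constraints if constraints is not None else ConstraintSet(
        ordering_margin=0.0, pp2_margin=0.0, kinase_up_margin=0.0)
    key = {"peak_in_window": "C1_peak_window",
           "returns_to_baseline": "C2_return",
           "additive_ordering": "C3_ordering",
           "pp2_reduces_scx": "C4_pp2"}

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_perturbations):
        logf = rng.uniform(-math.log(fold_range), math.log(fold_range),
                           size=len(RATE_NAMES))
        factors = dict(zip(RATE_NAMES, np.exp(logf)))
        perturbed = params.perturbed(factors)
        res = evaluate_constraints(perturbed, cs, mode="ode")
        rec = {"perturbation": i}
        for c in conclusions:
            rec[c] = bool(res[key[c]].passed)
        records.append(rec)

    details = pd.DataFrame(records, columns=["perturbation", *conclusions])
    frac = {c: (float(details[c].mean()) if n_perturbations else math.nan)
            for c in conclusions}
    return RobustnessReport(n_perturbations=n_perturbations,
                            fold_range=fold_range, seed=seed,
                            pass_fraction=frac, details=details)
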