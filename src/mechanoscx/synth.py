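"""Synthetic pseudo-experimental readouts.

Stands in for the study's wet-lab quantifications so the comparison and
fitting stages can be exercised end to end without any download:

* Western-blot-style band intensities (reference-normalised integrated
  optical densities) per treatment group and analyte, with multiplicative
  lognormal replicate noise;
* qPCR relative expression (2^-dCT scale) of MGF mRNA across pressure
  doses and time points, with the planted maximum at (120 kPa, 24 h);
* the two-group sample-size formula used to plan the animal experiments.

Noise is mean-corrected lognormal: a replicate equals its planted
expectation times ``exp(N(-s^2/2, s))`` with ``s^2 = ln(1 + cv^2)``, so the
expectation of the noisy value is exactly the planted value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Condition, hill_response
from .params import ParameterSet

__all__ = [
    "WB_ANALYTES", "SampleSizeSpec",
    "generate_wb_readouts", "generate_qpcr_mgf", "two_group_sample_size",
    "default_qpcr_profile",
]

#: Default analyte panel of the synthetic blot tables.
WB_ANALYTES: tuple[str, ...] = ("SCX", "p-FAK", "p-Fyn", "p-ERK", "p-p38",
                                "integrin-readout")


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return np.exp(rng.normal(-0.5 * s2, math.sqrt(s2), size=size))


def generate_wb_readouts(params: ParameterSet,
                         conditions: Sequence[Condition],
                         n_reps: int = 3, noise_cv: float = 0.15,
                         seed: int = 0,
                         analytes: Sequence[str] = WB_ANALYTES,
                         window: tuple[float, float] = (12.0, 24.0),
                         t_end: float = 48.0) -> pd.DataFrame:
    """Synthetic normalised band intensities per (group, replicate, analyte).

    The planted expectation of each kinase/SCX analyte is the model's
    mean-field window-mean fold change versus control, so the control
    group's expected intensity is 1 for every analyte.  The integrin
    engagement readout has no model species; it is planted directly from
    the Hill response as ``1 + H(P_peak)`` (pressure groups only), matching
    its observed pressure-specific activation.
    """
    from .calibrate import ANALYTE_SPECIES, predicted_folds

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    names = [c.name for c in conditions]
    if "control" not in names:
        raise ValueError("conditions must include one named 'control'")

    model_analytes = [a for a in analytes if a in ANALYTE_SPECIES]
    groups = [n for n in names if n != "control"]
    folds = predicted_folds(params, groups, model_analytes, window, t_end) \
        if groups and model_analytes else pd.DataFrame(
            columns=["group", "analyte", "fold"])
    fkey = folds.set_index(["group", "analyte"])["fold"] if len(folds) else {}

    expectations = {}
    for cond in conditions:
        peak_p = max((amp for _, _, amp in cond.protocol.segments),
                     default=0.0)
        for a in analytes:
            if a in ANALYTE_SPECIES:
                e = 1.0 if cond.name == "control" \
                    else float(fkey[(cond.name, a)])
            elif a == "integrin-readout":
                e = 1.0 + hill_response(peak_p, params.K_hill, params.h_hill)
            else:
                raise ValueError(f"unknown analyte {a!r}")
            expectations[(cond.name, a)] = e

    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for a in analytes:
            noise = _lognormal_factors(rng, noise_cv, n_reps)
            for rep in range(n_reps):
                rows.append({"group": cond.name, "replicate": rep,
                             "analyte": a,
                             "intensity": expectations[(cond.name, a)]
                             * noise[rep]})
    return pd.DataFrame(rows)


def default_qpcr_profile(doses: Sequence[float] = (90.0, 120.0, 150.0),
                         times: Sequence[float] = (0.0, 12.0, 24.0, 36.0),
                         ) -> dict[tuple[float, float], float]:
    """Planted MGF-mRNA relative expression per (dose kPa, time h).

    Unity at time 0 for every dose; a biphasic dose response peaking at
    120 kPa; a time course peaking at 24 h.  The global maximum sits at
    (120 kPa, 24 h).  Effect sizes are design choices of this generator -
    only the location of the maximum reflects the reported pattern.
    """
    dose_gain = {90.0: 0.8, 120.0: 1.6, 150.0: 1.1}
    time_shape = {0.0: 0.0, 12.0: 0.6, 24.0: 1.0, 36.0: 0.4}
    profile = {}
    for d in doses:
        for t in times:
            g = dose_gain.get(float(d), 1.0)
            s = time_shape.get(float(t), 0.5)
            profile[(float(d), float(t))] = 1.0 + g * s
    return profile


def generate_qpcr_mgf(doses: Sequence[float] = (90.0, 120.0, 150.0),
                      times: Sequence[float] = (0.0, 12.0, 24.0, 36.0),
                      n_reps: int = 3,
                      effect_profile: Mapping[tuple[float, float], float]
                      | None = None,
                      noise_cv: float = 0.15, seed: int = 0) -> pd.DataFrame:
    """Synthetic qPCR table of MGF relative expression (2^-dCT scale)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    profile = dict(effect_profile) if effect_profile is not None \
        else default_qpcr_profile(doses, times)
    for (d, t) in ((float(d), float(t)) for d in doses for t in times):
        v = profile.get((d, t))
        if v is None:
            raise ValueError(f"effect_profile lacks ({d} kPa, {t} h)")
        if v <= 0:
            raise ValueError(f"relative expression must be > 0, "
                             f"got {v} at ({d} kPa, {t} h)")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        for t in times:
            e = profile[(float(d), float(t))]
            noise = _lognormal_factors(rng, noise_cv, n_reps)
            for rep in range(n_reps):
                rows.append({"dose_kpa": float(d), "time_h": float(t),
                             "replicate": rep,
                             "rel_expression": e * noise[rep]})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the two-group sample-size formula.

    ``z_alpha`` and ``z_beta`` are standard-normal quantiles (supplied
    directly - e.g. 1.96 for two-sided alpha 0.05, 1.2816 for power 0.9);
    ``sigma`` the common within-group SD and ``delta`` the between-group
    mean difference, in the same units.
    """

    z_alpha: float
    z_beta: float
    sigma: float
    delta: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0 (the formula is undefined "
                             "for a zero group difference)")


def two_group_sample_size(spec: SampleSizeSpec) -> int:
    """Per-group n from ``n = (z_alpha + z_beta)^2 * 2 sigma^2 / delta^2``,
    rounded up."""
    n = (spec.z_alpha + spec.z_beta) ** 2 * 2.0 * spec.sigma ** 2 \
        / spec.delta ** 2
    return math.ceil(n)
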