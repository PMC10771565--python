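"""Reaction network: species, stoichiometry, propensities, treatment conditions.

Eleven elementary reactions over ten species.  The four kinases are
conserved two-state pools (activation/deactivation conversions R1-R8);
Scleraxis has zeroth-order production driven by active ERK and p38 plus
first-order decay (R9/R10); the MGF ligand is cleared first-order (R11).
Pressure enters only through the Hill response modulating FAK (and,
weakly, Fyn) activation; PP2-type Src-family inhibition scales the Fyn
activation propensity by a factor in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import ParameterSet

__all__ = [
    "SPECIES", "N_REACTIONS", "REACTIONS", "STOICHIOMETRY",
    "PressureProtocol", "Condition", "NetworkState",
    "hill_response", "propensities", "apply_reaction",
    "standard_conditions", "steady_state", "initial_state",
    "network_table",
]

SPECIES: tuple[str, ...] = (
    "FAK_i", "FAK_a", "FYN_i", "FYN_a", "ERK_i", "ERK_a",
    "P38_i", "P38_a", "MGF", "SCX",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}

#: (label, reactant species or None, product species or None)
REACTIONS: tuple[tuple[str, str | None, str | None], ...] = (
    ("FAK activation", "FAK_i", "FAK_a"),
    ("FAK deactivation", "FAK_a", "FAK_i"),
    ("Fyn activation", "FYN_i", "FYN_a"),
    ("Fyn deactivation", "FYN_a", "FYN_i"),
    ("p38 activation", "P38_i", "P38_a"),
    ("p38 deactivation", "P38_a", "P38_i"),
    ("ERK activation", "ERK_i", "ERK_a"),
    ("ERK deactivation", "ERK_a", "ERK_i"),
    ("SCX production", None, "SCX"),
    ("SCX degradation", "SCX", None),
    ("MGF clearance", "MGF", None),
)
N_REACTIONS = len(REACTIONS)

STOICHIOMETRY = np.zeros((N_REACTIONS, len(SPECIES)), dtype=np.int64)
for _j, (_, _src, _dst) in enumerate(REACTIONS):
    if _src is not None:
        STOICHIOMETRY[_j, _IDX[_src]] = -1
    if _dst is not None:
        STOICHIOMETRY[_j, _IDX[_dst]] = 1


def hill_response(pressure: float, K_hill: float, h_hill: float) -> float:
    """Saturating pressure -> activation drive, ``P^h / (K^h + P^h)``.

    Strictly increasing in pressure, 0 at rest, 1/2 at ``K_hill`` and
    approaching 1 at large amplitudes.
    """
    if pressure < 0:
        raise ValueError(f"pressure must be >= 0 kPa, got {pressure!r}")
    if K_hill <= 0:
        raise ValueError(f"K_hill must be > 0 kPa, got {K_hill!r}")
    if h_hill < 1:
        raise ValueError(f"h_hill must be >= 1, got {h_hill!r}")
    if pressure == 0:
        return 0.0
    # computed on log scale so huge P^h cannot overflow
    r = (K_hill / pressure) ** h_hill
    return 1.0 / (1.0 + r)


@dataclass(frozen=True)
class PressureProtocol:
    """Piecewise-constant pressure envelope.

    ``segments`` is an ordered list of ``(t_start, t_end, amplitude)`` with
    times in hours and amplitude in kPa.  Segments are half-open
    ``[t_start, t_end)``; pressure is 0 outside every segment.  Cyclic
    loading (e.g. 0.1 Hz cycling to a peak) is represented by its envelope
    amplitude: the model evolves on hour timescales where individual cycles
    are unresolvable.
    """

    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(p)) for a, b, p in self.segments)
        object.__setattr__(self, "segments", segs)
        last_end = -np.inf
        for t0, t1, amp in segs:
            if not t0 < t1:
                raise ValueError(f"segment [{t0}, {t1}) is empty or reversed")
            if t0 < last_end:
                raise ValueError("segments overlap or are out of order")
            if amp < 0:
                raise ValueError(f"amplitude must be >= 0 kPa, got {amp}")
            last_end = t1

    def pressure_at(self, t: float) -> float:
        """Amplitude of the segment containing time ``t`` (hours), else 0."""
        if t < 0:
            raise ValueError(f"time must be >= 0 h, got {t!r}")
        for t0, t1, amp in self.segments:
            if t0 <= t < t1:
                return amp
        return 0.0

    def breakpoints(self, t_end: float) -> np.ndarray:
        """Sorted segment boundaries strictly inside ``(0, t_end)``."""
        pts = {t for seg in self.segments for t in seg[:2] if 0.0 < t < t_end}
        return np.array(sorted(pts), dtype=np.float64)


def pressure_at(protocol: PressureProtocol, t: float) -> float:
    """Module-level alias for :meth:`PressureProtocol.pressure_at`."""
    return protocol.pressure_at(t)


@dataclass(frozen=True)
class Condition:
    """One named treatment: MGF bolus, pressure protocol, Fyn inhibition.

    ``inhibition`` multiplies the Fyn activation propensity: 1 means
    uninhibited, 0.1 emulates 10 uM PP2, 0 blocks Fyn activation entirely.
    """

    name: str
    mgf_initial: int = 0
    protocol: PressureProtocol = field(default_factory=PressureProtocol)
    inhibition: float = 1.0

    def __post_init__(self) -> None:
        if self.mgf_initial < 0 or int(self.mgf_initial) != self.mgf_initial:
            raise ValueError(f"mgf_initial must be a non-negative integer, "
                             f"got {self.mgf_initial!r}")
        object.__setattr__(self, "mgf_initial", int(self.mgf_initial))
        if not 0.0 <= self.inhibition <= 1.0:
            raise ValueError(f"inhibition must lie in [0, 1], got {self.inhibition!r}")


@dataclass
class NetworkState:
    """Integer copy-number state of the network at one instant."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(SPECIES),):
            raise ValueError(f"state must have {len(SPECIES)} species")

    def __getitem__(self, species: str) -> int:
        return int(self.counts[_IDX[species]])

    def validate(self, params: ParameterSet) -> None:
        if (self.counts < 0).any():
            bad = [SPECIES[i] for i in np.where(self.counts < 0)[0]]
            raise ValueError(f"negative copy numbers for {bad}")
        pools = (("FAK_i", "FAK_a", params.N_fak), ("FYN_i", "FYN_a", params.N_fyn),
                 ("ERK_i", "ERK_a", params.N_erk), ("P38_i", "P38_a", params.N_p38))
        for lo, hi, total in pools:
            if self[lo] + self[hi] != total:
                raise ValueError(
                    f"{lo}+{hi} = {self[lo] + self[hi]} != configured total {total}")


def propensities(state: NetworkState, params: ParameterSet,
                 pressure_now: float, inhibition: float = 1.0) -> np.ndarray:
    """Per-reaction firing rates (1/h) at the given state and inputs.

    Activation propensities are mass-action in the inactive pool with
    linear stimulus terms; the pressure drive is the Hill response
    ``H(P)``; active Fyn feeds back onto FAK activation through the
    crosstalk factor ``1 + w_cross * FYN_a / N_fyn``.
    """
    state.validate(params)
    if not 0.0 <= inhibition <= 1.0:
        raise ValueError(f"inhibition must lie in [0, 1], got {inhibition!r}")
    p = params
    H = hill_response(pressure_now, p.K_hill, p.h_hill)
    c = state.counts
    fak_i, fak_a = c[0], c[1]
    fyn_i, fyn_a = c[2], c[3]
    erk_i, erk_a = c[4], c[5]
    p38_i, p38_a = c[6], c[7]
    mgf, scx = c[8], c[9]

    a = np.empty(N_REACTIONS, dtype=np.float64)
    a[0] = fak_i * (p.k_f0 + p.k_fP * H) * (1.0 + p.w_cross * fyn_a / p.N_fyn)
    a[1] = p.k_fd * fak_a
    a[2] = inhibition * fyn_i * (p.k_y0 + p.k_yM * mgf / p.M_ref + p.k_yP * H)
    a[3] = p.k_yd * fyn_a
    a[4] = p38_i * (p.k_p0 + p.k_pF * fak_a / p.N_fak)
    a[5] = p.k_pd * p38_a
    a[6] = erk_i * (p.k_e0 + p.k_eY * fyn_a / p.N_fyn)
    a[7] = p.k_ed * erk_a
    a[8] = p.k_s0 + p.k_sE * erk_a + p.k_sP * p38_a
    a[9] = p.gamma_s * scx
    a[10] = p.delta_m * mgf
    return a


def apply_reaction(state: NetworkState, reaction_index: int) -> NetworkState:
    """Return the state after firing reaction ``reaction_index`` (0-based)."""
    if not 0 <= reaction_index < N_REACTIONS:
        raise ValueError(f"reaction index out of range: {reaction_index}")
    label, src, _ = REACTIONS[reaction_index]
    if src is not None and state[src] == 0:
        raise ValueError(f"cannot fire '{label}': {src} count is 0")
    return NetworkState(state.counts + STOICHIOMETRY[reaction_index],
                        time=state.time)


def steady_state(params: ParameterSet, inhibition: float = 1.0) -> dict[str, float]:
    """Pre-stimulus (P=0, MGF=0) deterministic steady state, exact in the
    mean field.

    The two-state pools equilibrate independently (Fyn first, then FAK via
    crosstalk, then ERK and p38 from the basal active fractions), and the
    SCX baseline balances total basal production against degradation.
    """
    p = params

    def frac(act: float, deact: float) -> float:
        tot = act + deact
        return act / tot if tot > 0 else 0.0

    y = frac(inhibition * p.k_y0, p.k_yd)
    f = frac(p.k_f0 * (1.0 + p.w_cross * y), p.k_fd)
    e = frac(p.k_e0 + p.k_eY * y, p.k_ed)
    q = frac(p.k_p0 + p.k_pF * f, p.k_pd)
    prod = p.k_s0 + p.k_sE * e * p.N_erk + p.k_sP * q * p.N_p38
    if p.gamma_s > 0:
        scx = prod / p.gamma_s
    else:
        scx = 0.0 if prod == 0 else np.inf  # no turnover at all -> empty pool
    return {
        "FAK_a": f * p.N_fak, "FYN_a": y * p.N_fyn,
        "ERK_a": e * p.N_erk, "P38_a": q * p.N_p38,
        "SCX": scx,
    }


def initial_state(condition: Condition, params: ParameterSet) -> NetworkState:
    """Integer initial state: each pool at its rounded pre-stimulus steady
    state for the condition's inhibition level, plus the MGF bolus."""
    ss = steady_state(params, condition.inhibition)
    c = np.zeros(len(SPECIES), dtype=np.int64)
    for sp, total in (("FAK", params.N_fak), ("FYN", params.N_fyn),
                      ("ERK", params.N_erk), ("P38", params.N_p38)):
        a = int(round(ss[f"{sp}_a"]))
        c[_IDX[f"{sp}_a"]] = a
        c[_IDX[f"{sp}_i"]] = total - a
    c[_IDX["MGF"]] = condition.mgf_initial
    c[_IDX["SCX"]] = int(round(ss["SCX"]))
    return NetworkState(c, time=0.0)


def standard_conditions(params: ParameterSet | None = None,
                        mgf_bolus: int = 100,
                        pressure_kpa: float = 120.0,
                        pressure_hours: float = 1.0,
                        pp2_inhibition: float = 0.1,
                        include_pp2: bool = True) -> list[Condition]:
    """The in-vitro treatment groups as model conditions.

    control; MGF (bolus of 100 copies at t=0); pressure (120 kPa envelope
    on [0, 1] h); pressure+MGF; and, optionally, a PP2 variant of each with
    the Fyn activation propensity scaled by ``pp2_inhibition``.  The two
    MGF preparations used experimentally (humanised and Goldspink peptide)
    behave alike and are represented by the single MGF condition.
    """
    pulse = PressureProtocol(((0.0, pressure_hours, pressure_kpa),))
    none = PressureProtocol()
    base = [
        Condition("control", 0, none, 1.0),
        Condition("MGF", mgf_bolus, none, 1.0),
        Condition("pressure", 0, pulse, 1.0),
        Condition("pressure+MGF", mgf_bolus, pulse, 1.0),
    ]
    if not include_pp2:
        return base
    pp2 = [Condition(c.name + "+PP2", c.mgf_initial, c.protocol, pp2_inhibition)
           for c in base]
    return base + pp2


def network_table(params: ParameterSet) -> pd.DataFrame:
    """Plain-text stoichiometry/propensity table for inspection or export."""
    formulas = (
        "FAK_i*(k_f0 + k_fP*H(P))*(1 + w_cross*FYN_a/N_fyn)",
        "k_fd*FAK_a",
        "inhibition*FYN_i*(k_y0 + k_yM*MGF/M_ref + k_yP*H(P))",
        "k_yd*FYN_a",
        "P38_i*(k_p0 + k_pF*FAK_a/N_fak)",
        "k_pd*P38_a",
        "ERK_i*(k_e0 + k_eY*FYN_a/N_fyn)",
        "k_ed*ERK_a",
        "k_s0 + k_sE*ERK_a + k_sP*P38_a",
        "gamma_s*SCX",
        "delta_m*MGF",
    )
    rows = []
    for j, (label, src, dst) in enumerate(REACTIONS):
        rows.append({
            "reaction": f"R{j + 1}",
            "label": label,
            "reactant": src or "-",
            "product": dst or "-",
            "propensity": formulas[j],
        })
    return pd.DataFrame(rows)
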