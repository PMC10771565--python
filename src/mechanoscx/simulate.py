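"""Exact stochastic simulation (Gillespie direct method) and mean-field ODE.

Pressure is piecewise constant, so between protocol breakpoints the jump
process is time-homogeneous and the direct method applies unchanged; at a
breakpoint the pending waiting time is discarded and the clock advanced to
the boundary, which is exact for piecewise-constant propensities.  The
deterministic counterpart integrates the same rate laws with copy numbers
treated as continuous, restarting the integrator at each breakpoint; it
serves as a validation oracle and as the fast screen during calibration.

Reproducibility contract: every stochastic run is driven by one
``numpy.random.Generator``.  An ensemble with master seed ``s`` gives
replicate ``i`` the generator ``default_rng(SeedSequence(s).spawn(n)[i])``,
so summaries are bit-reproducible across runs and machines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

from .model import (SPECIES, STOICHIOMETRY, Condition, NetworkState,
                    initial_state, steady_state)
from .params import ParameterSet

__all__ = [
    "Trajectory", "EnsembleSummary", "ODESolution",
    "simulate_ssa", "simulate_ode", "run_ensemble",
    "default_grid", "replicate_seeds",
]

_N_SP = len(SPECIES)
_SP_IDX = {name: i for i, name in enumerate(SPECIES)}


def default_grid(t_end: float, step: float = 0.5) -> np.ndarray:
    """Uniform output grid 0..t_end inclusive (hours)."""
    n = int(round(t_end / step))
    if not math.isclose(n * step, t_end):
        raise ValueError(f"t_end={t_end} is not a multiple of step={step}")
    return np.linspace(0.0, t_end, n + 1)


def replicate_seeds(master_seed: int, n_reps: int) -> list[np.random.SeedSequence]:
    """Deterministic replicate-seed derivation: children of the master
    ``SeedSequence`` (replicate i -> ``SeedSequence(master).spawn(n)[i]``)."""
    return np.random.SeedSequence(master_seed).spawn(n_reps)


def _intervals(condition: Condition, t_end: float):
    """Constant-pressure intervals covering [0, t_end]: edge times and the
    pressure on each [edges[i], edges[i+1])."""
    bps = condition.protocol.breakpoints(t_end)
    edges = np.concatenate(([0.0], bps, [t_end]))
    pvals = np.array([condition.protocol.pressure_at(edges[i])
                      for i in range(len(edges) - 1)], dtype=np.float64)
    return edges, pvals


@njit(cache=False)
def _ssa_kernel(y, pv, edges, pvals, inhibition, grid, grid_out,
                ev_times, ev_react, record, rng):  # pragma: no cover - jitted
    # pv layout: 18 rates (see params.RATE_NAMES), then K_hill, h_hill,
    # w_cross, N_fak, N_fyn, N_erk, N_p38, M_ref.
    k_f0, k_fP, k_fd = pv[0], pv[1], pv[2]
    k_y0, k_yM, k_yP, k_yd = pv[3], pv[4], pv[5], pv[6]
    k_p0, k_pF, k_pd = pv[7], pv[8], pv[9]
    k_e0, k_eY, k_ed = pv[10], pv[11], pv[12]
    k_s0, k_sE, k_sP = pv[13], pv[14], pv[15]
    gamma_s, delta_m = pv[16], pv[17]
    K_hill, h_hill, w_cross = pv[18], pv[19], pv[20]
    N_fak, N_fyn = pv[21], pv[22]
    M_ref = pv[25]

    ng = grid.shape[0]
    cap = ev_times.shape[0]
    gi = 0
    t = 0.0
    n_ev = 0
    a = np.empty(11, dtype=np.float64)

    for seg in range(edges.shape[0] - 1):
        t_next = edges[seg + 1]
        P = pvals[seg]
        if P <= 0.0:
            H = 0.0
        else:
            H = 1.0 / (1.0 + (K_hill / P) ** h_hill)
        while True:
            a[0] = y[0] * (k_f0 + k_fP * H) * (1.0 + w_cross * y[3] / N_fyn)
            a[1] = k_fd * y[1]
            a[2] = inhibition * y[2] * (k_y0 + k_yM * y[8] / M_ref + k_yP * H)
            a[3] = k_yd * y[3]
            a[4] = y[6] * (k_p0 + k_pF * y[1] / N_fak)
            a[5] = k_pd * y[7]
            a[6] = y[4] * (k_e0 + k_eY * y[3] / N_fyn)
            a[7] = k_ed * y[5]
            a[8] = k_s0 + k_sE * y[5] + k_sP * y[7]
            a[9] = gamma_s * y[9]
            a[10] = delta_m * y[8]
            a0 = 0.0
            for j in range(11):
                a0 += a[j]
            if a0 <= 0.0:
                t_new = t_next
                while gi < ng and grid[gi] < t_new:
                    for s in range(10):
                        grid_out[gi, s] = y[s]
                    gi += 1
                t = t_new
                break
            u1 = rng.random()
            tau = -math.log(1.0 - u1) / a0
            if t + tau >= t_next:
                # waiting time crosses the breakpoint: discard and restart
                while gi < ng and grid[gi] < t_next:
                    for s in range(10):
                        grid_out[gi, s] = y[s]
                    gi += 1
                t = t_next
                break
            t_new = t + tau
            while gi < ng and grid[gi] < t_new:
                for s in range(10):
                    grid_out[gi, s] = y[s]
                gi += 1
            thr = rng.random() * a0
            acc = 0.0
            r = 10
            for j in range(11):
                acc += a[j]
                if acc > thr:
                    r = j
                    break
            # apply stoichiometry
            if r == 0:
                y[0] -= 1; y[1] += 1
            elif r == 1:
                y[1] -= 1; y[0] += 1
            elif r == 2:
                y[2] -= 1; y[3] += 1
            elif r == 3:
                y[3] -= 1; y[2] += 1
            elif r == 4:
                y[6] -= 1; y[7] += 1
            elif r == 5:
                y[7] -= 1; y[6] += 1
            elif r == 6:
                y[4] -= 1; y[5] += 1
            elif r == 7:
                y[5] -= 1; y[4] += 1
            elif r == 8:
                y[9] += 1
            elif r == 9:
                y[9] -= 1
            else:
                y[8] -= 1
            t = t_new
            if record == 1:
                if n_ev >= cap:
                    return -1  # caller retries with a larger buffer
                ev_times[n_ev] = t_new
                ev_react[n_ev] = r
            n_ev += 1
    while gi < ng:
        for s in range(10):
            grid_out[gi, s] = y[s]
        gi += 1
    return n_ev


@dataclass
class Trajectory:
    """One exact SSA sample path.

    ``event_times``/``event_reactions`` are the full jump record (0-based
    reaction indices); ``event_states`` the state after each jump.  Grid
    states are sampled from the event path by last-value-carried-forward
    (right-continuous at jump times).
    """

    condition: Condition
    params: ParameterSet
    seed: int
    initial: np.ndarray
    event_times: np.ndarray
    event_reactions: np.ndarray
    grid_times: np.ndarray
    grid_states: np.ndarray

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def event_states(self) -> np.ndarray:
        if self.n_events == 0:
            return self.initial[None, :].copy()
        return self.initial[None, :] + np.cumsum(
            STOICHIOMETRY[self.event_reactions], axis=0)

    def species_mean(self, species: str) -> np.ndarray:
        """Grid-sampled copy numbers for one species (a single path)."""
        return self.grid_states[:, _SP_IDX[species]].astype(float)

    def final_state(self) -> NetworkState:
        return NetworkState(self.grid_states[-1],
                            time=float(self.grid_times[-1]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy grid samples: time, species, value, condition."""
        return _tidy(self.grid_times, self.grid_states.astype(float),
                     self.condition.name)


@dataclass
class EnsembleSummary:
    """Per-grid-point mean and variance over SSA replicates."""

    condition: Condition
    params: ParameterSet
    grid_times: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    n_reps: int
    master_seed: int

    def species_mean(self, species: str) -> np.ndarray:
        return self.mean[:, _SP_IDX[species]]

    def species_var(self, species: str) -> np.ndarray:
        return self.var[:, _SP_IDX[species]]

    def to_frame(self) -> pd.DataFrame:
        df = _tidy(self.grid_times, self.mean, self.condition.name)
        df["variance"] = _tidy(self.grid_times, self.var,
                               self.condition.name)["value"]
        df["n_reps"] = self.n_reps
        return df


@dataclass
class ODESolution:
    """Mean-field trajectory of expected copy numbers on the output grid."""

    condition: Condition
    params: ParameterSet
    grid_times: np.ndarray
    states: np.ndarray

    def species_mean(self, species: str) -> np.ndarray:
        return self.states[:, _SP_IDX[species]]

    def to_frame(self) -> pd.DataFrame:
        return _tidy(self.grid_times, self.states, self.condition.name)


def _tidy(times: np.ndarray, values: np.ndarray, condition: str) -> pd.DataFrame:
    long = pd.DataFrame(values, columns=list(SPECIES))
    long.insert(0, "time", times)
    out = long.melt(id_vars="time", var_name="species", value_name="value")
    out["condition"] = condition
    return out


def _run_kernel(condition: Condition, params: ParameterSet, t_end: float,
                grid: np.ndarray, seed, record: bool,
                initial: NetworkState | None = None):
    if initial is not None:
        initial.validate(params)
        y0 = initial.counts
    else:
        y0 = initial_state(condition, params).counts
    pv = params.pack()
    edges, pvals = _intervals(condition, t_end)
    grid_out = np.empty((len(grid), _N_SP), dtype=np.int64)
    cap = 1 << 14
    while True:
        y = y0.copy()
        rng = np.random.default_rng(seed)
        ev_times = np.empty(cap if record else 1, dtype=np.float64)
        ev_react = np.empty(cap if record else 1, dtype=np.int64)
        n_ev = _ssa_kernel(y, pv, edges, pvals, float(condition.inhibition),
                           grid, grid_out, ev_times, ev_react,
                           1 if record else 0, rng)
        if n_ev >= 0:
            return y0, grid_out, ev_times[:n_ev] if record else None, \
                ev_react[:n_ev] if record else None, n_ev
        cap *= 2


def simulate_ssa(condition: Condition, params: ParameterSet,
                 t_end: float = 48.0, seed: int | np.random.SeedSequence = 0,
                 grid_step: float = 0.5,
                 initial: NetworkState | None = None) -> Trajectory:
    """One exact SSA path under a treatment condition.

    The trajectory starts from the condition's pre-stimulus steady state
    (rounded to integers) with the MGF bolus added at t=0, unless an
    explicit ``initial`` state is given.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0 h, got {t_end!r}")
    grid = default_grid(t_end, grid_step)
    y0, grid_out, ev_t, ev_r, n_ev = _run_kernel(
        condition, params, t_end, grid, seed, record=True, initial=initial)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else -1
    return Trajectory(condition=condition, params=params, seed=int(seed_repr),
                      initial=y0, event_times=ev_t, event_reactions=ev_r,
                      grid_times=grid, grid_states=grid_out)


def run_ensemble(condition: Condition, params: ParameterSet,
                 n_reps: int = 200, t_end: float = 48.0, seed: int = 0,
                 grid_step: float = 0.5,
                 initial: NetworkState | None = None) -> EnsembleSummary:
    """SSA ensemble: per-grid-point mean and (unbiased) variance.

    Replicate ``i`` uses the generator seeded with
    ``SeedSequence(seed).spawn(n_reps)[i]``; identical inputs therefore give
    bit-identical summaries.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps!r}")
    grid = default_grid(t_end, grid_step)
    ssum = np.zeros((len(grid), _N_SP))
    ssq = np.zeros_like(ssum)
    for child in replicate_seeds(seed, n_reps):
        _, grid_out, _, _, _ = _run_kernel(condition, params, t_end, grid,
                                           child, record=False,
                                           initial=initial)
        g = grid_out.astype(np.float64)
        ssum += g
        ssq += g * g
    mean = ssum / n_reps
    if n_reps > 1:
        var = np.maximum(ssq - n_reps * mean * mean, 0.0) / (n_reps - 1)
    else:
        var = np.zeros_like(mean)
    return EnsembleSummary(condition=condition, params=params,
                           grid_times=grid, mean=mean, var=var,
                           n_reps=n_reps, master_seed=int(seed))


def _rhs(t, u, p: ParameterSet, H: float, inhibition: float):
    fak_a, fyn_a, erk_a, p38_a, mgf, scx = u
    dfak = ((p.N_fak - fak_a) * (p.k_f0 + p.k_fP * H)
            * (1.0 + p.w_cross * fyn_a / p.N_fyn) - p.k_fd * fak_a)
    dfyn = (inhibition * (p.N_fyn - fyn_a)
            * (p.k_y0 + p.k_yM * mgf / p.M_ref + p.k_yP * H)
            - p.k_yd * fyn_a)
    derk = ((p.N_erk - erk_a) * (p.k_e0 + p.k_eY * fyn_a / p.N_fyn)
            - p.k_ed * erk_a)
    dp38 = ((p.N_p38 - p38_a) * (p.k_p0 + p.k_pF * fak_a / p.N_fak)
            - p.k_pd * p38_a)
    dmgf = -p.delta_m * mgf
    dscx = p.k_s0 + p.k_sE * erk_a + p.k_sP * p38_a - p.gamma_s * scx
    return [dfak, dfyn, derk, dp38, dmgf, dscx]


def simulate_ode(condition: Condition, params: ParameterSet,
                 t_end: float = 48.0, grid: Sequence[float] | None = None,
                 grid_step: float = 0.5, rtol: float = 1e-9,
                 atol: float = 1e-9,
                 initial: NetworkState | None = None) -> ODESolution:
    """Mean-field trajectory: the same rate laws with continuous counts.

    Conservation of each kinase pool is exact by construction (the active
    fraction is the integrated variable).  The integrator restarts at each
    protocol breakpoint so the piecewise-constant pressure input is handled
    without smoothing.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0 h, got {t_end!r}")
    grid = np.asarray(grid, dtype=float) if grid is not None \
        else default_grid(t_end, grid_step)
    if initial is not None:
        initial.validate(params)
        c = initial.counts.astype(float)
        u = np.array([c[_SP_IDX["FAK_a"]], c[_SP_IDX["FYN_a"]],
                      c[_SP_IDX["ERK_a"]], c[_SP_IDX["P38_a"]],
                      c[_SP_IDX["MGF"]], c[_SP_IDX["SCX"]]])
    else:
        ss = steady_state(params, condition.inhibition)
        u = np.array([ss["FAK_a"], ss["FYN_a"], ss["ERK_a"], ss["P38_a"],
                      float(condition.mgf_initial), ss["SCX"]])
    edges, pvals = _intervals(condition, t_end)
    from .model import hill_response

    out = np.empty((len(grid), 6))
    done = np.zeros(len(grid), dtype=bool)
    for seg in range(len(edges) - 1):
        t0, t1 = edges[seg], edges[seg + 1]
        H = hill_response(pvals[seg], params.K_hill, params.h_hill)
        sel = (~done) & (grid >= t0) & (grid <= t1 if seg == len(edges) - 2
                                        else grid < t1)
        t_eval = grid[sel]
        t_full = np.union1d(t_eval, [t1])
        sol = solve_ivp(_rhs, (t0, t1), u, method="LSODA", t_eval=t_full,
                        args=(params, H, condition.inhibition),
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise RuntimeError(
                f"mean-field integration failed on [{t0}, {t1}] h for "
                f"condition {condition.name!r}: {sol.message}; "
                f"params={params.to_dict()}")
        if len(t_eval):
            cols = np.searchsorted(sol.t, t_eval)
            out[sel] = sol.y[:, cols].T
            done |= sel
        u = sol.y[:, -1]

    states = np.empty((len(grid), _N_SP))
    fak_a, fyn_a, erk_a, p38_a, mgf, scx = out.T
    states[:, _SP_IDX["FAK_a"]] = fak_a
    states[:, _SP_IDX["FAK_i"]] = params.N_fak - fak_a
    states[:, _SP_IDX["FYN_a"]] = fyn_a
    states[:, _SP_IDX["FYN_i"]] = params.N_fyn - fyn_a
    states[:, _SP_IDX["ERK_a"]] = erk_a
    states[:, _SP_IDX["ERK_i"]] = params.N_erk - erk_a
    states[:, _SP_IDX["P38_a"]] = p38_a
    states[:, _SP_IDX["P38_i"]] = params.N_p38 - p38_a
    states[:, _SP_IDX["MGF"]] = mgf
    states[:, _SP_IDX["SCX"]] = scx
    return ODESolution(condition=condition, params=params,
                       grid_times=grid, states=states)
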