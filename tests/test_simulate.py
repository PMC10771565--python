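"""SSA engine and mean-field oracle: exactness, determinism, analytic
stationary behaviour."""

import numpy as np
import pytest
from scipy import stats

from mechanoscx import (Condition, run_ensemble, simulate_ode, simulate_ssa,
                        replicate_seeds)
from mechanoscx.model import SPECIES
from mechanoscx.simulate import default_grid

from conftest import SP_IDX, make_state


class TestSSABasics:
    def test_frozen_system_never_fires(self, birth_death, control):
        frozen = birth_death.replace(k_s0=0.0, gamma_s=0.0)
        traj = simulate_ssa(control, frozen, t_end=10.0, seed=3)
        assert traj.n_events == 0
        assert np.all(traj.grid_states == traj.grid_states[0])

    def test_determinism_same_seed(self, defaults, pressure_mgf):
        a = simulate_ssa(pressure_mgf, defaults, t_end=12.0, seed=42)
        b = simulate_ssa(pressure_mgf, defaults, t_end=12.0, seed=42)
        assert np.array_equal(a.event_times, b.event_times)
        assert np.array_equal(a.event_reactions, b.event_reactions)
        assert np.array_equal(a.grid_states, b.grid_states)

    def test_different_seeds_differ(self, defaults, pressure_mgf):
        a = simulate_ssa(pressure_mgf, defaults, t_end=12.0, seed=1)
        b = simulate_ssa(pressure_mgf, defaults, t_end=12.0, seed=2)
        assert not np.array_equal(a.event_times, b.event_times)

    def test_conservation_and_nonnegativity_along_path(self, defaults,
                                                       pressure_mgf):
        traj = simulate_ssa(pressure_mgf, defaults, t_end=48.0, seed=7)
        states = traj.event_states
        assert np.all(states >= 0)
        for pool in ("FAK", "FYN", "ERK", "P38"):
            tot = states[:, SP_IDX[f"{pool}_i"]] + states[:, SP_IDX[f"{pool}_a"]]
            assert np.all(tot == 1000)
        assert np.all(np.diff(traj.event_times) >= 0)

    def test_grid_is_lvcf_of_event_path(self, birth_death, control):
        traj = simulate_ssa(control, birth_death, t_end=5.0, seed=11)
        # reconstruct the grid independently from the event record
        states = traj.event_states
        for gi, t in enumerate(traj.grid_times):
            k = np.searchsorted(traj.event_times, t, side="right") - 1
            expected = traj.initial if k < 0 else states[k]
            assert np.array_equal(traj.grid_states[gi], expected)

    def test_birth_death_time_average(self, birth_death, control):
        # stationary mean k_s0/gamma_s = 100; grid average over a long run
        traj = simulate_ssa(control, birth_death, t_end=400.0, seed=5)
        scx = traj.species_mean("SCX")
        # integrated autocorrelation time ~ 2/gamma -> effective n
        n_eff = 400.0 * 0.5 / 2.0
        se = np.sqrt(100.0 / n_eff)
        assert abs(scx.mean() - 100.0) < 3 * se


class TestEnsemble:
    def test_single_replicate_equals_trajectory(self, birth_death, control):
        ens = run_ensemble(control, birth_death, n_reps=1, t_end=10.0, seed=9)
        child = replicate_seeds(9, 1)[0]
        traj = simulate_ssa(control, birth_death, t_end=10.0, seed=child)
        assert np.array_equal(ens.mean, traj.grid_states.astype(float))
        assert np.all(ens.var == 0.0)

    def test_master_seed_reproducibility(self, defaults, pressure_mgf):
        a = run_ensemble(pressure_mgf, defaults, n_reps=20, t_end=12.0, seed=4)
        b = run_ensemble(pressure_mgf, defaults, n_reps=20, t_end=12.0, seed=4)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.var, b.var)

    def test_stationary_poisson_mean_variance(self, birth_death, control):
        # at stationarity SCX ~ Poisson(100): across-replicate variance
        # should match the mean within chi-square bounds
        n = 300
        ens = run_ensemble(control, birth_death, n_reps=n, t_end=10.0, seed=8)
        mean_T = ens.species_mean("SCX")[-1]
        var_T = ens.species_var("SCX")[-1]
        se_mean = np.sqrt(100.0 / n)
        assert abs(mean_T - 100.0) < 3 * se_mean
        lo = stats.chi2.ppf(0.0005, n - 1) / (n - 1)
        hi = stats.chi2.ppf(0.9995, n - 1) / (n - 1)
        assert lo < var_T / 100.0 < hi

    def test_rejects_zero_replicates(self, birth_death, control):
        with pytest.raises(ValueError):
            run_ensemble(control, birth_death, n_reps=0, t_end=1.0, seed=0)


class TestODE:
    def test_all_rates_zero_constant(self, birth_death, control):
        frozen = birth_death.replace(k_s0=0.0, gamma_s=0.0)
        sol = simulate_ode(control, frozen, t_end=10.0)
        assert np.allclose(sol.states, sol.states[0])

    def test_birth_death_closed_form(self, birth_death, control):
        # SCX(t) = k_s0/g + (SCX0 - k_s0/g) exp(-g t), from SCX0 = 300
        init = make_state(SCX=300)
        sol = simulate_ode(control, birth_death, t_end=20.0, initial=init)
        t = sol.grid_times
        exact = 100.0 + 200.0 * np.exp(-0.5 * t)
        rel = np.abs(sol.species_mean("SCX") - exact) / exact
        assert rel.max() < 1e-6

    def test_conservation_in_mean_field(self, defaults, pressure_mgf):
        sol = simulate_ode(pressure_mgf, defaults, t_end=48.0)
        for pool in ("FAK", "FYN", "ERK", "P38"):
            tot = (sol.states[:, SP_IDX[f"{pool}_i"]]
                   + sol.states[:, SP_IDX[f"{pool}_a"]])
            assert np.allclose(tot, 1000.0, rtol=1e-9)

    def test_breakpoint_restart_matches_piecewise_input(self, defaults):
        # MGF clearance is stimulus-independent: closed form across the
        # pressure breakpoint at t=1 h
        cond = Condition("pressure+MGF", 100,
                         protocol=__import__("mechanoscx").PressureProtocol(
                             ((0.0, 1.0, 120.0),)))
        sol = simulate_ode(cond, defaults, t_end=12.0)
        exact = 100.0 * np.exp(-defaults.delta_m * sol.grid_times)
        assert np.allclose(sol.species_mean("MGF"), exact, rtol=1e-6,
                           atol=1e-9)

    def test_invalid_horizon(self, defaults, control):
        with pytest.raises(ValueError):
            simulate_ode(control, defaults, t_end=0.0)


def test_default_grid_endpoints():
    g = default_grid(48.0, 0.5)
    assert g[0] == 0.0 and g[-1] == 48.0 and len(g) == 97
    with pytest.raises(ValueError):
        default_grid(48.3, 0.5)


def test_replicate_seed_derivation_is_stable():
    a = [s.generate_state(2) for s in replicate_seeds(123, 3)]
    b = [s.generate_state(2) for s in replicate_seeds(123, 3)]
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
    # children are distinct
    assert not np.array_equal(a[0], a[1])
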