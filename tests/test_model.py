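"""Network definition: Hill transduction, propensities, stoichiometry,
treatment conditions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanoscx import (Condition, ParameterSet, PressureProtocol,
                        apply_reaction, hill_response, propensities,
                        standard_conditions, steady_state)
from mechanoscx.model import (N_REACTIONS, REACTIONS, SPECIES, STOICHIOMETRY,
                              initial_state, network_table, pressure_at)

from conftest import SP_IDX, make_state


class TestHillResponse:
    @pytest.mark.parametrize("pressure,K,h,expected", [
        (0.0, 100.0, 2.0, 0.0),            # no stimulus, no drive
        (100.0, 100.0, 2.0, 0.5),          # half-saturation identity
        (50.0, 50.0, 7.0, 0.5),
        (200.0, 100.0, 2.0, 0.8),          # 4 / (1 + 4)
    ])
    def test_values(self, pressure, K, h, expected):
        assert hill_response(pressure, K, h) == pytest.approx(expected)

    @pytest.mark.parametrize("pressure,K,h", [(-1, 100, 2), (10, 0, 2),
                                              (10, -5, 2), (10, 100, 0.5)])
    def test_invalid_arguments(self, pressure, K, h):
        with pytest.raises(ValueError):
            hill_response(pressure, K, h)

    @given(st.floats(1e-2, 1e3), st.floats(1.0, 1e3), st.floats(1, 3))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_and_bounded(self, p, K, h):
        lo = hill_response(p, K, h)
        hi = hill_response(p * 1.5, K, h)
        assert 0 < lo < hi < 1


class TestPressureProtocol:
    def test_amplitude_inside_segment(self):
        proto = PressureProtocol(((0.0, 1.0, 120.0),))
        assert pressure_at(proto, 0.5) == 120.0

    def test_half_open_boundary(self):
        proto = PressureProtocol(((0.0, 1.0, 120.0),))
        assert pressure_at(proto, 1.0) == 0.0
        assert pressure_at(proto, 0.0) == 120.0

    def test_empty_protocol_is_zero(self):
        assert pressure_at(PressureProtocol(), 5.0) == 0.0

    def test_rejects_overlap_and_reversed(self):
        with pytest.raises(ValueError):
            PressureProtocol(((0.0, 2.0, 50.0), (1.0, 3.0, 80.0)))
        with pytest.raises(ValueError):
            PressureProtocol(((2.0, 1.0, 50.0),))

    @given(st.lists(st.tuples(st.floats(0, 40), st.floats(0.1, 5),
                              st.floats(0, 200)), max_size=4),
           st.floats(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_lookup_matches_linear_scan(self, raw, t):
        # build non-overlapping segments, then check containment semantics
        segs, cursor = [], 0.0
        for gap, width, amp in raw:
            start = cursor + gap
            segs.append((start, start + width, amp))
            cursor = start + width
        proto = PressureProtocol(tuple(segs))
        expected = next((a for s, e, a in segs if s <= t < e), 0.0)
        assert pressure_at(proto, t) == expected


class TestPropensities:
    def _params(self, **kw):
        base = dict(k_f0=0, k_fP=0, k_fd=0, k_y0=0, k_yM=0, k_yP=0, k_yd=0,
                    k_p0=0, k_pF=0, k_pd=0, k_e0=0, k_eY=0, k_ed=0,
                    k_s0=0, k_sE=0, k_sP=0, gamma_s=0, delta_m=0)
        base.update(kw)
        return ParameterSet(**base)

    def test_quiescent_network_only_scx_turnover(self):
        p = self._params(k_s0=7.0, gamma_s=0.5)
        a = propensities(make_state(SCX=10), p, pressure_now=0.0)
        assert a[8] == 7.0            # basal production
        assert a[9] == 5.0            # degradation of 10 copies
        assert np.all(a[[0, 1, 2, 3, 4, 5, 6, 7, 10]] == 0)

    def test_no_stimulus_no_basal_fak_silent(self):
        p = self._params(k_fP=1.0)
        a = propensities(make_state(), p, pressure_now=0.0)
        assert a[0] == 0.0

    def test_pressure_driven_fak_hand_value(self):
        # 1000 inactive FAK, H(100 kPa; K=100, h=2)=0.5, rate 1/h, no Fyn
        p = self._params(k_fP=1.0)
        a = propensities(make_state(), p, pressure_now=100.0)
        assert a[0] == pytest.approx(500.0)

    def test_crosstalk_scales_fak_activation(self):
        p = self._params(k_f0=0.1)
        base = propensities(make_state(), p, 0.0)[0]
        boosted = propensities(make_state(FYN_a=500), p, 0.0)[0]
        assert boosted == pytest.approx(base * 2.0)  # 1 + 2*0.5

    def test_inhibition_scales_fyn_only(self):
        p = self._params(k_y0=0.2, k_f0=0.1)
        full = propensities(make_state(MGF=50), p, 0.0, inhibition=1.0)
        tenth = propensities(make_state(MGF=50), p, 0.0, inhibition=0.1)
        assert tenth[2] == pytest.approx(0.1 * full[2])
        assert tenth[0] == full[0]

    def test_invalid_state_rejected(self):
        p = self._params()
        bad = make_state()
        bad.counts[SP_IDX["FAK_i"]] = 999  # breaks pool conservation
        with pytest.raises(ValueError):
            propensities(bad, p, 0.0)


class TestApplyReaction:
    def test_unit_conversion(self):
        s = make_state(FAK_a=0)
        s2 = apply_reaction(s, 0)
        assert s2["FAK_i"] == 999 and s2["FAK_a"] == 1

    def test_unit_decay(self):
        s = make_state(SCX=5)
        assert apply_reaction(s, 9)["SCX"] == 4

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            apply_reaction(make_state(SCX=0), 9)

    @given(st.integers(0, N_REACTIONS - 1), st.integers(0, 1000),
           st.integers(0, 200), st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_conversions_conserve_pools(self, r, fak_a, mgf, scx):
        s = make_state(FAK_a=fak_a, MGF=mgf, SCX=scx)
        src = REACTIONS[r][1]
        if src is not None and s[src] == 0:
            return
        s2 = apply_reaction(s, r)
        for pool in ("FAK", "FYN", "ERK", "P38"):
            assert s2[f"{pool}_i"] + s2[f"{pool}_a"] == 1000
        assert np.all(s2.counts >= 0)


class TestConditionsAndState:
    def test_standard_conditions_control(self):
        ctrl = standard_conditions()[0]
        assert ctrl.name == "control"
        assert ctrl.mgf_initial == 0
        assert ctrl.protocol.segments == ()
        assert ctrl.inhibition == 1.0

    def test_standard_conditions_pressure_mgf(self):
        cond = {c.name: c for c in standard_conditions()}["pressure+MGF"]
        assert cond.mgf_initial == 100
        assert cond.protocol.segments == ((0.0, 1.0, 120.0),)
        assert cond.inhibition == 1.0

    def test_pp2_variants_inhibited(self):
        conds = {c.name: c for c in standard_conditions()}
        assert len(conds) == 8
        assert conds["pressure+MGF+PP2"].inhibition == 0.1

    def test_initial_state_matches_steady_state(self, defaults):
        cond = Condition("MGF", 100)
        s = initial_state(cond, defaults)
        ss = steady_state(defaults)
        assert s["MGF"] == 100
        assert s["SCX"] == round(ss["SCX"])
        assert s["FAK_a"] == round(ss["FAK_a"])
        s.validate(defaults)

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            Condition("bad", -5)
        with pytest.raises(ValueError):
            Condition("bad", 0, inhibition=1.5)


def test_network_table_lists_all_reactions(defaults):
    df = network_table(defaults)
    assert len(df) == N_REACTIONS
    assert list(df["reaction"]) == [f"R{i + 1}" for i in range(N_REACTIONS)]
    # stoichiometry: conversions move one molecule, production/decay one
    assert np.all(np.abs(STOICHIOMETRY).sum(axis=1) <= 2)
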