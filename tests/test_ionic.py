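"""Membrane-model unit tests: gate curves, currents, single-cell
integration and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourcurrent.ionic import (RESTING_STATE, CellState, cell_rhs,
                               cell_step, gate_time_constants,
                               membrane_currents, simulate_cell,
                               steady_state_gates, theta)
from fourcurrent.params import builtin_set
from fourcurrent.protocols import measure_apd
from fourcurrent.stimulus import StimulusProtocol

from conftest import SET_NAMES


def test_heaviside_is_right_continuous():
    assert theta(0.0) == 1.0
    assert theta(-1e-15) == 0.0
    assert np.array_equal(theta(np.array([-1.0, 0.0, 2.0])), [0.0, 1.0, 1.0])


class TestSteadyStates:
    def test_below_threshold_lrd(self, lrd):
        g = steady_state_gates(0.0, lrd)
        assert g.m_inf == 0.0
        assert g.h_inf == 1.0 and g.f_inf == 1.0 and g.s_inf == 1.0
        assert g.d_inf == 0.0 and g.k_inf == 0.0 and g.r_inf == 0.0

    def test_d_gate_half_activation_at_V1(self, lrd):
        # V_1 > V_c for this set, so the threshold step is open
        assert steady_state_gates(lrd.V_1, lrd).d_inf == pytest.approx(0.5)

    def test_k_gate_linear_then_saturated(self, lrd):
        assert steady_state_gates(0.19, lrd).k_inf == pytest.approx(0.5)
        for v in (lrd.V_c, 0.5, 1.0, 1.4):
            assert steady_state_gates(v, lrd).k_inf == 1.0

    def test_fprime_near_one_at_rest(self, lrd):
        # frozen from an independent high-precision tanh evaluation
        assert steady_state_gates(0.0, lrd).fprime_inf == pytest.approx(
            0.99997333574529490, abs=1e-12)

    @given(v=st.floats(-0.5, 2.0))
    @settings(deadline=None, max_examples=60)
    def test_ranges(self, v):
        p = builtin_set("epi")
        g = steady_state_gates(v, p)
        for name in ("h_inf", "f_inf", "s_inf", "d_inf", "fprime_inf",
                     "r_inf"):
            assert 0.0 <= getattr(g, name) <= 1.0
        assert g.m_inf >= 0.0
        assert -1e-12 <= g.k_inf <= 1.0 or v < 0


class TestTimeConstants:
    def test_tnnp_below_all_thresholds(self, tnnp):
        tau = gate_time_constants(0.0, tnnp)
        assert tau == pytest.approx((90.5, 43.1, 2.2, 99.9))

    def test_tnnp_above_all_thresholds(self, tnnp):
        tau = gate_time_constants(1.0, tnnp)
        assert tau == pytest.approx((6.61, 181.0, 13.5, 4.34))

    @pytest.mark.parametrize("name", SET_NAMES)
    def test_discontinuity_at_Vc(self, name):
        p = builtin_set(name)
        eps = 1e-9
        tight = lambda x: pytest.approx(x, abs=1e-10)
        below = gate_time_constants(p.V_c - eps, p)
        at = gate_time_constants(p.V_c, p)
        assert below.tau_h == tight(p.tau_h_plus)
        assert at.tau_h == tight(p.tau_h_minus)  # theta(0)=1: jump on "-"
        assert below.tau_f == tight(p.tau_f_plus)
        assert at.tau_f == tight(p.tau_f_minus)

    @pytest.mark.parametrize("name", SET_NAMES)
    def test_r_switches_at_Vr_s_at_Vs(self, name):
        p = builtin_set(name)
        tight = lambda x: pytest.approx(x, abs=1e-10)
        assert gate_time_constants(p.V_r - 1e-9, p).tau_r == tight(p.tau_r_minus)
        assert gate_time_constants(p.V_r, p).tau_r == tight(p.tau_r_plus)
        assert gate_time_constants(p.V_s - 1e-9, p).tau_s == tight(p.tau_s_plus)
        assert gate_time_constants(p.V_s, p).tau_s == tight(p.tau_s_minus)


class TestCurrents:
    @pytest.mark.parametrize("name", SET_NAMES)
    def test_all_zero_at_rest(self, name):
        J = membrane_currents(RESTING_STATE, builtin_set(name))
        assert J == (0.0, 0.0, 0.0, 0.0)

    def test_fast_inward_hand_computed(self, lrd):
        state = CellState(V=1.0, h=1.0, f=1.0, r=0.0, s=1.0)
        J = membrane_currents(state, lrd)
        assert J.J_fi == pytest.approx(-1.24)  # -10*(1-0.38)*(1.2-1)

    def test_slow_outward_saturates(self, all_sets):
        for p in all_sets.values():
            state = CellState(V=p.V_c + 0.2, h=0.5, f=0.5, r=0.5, s=0.5)
            assert membrane_currents(state, p).J_so == pytest.approx(p.g_so)

    @given(v=st.floats(-0.2, 1.8), h=st.floats(0, 1), f=st.floats(0, 1),
           r=st.floats(0, 1), s=st.floats(0, 1),
           name=st.sampled_from(SET_NAMES))
    @settings(deadline=None, max_examples=120)
    def test_sign_structure(self, v, h, f, r, s, name):
        p = builtin_set(name)
        J = membrane_currents(CellState(v, h, f, r, s), p)
        assert J.J_si <= 0.0
        if v >= p.V_to:
            assert J.J_to >= 0.0 and J.J_so >= 0.0
        if v <= p.V_fi:
            assert J.J_fi <= 0.0


class TestCellDynamics:
    @pytest.mark.parametrize("name", SET_NAMES)
    def test_resting_state_is_fixed_point(self, name):
        d = cell_rhs(RESTING_STATE, 0.0, builtin_set(name))
        assert np.all(d.as_array() == 0.0)

    def test_stimulus_enters_depolarizing(self, epi):
        d = cell_rhs(RESTING_STATE, 0.5, epi)
        assert d.V == 0.5 and d.h == d.f == d.r == d.s == 0.0

    def test_fast_inward_vanishes_at_reversal(self, epi):
        state = CellState(V=epi.V_fi, h=0.7, f=0.5, r=0.2, s=0.8)
        assert membrane_currents(state, epi).J_fi == 0.0

    def test_step_rejects_bad_dt(self, epi):
        with pytest.raises(ValueError):
            cell_step(RESTING_STATE, 0.0, 0.0, epi)
        with pytest.raises(ValueError):
            cell_step(RESTING_STATE, -0.01, 0.0, epi)

    def test_step_euler_arithmetic(self, epi):
        out = cell_step(RESTING_STATE, 0.01, 0.5, epi)
        assert out.V == pytest.approx(0.005)
        assert (out.h, out.f, out.r, out.s) == (1.0, 1.0, 0.0, 1.0)

    def test_perturbations_return_to_rest(self, all_sets):
        for p in all_sets.values():
            start = CellState(V=0.01, h=0.99, f=1.0, r=0.01, s=1.0)
            tr = simulate_cell(p, StimulusProtocol.single(0.0),
                               duration=2000.0, initial_state=start,
                               record_gates=True)
            assert abs(tr.V[-1]) < 1e-4
            assert tr.gates["h"][-1] == pytest.approx(1.0, abs=1e-4)
            assert tr.gates["r"][-1] == pytest.approx(0.0, abs=1e-4)


class TestSimulateCell:
    def test_zero_stimulus_stays_at_rest(self, epi):
        tr = simulate_cell(epi, StimulusProtocol.single(0.0), duration=100.0)
        assert np.all(tr.V == 0.0)

    def test_subthreshold_response(self, epi, thresholds):
        tr = simulate_cell(epi, StimulusProtocol.single(
            0.2 * thresholds["epi"]), duration=100.0)
        assert tr.V.max() < epi.V_c

    def test_matches_explicit_euler_steps(self, lrd):
        """The compiled integrator is exactly repeated cell_step calls."""
        dt = 0.01
        protocol = StimulusProtocol.single(2.0, duration=1.0)
        tr = simulate_cell(lrd, protocol, dt=dt, duration=20.0,
                           sample_ms=dt, record_gates=True)
        state = RESTING_STATE
        stim = protocol.waveform(dt, 2000)
        for i in range(2000):
            state = cell_step(state, dt, stim[i], lrd)
        assert tr.V[-1] == pytest.approx(state.V, abs=1e-12)
        assert tr.gates["f"][-1] == pytest.approx(state.f, abs=1e-12)

    def test_gate_bounds_along_trajectory(self, all_sets, thresholds):
        # one full paced run per set; samples must stay within [0, 1]
        for name, p in all_sets.items():
            tr = simulate_cell(
                p, StimulusProtocol.pacing(1.5 * thresholds[name],
                                           bcl=500.0, n_beats=4),
                duration=2000.0, record_gates=True)
            for g in tr.gates.values():
                assert g.min() >= -1e-12 and g.max() <= 1.0 + 1e-12

    def test_current_decomposition_identity(self, epi, thresholds):
        """dV/dt + sum(J) - J_stim = 0 at every recorded step."""
        dt = 0.01
        protocol = StimulusProtocol.single(1.5 * thresholds["epi"])
        tr = simulate_cell(epi, protocol, dt=dt, duration=50.0,
                           sample_ms=dt, record_gates=True)
        stim = protocol.waveform(dt, tr.t.size - 1)
        for i in range(0, tr.t.size - 1, 7):
            state = CellState(tr.V[i], tr.gates["h"][i], tr.gates["f"][i],
                              tr.gates["r"][i], tr.gates["s"][i])
            dVdt = (tr.V[i + 1] - tr.V[i]) / dt
            total = membrane_currents(state, epi).total
            assert dVdt + total - stim[i] == pytest.approx(0.0, abs=1e-9)

    def test_repolarizing_above_fast_reversal(self, all_sets, thresholds):
        """Past the fast-current reversal potential the net unstimulated
        current is repolarizing along simulated trajectories."""
        for name, p in all_sets.items():
            tr = simulate_cell(
                p, StimulusProtocol.single(1.5 * thresholds[name]),
                duration=400.0, record_gates=True)
            sel = (tr.V > p.V_fi) & (tr.t > 2.0)
            for i in np.nonzero(sel)[0]:
                state = CellState(tr.V[i], tr.gates["h"][i],
                                  tr.gates["f"][i], tr.gates["r"][i],
                                  tr.gates["s"][i])
                assert cell_rhs(state, 0.0, p).V < 0.0

    def test_euler_convergence_of_apd(self, epi, thresholds):
        """APD converges ~first order under dt halving (< 1 ms change)."""
        apds = []
        for dt in (0.01, 0.005, 0.0025):
            tr = simulate_cell(
                epi, StimulusProtocol.pacing(1.5 * thresholds["epi"],
                                             bcl=600.0, n_beats=3),
                dt=dt, duration=1800.0, sample_ms=0.1)
            apds.append(measure_apd(tr)[-1].apd)
        d1, d2 = abs(apds[0] - apds[1]), abs(apds[1] - apds[2])
        assert d1 < 1.0
        assert d2 <= d1 + 0.05  # shrinking increments (first-order)

    def test_blowup_reports_time(self, epi):
        # a absurdly large dt destabilizes the gates -> clean error
        with pytest.raises((FloatingPointError, ValueError)):
            tr = simulate_cell(epi, StimulusProtocol.single(5.0), dt=50.0,
                               duration=5000.0, sample_ms=50.0)
            if np.all(np.isfinite(tr.V)):  # pragma: no cover
                raise ValueError("expected instability")
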