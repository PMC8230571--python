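"""Channel kinetics, steady states and the step integrator."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ca1ephys import (
    CellModel,
    Geometry,
    IhParams,
    PassiveParams,
    StimulusStep,
    cell_model_for_group,
    compute_holding_current,
    default_protocol,
    ih_steady_state,
    ih_time_constant,
    load_group_params,
    run_protocol,
    simulate_step,
    steady_state_voltage,
    with_params,
)
from ca1ephys.biophys import GROUP_LABELS, IntegrationError

AREA = 2.0e-4


def passive_cell(Rm=29400.0, e_pas=-88.28, gbar=0.0, **ih):
    return CellModel(PassiveParams(Rm=Rm, Cm=1.0, e_pas=e_pas),
                     IhParams(gbar=gbar, **ih), Geometry())


# ---------------------------------------------------------------------------
# activation curve
# ---------------------------------------------------------------------------

class TestSteadyState:
    def test_midpoint_is_exactly_half(self, wt1m):
        assert ih_steady_state(wt1m.ih.Vl_half, wt1m.ih) == pytest.approx(0.5, abs=0)

    def test_saturates_to_one_under_strong_hyperpolarization(self, wt1m):
        assert ih_steady_state(-1000.0, wt1m.ih) > 0.999999

    def test_value_matches_high_precision_logistic(self, wt1m):
        # independent oracle: 50-digit evaluation of the logistic
        import mpmath
        mpmath.mp.dps = 50
        x = -(mpmath.mpf(-120) - mpmath.mpf("-89.85")) / mpmath.mpf("-12.48")
        expected = 1 / (1 + mpmath.e ** x)
        assert ih_steady_state(-120.0, wt1m.ih) == pytest.approx(
            float(expected), abs=1e-12)
        assert float(expected) == pytest.approx(0.918, abs=5e-4)

    def test_monotone_decreasing_and_bounded(self, wt1m):
        v = np.linspace(-150.0, 50.0, 801)
        l = ih_steady_state(v, wt1m.ih)
        assert np.all(np.diff(l) < 0)
        assert np.all((l > 0) & (l < 1))

    def test_rejects_non_finite_voltage(self, wt1m):
        with pytest.raises(ValueError):
            ih_steady_state(float("nan"), wt1m.ih)


class TestTimeConstant:
    def test_closed_form_at_half_voltage(self, wt1m):
        # alpha = beta = 1 there, so tau = 1/(2 q_t a0t)
        qt = 4.5 ** ((34.0 - 33.0) / 10.0)
        expected = 1.0 / (2.0 * qt * 3.02e-3)
        assert expected == pytest.approx(142.4, abs=0.1)
        assert ih_time_constant(wt1m.ih.Vt_half, wt1m.ih, 34.0) == pytest.approx(
            expected, rel=1e-12)

    def test_positive_and_continuous_over_physiological_range(self, wt1m):
        v = np.arange(-150.0, 51.0, 1.0)
        tau = ih_time_constant(v, wt1m.ih)
        assert np.all(tau > 0)
        assert np.all(np.abs(np.diff(np.log(tau))) < 1.0)

    def test_extreme_voltages_do_not_overflow(self, wt1m):
        for v in (-1e6, 1e6):
            assert np.isfinite(ih_time_constant(v, wt1m.ih))
            assert ih_time_constant(v, wt1m.ih) > 0


# ---------------------------------------------------------------------------
# holding current and steady states
# ---------------------------------------------------------------------------

class TestHoldingCurrent:
    def test_zero_at_open_circuit_rest(self, wt1m):
        rest = steady_state_voltage(wt1m, 0.0)
        assert compute_holding_current(wt1m, rest) == pytest.approx(0.0, abs=1e-6)

    def test_pure_leak_follows_ohms_law(self):
        cell = passive_cell()
        expected = (-65.0 - (-88.28)) * AREA / 29400.0 * 1e9
        assert expected == pytest.approx(158.4, abs=0.05)
        assert compute_holding_current(cell, -65.0) == pytest.approx(expected)

    @pytest.mark.parametrize("label", GROUP_LABELS)
    def test_matches_bisection_oracle_on_steady_state(self, label):
        model = cell_model_for_group(label)
        hold = compute_holding_current(model, -65.0)

        def net_current(i_pA):  # independent statement of dV/dt = 0
            p, q = model.passive, model.ih
            v = -65.0
            l = 1.0 / (1.0 + np.exp(-(v - q.Vl_half) / q.kl))
            return (-(v - p.e_pas) / p.Rm - q.gbar * l * (v - q.E_h)
                    + i_pA * 1e-9 / AREA)

        oracle = brentq(net_current, -2000.0, 2000.0, xtol=1e-9)
        assert hold == pytest.approx(oracle, abs=1e-6)


class TestSteadyStateVoltage:
    @pytest.mark.parametrize("label", GROUP_LABELS)
    def test_end_of_step_voltage_reaches_algebraic_steady_state(self, label):
        model = cell_model_for_group(label)
        hold = compute_holding_current(model, -65.0)
        stim = StimulusStep(amplitude=-100.0, duration=2000.0)
        trace = simulate_step(model, stim, dt=0.025)
        v_end = trace.voltage[trace.sample_index(stim.onset + stim.duration) - 1]
        assert v_end == pytest.approx(steady_state_voltage(model, hold - 100.0),
                                      abs=0.1)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

class TestSimulateStep:
    def test_baseline_sits_at_holding_target(self, wt1m_sweep_m50):
        tr = wt1m_sweep_m50
        baseline = tr.voltage[:tr.sample_index(tr.stimulus.onset)]
        assert np.all(np.abs(baseline - (-65.0)) < 0.1)

    def test_pure_rc_relaxation_has_exact_time_constant(self):
        cell = passive_cell()
        tr = simulate_step(cell, StimulusStep(amplitude=-50.0), dt=0.025)
        i0 = tr.sample_index(100.0)
        seg = tr.voltage[i0:tr.sample_index(500.0)]
        t = np.arange(seg.size) * tr.dt
        v_inf = seg[-1]
        # log-linear fit of the mono-exponential approach (V decays onto v_inf)
        mask = (seg - v_inf) > 1e-3
        tau = -1.0 / np.polyfit(t[mask], np.log(seg[mask] - v_inf), 1)[0]
        assert tau == pytest.approx(29.4, rel=0.01)

    def test_sag_present_with_ih_and_absent_without(self, wt1m, wt1m_sweep_m50):
        tr = wt1m_sweep_m50
        seg = tr.voltage[tr.sample_index(100.0):tr.sample_index(500.0) + 1]
        sag = np.mean(seg[-len(seg) // 10:]) - seg.min()
        assert sag > 0.1
        tr0 = simulate_step(with_params(wt1m, gbar=0.0), StimulusStep(amplitude=-50.0))
        seg0 = tr0.voltage[tr0.sample_index(100.0):tr0.sample_index(500.0) + 1]
        assert np.mean(seg0[-len(seg0) // 10:]) - seg0.min() <= 0.05

    def test_sag_strictly_increases_with_peak_conductance(self, wt1m):
        sags = []
        for scale in (0.5, 1.0, 2.0):
            m = with_params(wt1m, gbar=wt1m.ih.gbar * scale)
            tr = simulate_step(m, StimulusStep(amplitude=-100.0))
            seg = tr.voltage[tr.sample_index(100.0):tr.sample_index(500.0) + 1]
            sags.append(np.mean(seg[-len(seg) // 10:]) - seg.min())
        assert sags[0] < sags[1] < sags[2]

    @pytest.mark.parametrize("label", ["WT-1m", "AD-10m"])
    def test_grid_refinement_changes_no_sample_beyond_tolerance(self, label):
        model = cell_model_for_group(label)
        stim = StimulusStep(amplitude=-150.0)
        a = simulate_step(model, stim, dt=0.05)
        b = simulate_step(model, stim, dt=0.025)
        assert np.max(np.abs(a.voltage - b.voltage[::2])) < 0.05

    def test_agrees_with_independent_stiff_solver(self, wt1m):
        """Dual-route check: our splitting scheme vs scipy LSODA."""
        model, stim = wt1m, StimulusStep(amplitude=-50.0)
        hold = compute_holding_current(model, -65.0)
        p, q = model.passive, model.ih

        def rhs(t, y):
            v, l = y
            linf = ih_steady_state(v, q)
            tau = ih_time_constant(v, q, model.temperature)
            i_inj = hold + (stim.amplitude if 100.0 <= t < 500.0 else 0.0)
            dv = (1000.0 * (-(v - p.e_pas) / p.Rm - q.gbar * l * (v - q.E_h))
                  + i_inj * 1e-6 / AREA) / p.Cm
            return [dv, (linf - l) / tau]

        t_eval = np.arange(0.0, 600.0 + 1e-9, 1.0)
        sol = solve_ivp(rhs, (0.0, 600.0), [-65.0, ih_steady_state(-65.0, q)],
                        method="LSODA", rtol=1e-9, atol=1e-9, t_eval=t_eval,
                        max_step=1.0)
        ours = simulate_step(model, stim, dt=0.025, hold_current_pA=hold)
        idx = (t_eval / 0.025).astype(int)
        assert np.max(np.abs(ours.voltage[idx] - sol.y[0])) < 0.05

    def test_blow_up_is_reported_not_propagated(self, wt1m):
        with pytest.raises(IntegrationError):
            simulate_step(wt1m, StimulusStep(amplitude=1e9))

    def test_rejects_too_coarse_grid(self, wt1m):
        with pytest.raises(ValueError):
            simulate_step(wt1m, StimulusStep(amplitude=-50.0), dt=0.5)


class TestProtocol:
    def test_default_protocol_has_thirteen_amplitudes(self):
        amps = [s.amplitude for s in default_protocol()]
        assert amps == list(range(-200, 401, 50))
        assert len(amps) == 13

    def test_empty_protocol_yields_empty_result(self, wt1m):
        assert run_protocol(wt1m, []) == []

    def test_all_sweeps_share_the_holding_baseline(self, wt1m):
        traces = run_protocol(wt1m, default_protocol([-100.0, -50.0, 50.0]),
                              dt=0.05)
        for tr in traces:
            baseline = tr.voltage[:tr.sample_index(100.0)]
            assert np.all(np.abs(baseline - (-65.0)) < 0.1)


class TestBallAndStick:
    def test_soma_baseline_holds_and_sag_appears(self, wt1m):
        model = dataclasses.replace(wt1m, geom=Geometry(mode="ball-and-stick"))
        tr = simulate_step(model, StimulusStep(amplitude=-50.0), dt=0.05)
        baseline = tr.voltage[:tr.sample_index(100.0)]
        assert np.all(np.abs(baseline - (-65.0)) < 0.1)
        seg = tr.voltage[tr.sample_index(100.0):tr.sample_index(500.0) + 1]
        assert np.mean(seg[-len(seg) // 10:]) - seg.min() > 0.05


class TestValidation:
    def test_parameter_invariants_are_enforced(self):
        with pytest.raises(ValueError):
            PassiveParams(Rm=-1.0)
        with pytest.raises(ValueError):
            PassiveParams(Rm=1e4, e_pas=-20.0)
        with pytest.raises(ValueError):
            IhParams(gbar=1e-5, kl=+5.0)
        with pytest.raises(ValueError):
            IhParams(gbar=1e-5, gmt=1.5)
        with pytest.raises(ValueError):
            Geometry(mode="torus")

    def test_group_table_round_trips_all_six_rows(self):
        table = load_group_params()
        assert set(table) == set(GROUP_LABELS)
        for label in GROUP_LABELS:
            m = cell_model_for_group(label)
            assert m.passive.Rm == table[label]["Rm"]
            assert m.ih.kl < 0
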