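"""Feature extraction: scalar features, spikes, and the feature table."""

import numpy as np
import pytest

from ca1ephys import (
    CellSweeps,
    SpikeDetectConfig,
    StimulusStep,
    Trace,
    cell_model_for_group,
    detect_spikes,
    extract_feature_table,
    first_ap_features,
    fit_membrane_tau,
    instantaneous_frequency,
    measure_sag,
    phase_plane,
    resting_membrane_potential,
    simulate_step,
    with_params,
)
from ca1ephys.features import (
    input_resistance_hold,
    input_resistance_step,
    isi_adaptation_index,
    mean_frequency,
)

DT = 0.025


def flat_trace(level=-72.0, amplitude=0.0, total=600.0, dt=DT, noise=None,
               rng=None):
    stim = StimulusStep(amplitude=amplitude, onset=100.0, duration=400.0,
                        holding_target=level)
    n = int(round(total / dt)) + 1
    v = np.full(n, level)
    if noise:
        v = v + rng.normal(0.0, noise, n)
    return Trace(dt=dt, voltage=v, stimulus=stim)


def synthetic_exponential(tau, v0=-65.0, v_ss=-75.0, dt=DT, sag_depth=1.0):
    """Exponential relaxation with a shallow late rebound to define a trough."""
    stim = StimulusStep(amplitude=-50.0, onset=100.0, duration=400.0)
    t = np.arange(int(round(600.0 / dt)) + 1) * dt
    v = np.full(t.size, v0)
    on, off = 100.0, 500.0
    in_step = (t >= on) & (t <= off)
    ts = t[in_step] - on
    v[in_step] = v_ss + (v0 - v_ss) * np.exp(-ts / tau)
    # gentle linear rebound over the second half of the step -> trough at mid
    second = in_step & (t - on > 200.0)
    v[second] += sag_depth * (t[second] - on - 200.0) / 200.0
    v[t > off] = v[np.flatnonzero(in_step)[-1]]
    return Trace(dt=dt, voltage=v, stimulus=stim)


class TestRMP:
    def test_constant_baseline_is_returned_exactly(self):
        assert resting_membrane_potential(flat_trace(-72.0)).value == -72.0

    def test_noisy_baseline_recovered_within_standard_error(self, rng):
        tr = flat_trace(-72.0, noise=0.5, rng=rng)
        res = resting_membrane_potential(tr)
        assert res.value == pytest.approx(-72.0, abs=0.05)
        assert not res.excluded

    def test_depolarized_cell_is_flagged_for_exclusion(self):
        assert resting_membrane_potential(flat_trace(-45.0)).excluded

    def test_short_baseline_gives_missing_value(self):
        tr = flat_trace()
        short = Trace(dt=1.0, voltage=tr.voltage[:50],
                      stimulus=StimulusStep(amplitude=0.0, onset=30.0,
                                            duration=10.0, pre=30.0))
        assert np.isnan(resting_membrane_potential(short).value)


class TestInputResistance:
    @pytest.mark.parametrize("rmp,i_hold,expected",
                             [(-75.0, 100.0, 100.0), (-70.0, 50.0, 100.0)])
    def test_holding_method_follows_ohms_law(self, rmp, i_hold, expected):
        assert input_resistance_hold(rmp, i_hold) == pytest.approx(expected)

    def test_zero_holding_current_is_undefined(self):
        assert np.isnan(input_resistance_hold(-75.0, 0.0))

    def test_step_method_recovers_a_perfectly_linear_cell(self):
        traces = []
        for amp in (-100.0, -50.0):
            stim = StimulusStep(amplitude=amp)
            n = int(round(600.0 / DT)) + 1
            v = np.full(n, -65.0)
            sl = slice(int(100 / DT), int(500 / DT) + 1)
            v[sl] = -65.0 + amp * 150.0 * 1e-3  # 150 MOhm
            traces.append(Trace(dt=DT, voltage=v, stimulus=stim))
        assert input_resistance_step(traces) == pytest.approx(150.0)

    def test_single_sweep_is_missing(self):
        tr = flat_trace(amplitude=-50.0)
        assert np.isnan(input_resistance_step([tr]))

    def test_two_methods_agree_on_a_model_cell(self, wt1m):
        from ca1ephys.biophys import compute_holding_current, steady_state_voltage
        hold = compute_holding_current(wt1m, -65.0)
        rest = steady_state_voltage(wt1m, 0.0)
        r_hold = input_resistance_hold(rest, hold)
        traces = [simulate_step(wt1m, StimulusStep(amplitude=a))
                  for a in (-100.0, -50.0)]
        r_step = input_resistance_step(traces)
        assert r_step == pytest.approx(r_hold, rel=0.10)

    def test_holding_method_matches_leak_resistance_without_ih(self, wt1m):
        from ca1ephys.biophys import compute_holding_current, steady_state_voltage
        cell = with_params(wt1m, gbar=0.0)
        hold = compute_holding_current(cell, -65.0)
        rest = steady_state_voltage(cell, 0.0)
        expected = cell.passive.Rm / cell.geom.area_cm2 / 1e6
        assert input_resistance_hold(rest, hold) == pytest.approx(expected,
                                                                  rel=0.02)


class TestMembraneTau:
    @pytest.mark.parametrize("tau", [5.0, 20.0, 50.0])
    def test_exact_exponential_recovered_to_a_tenth_percent(self, tau):
        tr = synthetic_exponential(tau)
        fit = fit_membrane_tau(tr)
        assert fit.converged
        assert fit.tau == pytest.approx(tau, rel=1e-3)

    def test_rc_cell_yields_rm_times_cm(self, wt1m):
        cell = with_params(wt1m, gbar=1e-12)  # vanishing I_h keeps a trough
        tr = simulate_step(cell, StimulusStep(amplitude=-50.0))
        fit = fit_membrane_tau(tr)
        assert fit.tau == pytest.approx(29.4, rel=0.01)

    def test_noise_robustness_over_many_seeds(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tr = synthetic_exponential(20.0)
            noisy = Trace(dt=tr.dt, voltage=tr.voltage
                          + rng.normal(0, 0.2, tr.voltage.size),
                          stimulus=tr.stimulus)
            errs.append(abs(fit_membrane_tau(noisy).tau - 20.0) / 20.0)
        assert np.median(errs) < 0.05

    def test_positive_step_is_rejected(self):
        assert not fit_membrane_tau(flat_trace(amplitude=50.0)).converged


class TestSag:
    def test_definition_on_a_constructed_trace(self):
        stim = StimulusStep(amplitude=-50.0)
        n = int(round(600.0 / DT)) + 1
        t = np.arange(n) * DT
        v = np.full(n, -65.0)
        in_step = (t >= 100.0) & (t <= 500.0)
        ts = t[in_step] - 100.0
        # smooth dip to -84 at 100 ms, relaxing to -80 by end of step
        v[in_step] = -80.0 - 4.0 * np.exp(-((ts - 100.0) / 60.0) ** 2)
        v[t > 500.0] = -65.0
        res = measure_sag(Trace(dt=DT, voltage=v, stimulus=stim))
        assert res.sag == pytest.approx(4.0, abs=0.05)

    def test_zero_for_a_passive_cell(self, wt1m):
        tr = simulate_step(with_params(wt1m, gbar=0.0),
                           StimulusStep(amplitude=-100.0))
        assert measure_sag(tr).sag <= 0.05

    def test_matches_dense_solver_trace(self, wt1m, wt1m_sweep_m50):
        """Oracle route: sag measured on an LSODA-integrated trace."""
        from scipy.integrate import solve_ivp
        from ca1ephys.biophys import (compute_holding_current, ih_steady_state,
                                      ih_time_constant)
        model = wt1m
        hold = compute_holding_current(model, -65.0)
        p, q = model.passive, model.ih

        def rhs(t, y):
            v, l = y
            i_inj = hold + (-50.0 if 100.0 <= t < 500.0 else 0.0)
            dv = (1000.0 * (-(v - p.e_pas) / p.Rm - q.gbar * l * (v - q.E_h))
                  + i_inj * 1e-6 / model.geom.area_cm2) / p.Cm
            return [dv, (ih_steady_state(v, q) - l) / ih_time_constant(v, q)]

        t_eval = np.arange(0.0, 600.0 + 1e-9, 0.025)
        sol = solve_ivp(rhs, (0.0, 600.0), [-65.0, ih_steady_state(-65.0, q)],
                        method="LSODA", rtol=1e-8, atol=1e-8, t_eval=t_eval,
                        max_step=1.0)
        oracle_trace = Trace(dt=0.025, voltage=sol.y[0],
                             stimulus=wt1m_sweep_m50.stimulus)
        assert measure_sag(wt1m_sweep_m50).sag == pytest.approx(
            measure_sag(oracle_trace).sag, abs=0.02)


class TestSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert detect_spikes(flat_trace(-65.0)).count == 0

    def test_spliced_templates_detected_at_their_peaks(self):
        from ca1ephys.synth import APTemplate
        tpl = APTemplate()
        stim = StimulusStep(amplitude=100.0)
        n = int(round(600.0 / DT)) + 1
        v = np.full(n, -65.0)
        for pk in (120.0, 180.0):
            ipk = int(round(pk / DT))
            nr = int(round(tpl.rise_ms / DT))
            nf = int(round(tpl.fall_total_ms / DT))
            v[ipk - nr:ipk + 1] = np.linspace(tpl.onset_mV, tpl.peak_mV, nr + 1)
            v[ipk:ipk + nf + 1] = np.linspace(tpl.peak_mV,
                                              tpl.onset_mV - tpl.ahp_mV, nf + 1)
        train = detect_spikes(Trace(dt=DT, voltage=v, stimulus=stim))
        assert train.count == 2
        assert np.allclose(train.times_ms, [120.0, 180.0], atol=DT)

    def test_sinusoid_counts_upward_threshold_crossings(self):
        stim = StimulusStep(amplitude=100.0)
        t = np.arange(0, 600.0 + 1e-9, DT)
        v = -20.0 + 15.0 * np.sin(2 * np.pi * t / 200.0)
        train = detect_spikes(Trace(dt=DT, voltage=v, stimulus=stim))
        assert train.count == 3  # one upward -10 mV crossing per 200 ms cycle

    def test_truncated_final_spike_is_kept_and_flagged(self):
        stim = StimulusStep(amplitude=100.0)
        t = np.arange(0, 600.0 + 1e-9, DT)
        v = np.full(t.size, -65.0)
        v[-200:] = 0.0  # rises above threshold and never comes back
        train = detect_spikes(Trace(dt=DT, voltage=v, stimulus=stim))
        assert train.count == 1
        assert train.truncated_last


class TestFirstAP:
    def make_triangle(self, base_ms=2.0, rise_mV=80.0, onset_v=-60.0):
        stim = StimulusStep(amplitude=100.0)
        n = int(round(600.0 / DT)) + 1
        v = np.full(n, onset_v)
        ipk = int(round(200.0 / DT))
        half = int(round(base_ms / 2.0 / DT))
        v[ipk - half:ipk + 1] = np.linspace(onset_v, onset_v + rise_mV, half + 1)
        v[ipk:ipk + half + 1] = np.linspace(onset_v + rise_mV, onset_v, half + 1)
        return Trace(dt=DT, voltage=v, stimulus=stim)

    def test_symmetric_triangle_width_is_half_base(self):
        ap = first_ap_features(self.make_triangle())
        assert ap.width == pytest.approx(1.0, abs=DT)
        assert ap.amplitude == pytest.approx(80.0, abs=0.5)

    def test_amplitude_scaling_leaves_width_and_scales_dvdt(self):
        ap1 = first_ap_features(self.make_triangle(rise_mV=80.0))
        ap2 = first_ap_features(self.make_triangle(rise_mV=120.0))
        assert ap2.width == pytest.approx(ap1.width, abs=DT)
        assert ap2.max_dvdt == pytest.approx(1.5 * ap1.max_dvdt, rel=0.02)

    def test_no_spike_returns_none(self):
        assert first_ap_features(flat_trace(-65.0)) is None


class TestPhasePlane:
    def test_sine_wave_max_slope_is_amplitude_times_omega(self):
        stim = StimulusStep(amplitude=100.0)
        t = np.arange(0, 600.0 + 1e-9, DT)
        A, period = 30.0, 100.0
        omega = 2 * np.pi / period
        v = -20.0 + A * np.sin(omega * t)
        tr = Trace(dt=DT, voltage=v, stimulus=stim)
        _, dvdt = phase_plane(tr, window_ms=(-60.0, 60.0))
        assert dvdt.max() == pytest.approx(A * omega, rel=0.01)

    def test_max_dvdt_consistent_with_first_ap_feature(self, small_cohort):
        cell = small_cohort.cells[0]
        tr = cell.by_amplitude()[300.0]
        ap = first_ap_features(tr)
        _, dvdt = phase_plane(tr)
        assert dvdt.max() == pytest.approx(ap.max_dvdt, rel=1e-6)

    def test_requires_a_spike(self):
        with pytest.raises(ValueError):
            phase_plane(flat_trace(-65.0))


class TestFrequencies:
    def test_uniform_train_gives_uniform_frequency(self):
        times = 100.0 + 50.0 * np.arange(11)
        f = instantaneous_frequency(times)
        assert np.allclose(f, 20.0)

    def test_short_train_pads_with_missing(self):
        f = instantaneous_frequency(np.array([100.0, 120.0, 160.0]))
        assert f[0] == pytest.approx(50.0)
        assert f[1] == pytest.approx(25.0)
        assert np.all(np.isnan(f[2:]))

    def test_accelerating_isis_give_decreasing_frequency(self):
        isis = 10.0 + 2.0 * np.arange(1, 11)
        times = 100.0 + np.concatenate([[0.0], np.cumsum(isis)])
        f = instantaneous_frequency(times)
        assert np.all(np.diff(f) < 0)

    def test_mean_frequency_and_adaptation_index(self):
        times = 100.0 + 50.0 * np.arange(4)
        assert mean_frequency(times, 400.0) == pytest.approx(10.0)
        assert isi_adaptation_index(times) == pytest.approx(0.0)
        assert np.isnan(isi_adaptation_index(times[:2]))


class TestFeatureTable:
    def test_two_cells_give_two_complete_rows(self, small_cohort):
        cells = [c for c in small_cohort.cells if c.group_label == "WT-1m"][:2]
        df = extract_feature_table(cells)
        assert len(df) == 2
        for col in ("rmp", "rin_hold", "rin_step", "tau_-50", "sag_-200",
                    "spike_count_300", "ap_width_300", "f1_300"):
            assert df[col].notna().all(), col

    def test_cell_without_300pA_sweep_has_missing_frequencies(self, small_cohort):
        cell = small_cohort.cells[0]
        reduced = CellSweeps(cell.cell_id, cell.group_label,
                             [t for t in cell.traces
                              if t.stimulus.amplitude != 300.0],
                             cell.rmp_trace)
        df = extract_feature_table([reduced])
        assert df["f1_300"].isna().all()
        assert df["tau_-50"].notna().all()

    def test_extraction_is_deterministic(self, small_cohort):
        cells = small_cohort.cells[:3]
        a = extract_feature_table(cells)
        b = extract_feature_table(cells)
        assert a.equals(b)

    def test_empty_cell_is_skipped_with_warning(self):
        empty = CellSweeps("x", "WT-1m", [])
        with pytest.warns(UserWarning):
            df = extract_feature_table([empty])
        assert df.empty
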