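"""Unit and property tests for spike-waveform and excitability analysis."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obda import ephys, synth
from obda.ephys import (NoSpikeError, PhasePlane, VoltageSweep,
                        ap_waveform_metrics, count_spikes, firing_metrics,
                        phase_plane, smooth_trace, waveform_classify)


def _sweep(v, dt=5e-6):
    t = np.arange(len(v)) * dt
    return VoltageSweep(time_s=t, vm_mV=np.asarray(v, dtype=float),
                        sample_interval_s=dt)


def _analyze(cfg):
    sw = synth.gen_ap_sweep(cfg)
    sm = smooth_trace(sw)
    pp = phase_plane(sm)
    m = ap_waveform_metrics(sm, pp)
    return m, waveform_classify(pp, m)


class TestSmoothTrace:
    def test_constant_unchanged(self):
        sw = _sweep(np.full(100, -60.0))
        np.testing.assert_allclose(smooth_trace(sw).vm_mV, -60.0)

    def test_unit_impulse_spreads_to_one_twentieth(self):
        v = np.zeros(200)
        v[100] = 1.0
        sm = smooth_trace(_sweep(v)).vm_mV
        # interior plateau of exactly 20 samples at 1/20
        plateau = np.flatnonzero(np.isclose(sm, 1 / 20))
        assert len(plateau) == 20
        assert len(sm) == len(v)

    def test_window_duration_100_us_at_native_rate(self):
        assert ephys.SMOOTH_POINTS * 5e-6 == pytest.approx(100e-6)

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            smooth_trace(_sweep(np.zeros(10)))


class TestPhasePlane:
    def test_linear_ramp_unit_check(self):
        # 1 mV/ms ramp: dV/dt must be 1 mV/ms == 1 V/s everywhere
        t = np.arange(1000) * 5e-6
        sw = VoltageSweep(time_s=t, vm_mV=t * 1e3, sample_interval_s=5e-6)
        pp = phase_plane(sw)
        np.testing.assert_allclose(pp.dvdt_V_per_s, 1.0, rtol=1e-9)

    def test_sine_max_derivative_closed_form(self):
        t = np.arange(20000) * 5e-6
        f = 200.0  # Hz
        sw = VoltageSweep(time_s=t, vm_mV=10 * np.sin(2 * np.pi * f * t),
                          sample_interval_s=5e-6)
        pp = phase_plane(sw)
        expected = 10 * 2 * np.pi * f / 1e3  # mV/ms == V/s
        assert np.max(np.abs(pp.dvdt_V_per_s)) == pytest.approx(expected,
                                                                rel=1e-4)

    def test_voltage_offset_shifts_plot_horizontally(self):
        cfg = synth.APSimConfig(kind="monophasic")
        sw = synth.gen_ap_sweep(cfg)
        pp1 = phase_plane(sw)
        sw2 = VoltageSweep(time_s=sw.time_s, vm_mV=sw.vm_mV + 7.0,
                           sample_interval_s=sw.sample_interval_s)
        pp2 = phase_plane(sw2)
        np.testing.assert_allclose(pp2.vm_mV, pp1.vm_mV + 7.0)
        np.testing.assert_allclose(pp2.dvdt_V_per_s, pp1.dvdt_V_per_s)


class TestAPMetrics:
    def test_logistic_threshold_matches_analytic_solution(self):
        # V(t) = -60 + 80*sigma((t-1ms)/0.1ms); dV/dt = 10 V/s where
        # 800*s*(1-s) = 10, analytically V = -58.987 mV
        t = np.arange(0, 3e-3, 5e-6)
        v = -60 + 80 / (1 + np.exp(-(t * 1e3 - 1) / 0.1))
        m = ap_waveform_metrics(VoltageSweep(time_s=t, vm_mV=v,
                                             sample_interval_s=5e-6))
        s = (1 - math.sqrt(1 - 4 * 10 / 800)) / 2
        assert m.threshold_mV == pytest.approx(-60 + 80 * s, abs=0.1)

    def test_subthreshold_trace_raises(self):
        # max dV/dt ~5 V/s: no spike
        t = np.arange(0, 10e-3, 5e-6)
        v = -60 + 5.0 * (t * 1e3)  # 5 mV/ms ramp, peaks below 0 anyway
        with pytest.raises(NoSpikeError):
            ap_waveform_metrics(VoltageSweep(time_s=t, vm_mV=v,
                                             sample_interval_s=5e-6))

    def test_default_monophasic_rapidness_in_population_band(self):
        m, _ = _analyze(synth.APSimConfig(kind="monophasic"))
        assert 3.0 <= m.onset_rapidness_per_ms <= 5.0

    def test_amplitude_and_ahp_consistency(self):
        m, _ = _analyze(synth.APSimConfig(kind="biphasic"))
        assert m.peak_mV > m.threshold_mV
        assert m.amplitude_mV == pytest.approx(m.peak_mV - m.threshold_mV)
        assert m.ahp_rel_threshold_mV == pytest.approx(
            m.threshold_mV - m.ahp_mV)
        assert m.width_ms > 0

    @given(delta=st.floats(-20.0, 20.0))
    def test_translation_invariance(self, delta):
        cfg = synth.APSimConfig(kind="monophasic")
        sw = smooth_trace(synth.gen_ap_sweep(cfg))
        m1 = ap_waveform_metrics(sw)
        sw2 = VoltageSweep(time_s=sw.time_s, vm_mV=sw.vm_mV + delta,
                           sample_interval_s=sw.sample_interval_s)
        m2 = ap_waveform_metrics(sw2)
        assert m2.threshold_mV == pytest.approx(m1.threshold_mV + delta, abs=1e-9)
        assert m2.peak_mV == pytest.approx(m1.peak_mV + delta, abs=1e-9)
        assert m2.ahp_mV == pytest.approx(m1.ahp_mV + delta, abs=1e-9)
        assert m2.width_ms == pytest.approx(m1.width_ms, rel=1e-9)
        assert m2.max_dvdt_V_per_s == pytest.approx(m1.max_dvdt_V_per_s)
        assert m2.onset_rapidness_per_ms == pytest.approx(
            m1.onset_rapidness_per_ms, rel=1e-6)

    def test_discretisation_robustness_at_double_sample_rate(self):
        metrics = []
        for dt, n_smooth in ((5e-6, 20), (2.5e-6, 40)):
            cfg = synth.APSimConfig(kind="monophasic", sample_interval_s=dt)
            sw = smooth_trace(synth.gen_ap_sweep(cfg), n_points=n_smooth)
            metrics.append(ap_waveform_metrics(sw))
        m1, m2 = metrics
        for attr in ("threshold_mV", "max_dvdt_V_per_s", "peak_mV",
                     "width_ms", "onset_rapidness_per_ms", "ahp_mV"):
            a, b = getattr(m1, attr), getattr(m2, attr)
            assert abs(b - a) / max(abs(a), 1e-9) < 0.01, attr


class TestWaveformClassify:
    def test_noiseless_exponential_segment_is_steep(self):
        # phase plane dV/dt = 2*exp(V/2): convex sharp onset
        v = np.linspace(-60, -40, 400)
        dvdt = 2.0 * np.exp((v - v[0]) / 2.0)
        pp = PhasePlane(vm_mV=v, dvdt_V_per_s=dvdt)
        wc = waveform_classify(pp, _metrics_stub(threshold_index=0))
        assert wc.label == "steep"
        assert wc.max_ratio > 3.0

    def test_noiseless_linear_segment_is_smooth(self):
        v = np.linspace(-60, -40, 400)
        dvdt = 1.0 + 5.0 * (v - v[0])
        pp = PhasePlane(vm_mV=v, dvdt_V_per_s=dvdt)
        wc = waveform_classify(pp, _metrics_stub(threshold_index=0))
        assert wc.label == "smooth"
        assert wc.max_ratio < 1.0

    @pytest.mark.parametrize("ratio,label", [
        (0.999, "smooth"), (1.0, "unclassified"), (2.0, "unclassified"),
        (3.0, "unclassified"), (3.001, "steep")])
    def test_label_thresholds_are_non_inclusive(self, ratio, label):
        assert ephys.label_from_ratio(ratio) == label

    def test_generated_waveforms_recover_ground_truth(self):
        rng = np.random.default_rng(1)
        for kind, expected in (("monophasic", "smooth"), ("biphasic", "steep")):
            hits = 0
            for _ in range(10):
                _, wc = _analyze(synth.sample_ap_config(kind, rng))
                hits += wc.label == expected
            assert hits >= 9, kind


def _metrics_stub(threshold_index):
    from obda.ephys import APMetrics
    return APMetrics(threshold_mV=0.0, threshold_index=threshold_index,
                     max_dvdt_V_per_s=0.0, peak_mV=1.0, amplitude_mV=1.0,
                     width_ms=1.0, onset_rapidness_per_ms=1.0, ahp_mV=0.0,
                     ahp_rel_threshold_mV=0.0)


class TestCountSpikes:
    def test_flat_trace(self):
        count, times = count_spikes(_sweep(np.full(100, -60.0)))
        assert count == 0 and len(times) == 0

    def test_three_well_separated_crossings(self):
        dt = 1e-4
        t = np.arange(0, 0.4, dt)
        v = np.full_like(t, -60.0)
        for tc in (0.05, 0.15, 0.25):
            v[(t >= tc) & (t < tc + 0.002)] = 20.0
        count, times = count_spikes(VoltageSweep(time_s=t, vm_mV=v,
                                                 sample_interval_s=dt))
        assert count == 3
        np.testing.assert_allclose(times, [0.05, 0.15, 0.25], atol=2 * dt)

    def test_refractory_rule_counts_jitter_once(self):
        dt = 1e-5
        t = np.arange(0, 0.01, dt)
        v = np.full_like(t, -60.0)
        # rapid oscillation around 0 mV within 1 ms
        burst = (t >= 0.003) & (t < 0.0038)
        v[burst] = 30.0 * np.sign(np.sin(2 * np.pi * 5000 * t[burst]))
        count, _ = count_spikes(VoltageSweep(time_s=t, vm_mV=v,
                                             sample_interval_s=dt))
        assert count == 1


class TestFiringMetrics:
    def _steps(self, rule):
        cfg = synth.StepProtocolConfig(count_rule=rule)
        return synth.gen_step_protocol(cfg, step_increment_pA=10.0,
                                       n_steps=4, capacitance_pF=10.0)

    def test_hand_regression_example(self):
        fm = firing_metrics(self._steps(lambda i: int(i) // 5))
        np.testing.assert_array_equal(fm.counts, [0, 2, 4, 6])
        np.testing.assert_allclose(fm.densities_pA_per_pF, [0, 1, 2, 3])
        np.testing.assert_allclose(fm.rates_hz, [0, 4, 8, 12])
        assert fm.rheobase_pA_per_pF == 1.0
        # three exactly collinear points: slope 4 to machine precision
        assert fm.io_slope_hz_per_pA_per_pF == pytest.approx(4.0, abs=1e-9)
        assert fm.max_spikes == 6

    def test_single_spiking_step_flagged(self):
        fm = firing_metrics(self._steps(lambda i: 1 if i >= 30 else 0))
        assert math.isnan(fm.io_slope_hz_per_pA_per_pF)
        assert any("IO slope" in f for f in fm.flags)

    def test_no_spiking_step_flagged(self):
        fm = firing_metrics(self._steps(lambda i: 0))
        assert math.isnan(fm.rheobase_pA_per_pF)

    def test_equal_isis_give_zero_cv(self):
        fm = firing_metrics(self._steps(lambda i: 5 if i >= 10 else 0))
        assert fm.isi_cv == pytest.approx(0.0, abs=1e-9)

    def test_exact_slope_on_constructed_linear_rates(self):
        fm = firing_metrics(self._steps(lambda i: int(i) // 5))
        dens = fm.densities_pA_per_pF[1:]
        rates = fm.rates_hz[1:]
        expected = np.polyfit(dens, rates, 1)[0]
        assert fm.io_slope_hz_per_pA_per_pF == expected
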