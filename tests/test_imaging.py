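"""Unit and property tests for the odour-response pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obda import imaging
from obda.imaging import (DffTrace, TrialTiming, bleach_correct, compute_dff,
                          derive_early_late_cutoff, detect_responses,
                          fit_decay, normalize_baseline, repeat_reliability,
                          subtract_background, tuning_index)

TIMING = TrialTiming()
T = TIMING.frame_times


def _dff(values, noise_sd, timing=TIMING):
    return DffTrace(values=np.asarray(values, dtype=float), f_baseline=1.0,
                    noise_sd=noise_sd, timing=timing)


def _boxcar_dff(height, start_s, stop_s, noise_sd=0.1, timing=TIMING):
    v = np.where((timing.frame_times >= start_s)
                 & (timing.frame_times < stop_s), height, 0.0)
    return _dff(v, noise_sd, timing)


class TestSubtractBackground:
    @pytest.mark.parametrize("trace,bg,expected", [
        (np.full(5, 10.0), 2.0, np.full(5, 8.0)),
        (np.full(5, 7.0), 0.0, np.full(5, 7.0)),
        (np.array([5.0, 6.0]), np.array([1.0, 2.0]), np.array([4.0, 4.0])),
    ])
    def test_elementwise(self, trace, bg, expected):
        np.testing.assert_allclose(subtract_background(trace, bg), expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros(5), np.zeros(4))


class TestBleachCorrect:
    def test_recovers_noiseless_exponential(self):
        trace = 2.0 * np.exp(-T / 10.0) + 1.0
        corrected, fit = bleach_correct(trace, TIMING)
        assert fit.a == pytest.approx(2.0, abs=1e-3)
        assert fit.tau_s == pytest.approx(10.0, abs=1e-3)
        assert fit.c == pytest.approx(1.0, abs=1e-3)
        np.testing.assert_allclose(corrected[TIMING.prestim_window], 1.0,
                                   atol=1e-6)

    def test_constant_trace_is_identity(self):
        trace = np.full(TIMING.n_frames, 5.0)
        corrected, fit = bleach_correct(trace, TIMING)
        assert abs(fit.a) < 1e-6
        np.testing.assert_allclose(corrected, trace, atol=1e-6)

    def test_brightening_negative_amplitude(self):
        trace = -0.5 * np.exp(-T / 5.0) + 2.0
        _, fit = bleach_correct(trace, TIMING)
        assert fit.a == pytest.approx(-0.5, abs=1e-3)
        assert fit.tau_s == pytest.approx(5.0, abs=0.01)


class TestComputeDff:
    def test_constant_trace(self):
        dff = compute_dff(np.full(TIMING.n_frames, 3.0), TIMING)
        np.testing.assert_allclose(dff.values, 0.0)
        assert dff.noise_sd == 0.0
        assert dff.f_baseline == 3.0

    def test_single_elevated_frame(self):
        trace = np.full(TIMING.n_frames, 2.0)
        trace[40] = 3.0   # outside the baseline window
        dff = compute_dff(trace, TIMING)
        assert dff.values[40] == pytest.approx(0.5)
        assert abs(np.mean(dff.values[TIMING.baseline_window])) < 1e-12

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.full(TIMING.n_frames, -1.0), TIMING)

    @given(g=st.floats(0.01, 100.0))
    def test_scale_invariance(self, g):
        rng = np.random.default_rng(7)
        trace = 100.0 + rng.normal(0, 3, TIMING.n_frames)
        ref = compute_dff(trace, TIMING)
        scaled = compute_dff(g * trace, TIMING)
        np.testing.assert_allclose(scaled.values, ref.values, atol=1e-9)
        assert scaled.noise_sd == pytest.approx(ref.noise_sd, abs=1e-12)


class TestDetectResponses:
    def test_flat_trace_not_significant(self):
        events = detect_responses(_dff(np.zeros(TIMING.n_frames), 0.1))
        assert all(not e.significant for e in events)

    def test_boxcar_event_matches_window_oracle(self):
        dff = _boxcar_dff(1.0, 8.0, 11.0)
        exc = [e for e in detect_responses(dff) if e.direction == "excitatory"][0]
        assert exc.significant
        assert exc.timing_class == "early"
        assert exc.peak_latency_s == pytest.approx(0.5)  # first frame of ties
        # independent brute-force window average around the detected peak
        tpk = TIMING.frame_times[exc.peak_frame]
        mask = (T >= tpk - 1.5) & (T < tpk + 1.5)
        assert exc.amplitude == pytest.approx(float(np.mean(dff.values[mask])))

    @pytest.mark.parametrize("mult,expected", [(3.0, True), (2.999, False)])
    def test_significance_boundary_is_inclusive_at_three(self, mult, expected):
        # constant trace: every amplitude window averages to exactly
        # mult*sigma (sigma chosen binary-exact so the boundary is sharp)
        sigma = 0.125
        dff = _dff(np.full(TIMING.n_frames, mult * sigma), noise_sd=sigma)
        exc = [e for e in detect_responses(dff) if e.direction == "excitatory"][0]
        assert exc.amplitude == mult * sigma
        assert exc.significant is expected

    def test_inhibitory_event_detected_independently(self):
        dff = _boxcar_dff(-1.0, 12.0, 15.0)
        inh = [e for e in detect_responses(dff) if e.direction == "inhibitory"][0]
        assert inh.significant and inh.amplitude < 0

    def test_early_late_partition_is_step_at_cutoff(self):
        for latency, expected in [(5.75, "early"), (6.0, "early"), (6.25, "late")]:
            v = np.zeros(TIMING.n_frames)
            v[TIMING.onset_frame + int(latency * 4)] = 1.0
            ev = [e for e in detect_responses(_dff(v, 0.01))
                  if e.direction == "excitatory"][0]
            assert ev.timing_class == expected, latency


class TestEarlyLateCutoff:
    def test_exhaustive_split_example(self):
        cutoff = derive_early_late_cutoff([1, 2, 2.5, 9, 10, 12])
        assert cutoff == pytest.approx((1.8333333 + 10.3333333) / 2, abs=1e-6)

    def test_two_point_symmetry(self):
        assert derive_early_late_cutoff([2.0, 10.0]) == pytest.approx(6.0)

    def test_identical_latencies_rejected(self):
        with pytest.raises(ValueError):
            derive_early_late_cutoff([4.0, 4.0, 4.0])

    def test_matches_sklearn_kmeans_on_bimodal_data(self):
        # independent cross-check of the exhaustive 1-D split
        from sklearn.cluster import KMeans
        rng = np.random.default_rng(5)
        lat = np.concatenate([rng.normal(2, 0.8, 120), rng.normal(10, 1, 80)])
        lat = np.clip(lat, 0.1, None)
        cutoff = derive_early_late_cutoff(lat)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(lat[:, None])
        km_cutoff = float(np.mean(np.sort(km.cluster_centers_.ravel())))
        assert cutoff == pytest.approx(km_cutoff, abs=1e-6)
        assert 4.0 <= cutoff <= 8.0


class TestRepeatReliability:
    def _repeats(self, latencies, heights, noise_sd=1.0):
        # plateau from the latency to sweep end: the peak window then sits
        # half on zeros, half on the plateau, so z = height / (2 * noise)
        out = []
        for lat, h in zip(latencies, heights):
            out.append(_boxcar_dff(h, TIMING.odor_onset_s + lat, 18.5,
                                   noise_sd=noise_sd))
        return out

    def test_identical_repeats_zero_cv(self):
        stats = repeat_reliability(self._repeats([2, 2, 2], [5, 5, 5]),
                                   "excitatory")
        assert stats.latency_cv == 0.0

    def test_latency_cv_hand_example(self):
        stats = repeat_reliability(self._repeats([2, 4, 6], [5, 5, 5]),
                                   "excitatory")
        assert stats.latency_cv == pytest.approx(0.5)  # sd 2 / mean 4

    def test_weakest_two_z_scores(self):
        stats = repeat_reliability(self._repeats([2, 2, 2], [12, 6, 6]),
                                   "excitatory")
        np.testing.assert_allclose(np.sort(stats.per_repeat_z), [3, 3, 6])
        assert stats.weakest2_z == pytest.approx(3.0, abs=1e-9)

    def test_requires_three_repeats(self):
        with pytest.raises(ValueError):
            repeat_reliability(self._repeats([2, 2], [5, 5]), "excitatory")


class TestFitDecay:
    def _exp_event(self, tau, peak_s=8.0, noise_sd=0.2, noise=None, seed=0):
        v = np.where(T >= peak_s, np.exp(-(T - peak_s) / tau), 0.0)
        v = np.where((T >= peak_s - 1.0) & (T < peak_s), T - peak_s + 1.0, v)
        if noise:
            v = v + np.random.default_rng(seed).normal(0, noise, len(v))
        dff = _dff(v, noise_sd)
        peak_frame = int(round(peak_s * 4))
        ev = imaging.ResponseEvent(
            direction="excitatory",
            peak_latency_s=peak_s - TIMING.odor_onset_s, peak_frame=peak_frame,
            amplitude=1.0, significant=True, timing_class="early")
        return dff, ev

    def test_exact_exponential_recovered(self):
        dff, ev = self._exp_event(5.0)
        est = fit_decay(dff, ev)
        assert est.eligible
        assert est.tau_partial_s == pytest.approx(5.0, abs=0.01)
        assert est.returned_to_baseline
        assert est.tau_full_s == pytest.approx(5.0, abs=0.01)

    def test_noisy_tau_recovery_median(self):
        errs = []
        for seed in range(100):
            dff, ev = self._exp_event(5.0, noise=0.05, seed=seed)
            est = fit_decay(dff, ev)
            errs.append(abs(est.tau_partial_s - 5.0))
        assert np.median(errs) < 0.5

    def test_late_peak_ineligible(self):
        dff, ev = self._exp_event(5.0, peak_s=16.5)
        est = fit_decay(dff, ev)
        assert not est.eligible and est.tau_partial_s is None


class TestCellSummaries:
    def test_tuning_index_counts(self):
        def ev(direction, cls, sig=True):
            return imaging.ResponseEvent(direction=direction, peak_latency_s=1,
                                         peak_frame=35, amplitude=1.0,
                                         significant=sig, timing_class=cls)
        events = {
            "o1": [ev("excitatory", "early")],
            "o2": [ev("excitatory", "early"), ev("inhibitory", "n/a")],
            "o3": [ev("excitatory", "late")],
            "o4": [ev("excitatory", "early", sig=False)],
        }
        assert tuning_index(events) == (2, 1, 1)
        assert tuning_index({}) == (0, 0, 0)

    def test_normalize_baseline_hand_example(self):
        import pandas as pd
        cells = pd.DataFrame({
            "size_class": ["small", "small", "big"],
            "baseline_f": [2.0, 4.0, 6.0]})
        out = normalize_baseline(cells)
        np.testing.assert_allclose(out["baseline_f_norm"],
                                   [2 / 3, 4 / 3, 2.0])
        small = out[out.size_class == "small"]
        assert small["baseline_f_norm"].mean() == pytest.approx(1.0)

    def test_normalize_requires_small_cells(self):
        import pandas as pd
        with pytest.raises(ValueError):
            normalize_baseline(pd.DataFrame({"size_class": ["big"],
                                             "baseline_f": [5.0]}))


class TestAnalyzeFov:
    def test_zero_event_zero_noise_fov(self):
        from obda import synth
        cfg = synth.GCaMPSimConfig(
            rng_seed=3, n_small_cells=2, n_big_cells=2,
            small_noise_sd=0.0, big_noise_sd=0.0,
            early=synth.EventTypeParams(0.0, (3, 12), (0.2, 3.5), 0.3, (1.5, 2.5)),
            late=synth.EventTypeParams(0.0, (3, 9), (3.0, 5.5), 2.0, (8, 11)),
            inhib=synth.EventTypeParams(0.0, (3, 8), (2.0, 5.0), 1.5, (8, 11)))
        sweeps, gt = synth.gen_gcamp_fov(cfg)
        assert len(gt) == 0
        cells, events = imaging.analyze_fov(sweeps)
        assert len(cells) == 4
        assert (cells[["ti_early", "ti_late", "ti_inhib"]] == 0).all().all()

    def test_structural_bounds(self):
        from obda import synth
        cfg = synth.GCaMPSimConfig(rng_seed=2, n_small_cells=3, n_big_cells=3)
        sweeps, _ = synth.gen_gcamp_fov(cfg)
        cells, events = imaging.analyze_fov(sweeps)
        assert len(cells) == 6
        assert len(events) <= 2 * 6 * cfg.n_odors
        assert set(cells.size_class) <= {"small", "big", "unclassified"}

    @given(g=st.floats(0.05, 20.0))
    def test_full_pipeline_scale_invariance(self, g):
        """Rescaling the raw traces by g > 0 changes no detected event."""
        from obda import synth
        cfg = synth.GCaMPSimConfig(rng_seed=4, n_small_cells=2, n_big_cells=1,
                                   n_odors=2, background_au=0.0)
        sweeps, _ = synth.gen_gcamp_fov(cfg)
        ss = sweeps[0]
        ref_events, _, ref_sigma, _ = imaging._analyze_sweepset(
            ss, 6.0, "per_repeat")
        scaled = imaging.SweepSet(
            cell_id=ss.cell_id, odor_id=ss.odor_id,
            repeats=[g * r for r in ss.repeats], timing=ss.timing,
            soma_area_um2=ss.soma_area_um2, background=None)
        ev2, _, sigma2, _ = imaging._analyze_sweepset(scaled, 6.0, "per_repeat")
        for a, b in zip(ref_events, ev2):
            assert a.significant == b.significant
            assert a.peak_latency_s == pytest.approx(b.peak_latency_s)
            assert a.amplitude == pytest.approx(b.amplitude, rel=1e-5, abs=1e-9)
        assert sigma2 == pytest.approx(ref_sigma, rel=1e-5)
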