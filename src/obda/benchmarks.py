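"""End-to-end validation benchmarks on synthetic data.

Each function runs a full slice of the package on generated inputs with
known ground truth and returns summary quantities: detection sensitivity
and false-positive rates for the imaging pipeline, decay-constant recovery,
waveform-classification accuracy, Sholl agreement with a brute-force
geometric oracle, and leave-one-out classification accuracy.  The
worked-example function reproduces the soma-size cutoffs, the AIS
prevalence estimate and the headline response-prevalence percentages from
their printed inputs.
"""

from __future__ import annotations

import logging
import numpy as np
from scipy import stats as sp_stats

from . import classify, ephys, imaging, morpho, synth

logger = logging.getLogger(__name__)

_TYPEMAP = {
    "early_exc": ("excitatory", "early"),
    "late_exc": ("excitatory", "late"),
    "inhib": ("inhibitory", None),
}


def worked_examples() -> dict[str, float]:
    """Deterministic worked examples from printed counts and statistics.

    * small/big soma-size cutoffs from mean -/+ 2 SD of the confirmed
      AIS-positive (136.7 +/- 33.2 um^2) and AIS-negative (65.6 +/- 16.6
      um^2) distributions,
    * AIS-positive prevalence from 297 identified cells over an estimated
      11,801 TH-positive cells,
    * percentage of AIS-positive cells among embryonically born neurons
      surviving to six months (71 of 78),
    * fractions of imaged cells with at least one early-excitatory response
      (631 of 1216) and with any response (817 of 1216).
    """
    return {
        "small_cutoff_um2": float(
            morpho.derive_size_cutoffs(136.7, 33.2, "minus")),
        "big_cutoff_um2": float(
            morpho.derive_size_cutoffs(65.6, 16.6, "plus")),
        "ais_prevalence_pct": morpho.prevalence_estimate(
            morpho.PrevalenceInputs(297, n_th_estimated=11801)),
        "e12_6mo_ais_positive_pct": morpho.prevalence_estimate(
            morpho.PrevalenceInputs(71, n_th_estimated=78)),
        "early_excitatory_cell_pct": morpho.prevalence_estimate(
            morpho.PrevalenceInputs(631, n_th_estimated=1216)),
        "any_response_cell_pct": morpho.prevalence_estimate(
            morpho.PrevalenceInputs(817, n_th_estimated=1216)),
    }


# ---------------------------------------------------------------------------
# imaging pipeline


def imaging_detection_benchmark(seeds=range(1, 6)) -> dict[str, float]:
    """Run the full pipeline on standard synthetic fields of view.

    Sensitivity is measured on injected events of amplitude >= 6x the
    baseline noise; the false-positive rate on cell x odour pairs with no
    injected event.  Latency error is relative to the analytic kernel peak.
    """
    sens_n = sens_hit = fp = fp_n = 0
    lat_errs: list[float] = []
    pairs = 0
    for seed in seeds:
        cfg = synth.GCaMPSimConfig(rng_seed=int(seed))
        sweeps, gt = synth.gen_gcamp_fov(cfg)
        pairs += len(sweeps)
        _, events = imaging.analyze_fov(sweeps)
        with_event = set(zip(gt.cell_id, gt.odor_id))
        for _, row in gt.iterrows():
            direction, tclass = _TYPEMAP[row.type]
            det = events[(events.cell_id == row.cell_id)
                         & (events.odor_id == row.odor_id)
                         & (events.direction == direction)]
            if tclass is not None:
                det = det[det.timing_class == tclass]
            if row.true_amplitude >= 6.0:
                sens_n += 1
                if len(det):
                    sens_hit += 1
                    lat_errs.append(abs(float(det.peak_latency_s.iloc[0])
                                        - row.true_latency_s))
        for ss in sweeps:
            if (ss.cell_id, ss.odor_id) not in with_event:
                fp_n += 1
                if len(events[(events.cell_id == ss.cell_id)
                              & (events.odor_id == ss.odor_id)]):
                    fp += 1
    return {
        "n_pairs": pairs,
        "n_strong_events": sens_n,
        "sensitivity_pct": 100.0 * sens_hit / max(sens_n, 1),
        "false_positive_pct": 100.0 * fp / max(fp_n, 1),
        "latency_median_error_s": float(np.median(lat_errs)) if lat_errs
        else float("nan"),
    }


def noiseless_latency_benchmark(seed: int = 11) -> dict[str, float]:
    """Peak-latency recovery on exact (noise-free) traces."""
    cfg = synth.GCaMPSimConfig(rng_seed=seed, small_noise_sd=0.0,
                               big_noise_sd=0.0, amp_scale_dff=0.05,
                               n_small_cells=10, n_big_cells=10)
    sweeps, gt = synth.gen_gcamp_fov(cfg)
    _, events = imaging.analyze_fov(sweeps)
    errs = []
    for _, row in gt.iterrows():
        direction, _ = _TYPEMAP[row.type]
        det = events[(events.cell_id == row.cell_id)
                     & (events.odor_id == row.odor_id)
                     & (events.direction == direction)]
        errs.append(abs(float(det.peak_latency_s.iloc[0]) - row.true_latency_s)
                    if len(det) else np.inf)
    return {"n_events": len(errs),
            "max_latency_error_s": float(np.max(errs)) if errs else 0.0}


def cutoff_benchmark(seeds=range(1, 6)) -> list[float]:
    """Early/late cutoffs derived from bimodal latencies (modes 2 s / 10 s)."""
    out = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        lat = np.concatenate([rng.normal(2.0, 0.8, 120),
                              rng.normal(10.0, 1.0, 80)])
        out.append(imaging.derive_early_late_cutoff(np.clip(lat, 0.1, None)))
    return out


def _exp_response_dff(timing, peak_s, tau, noise, rng):
    t = timing.frame_times
    v = np.where(t >= peak_s, np.exp(-(t - peak_s) / tau), 0.0)
    v = np.where((t >= peak_s - 2.0) & (t < peak_s), (t - peak_s + 2.0) / 2, v)
    v = v + rng.normal(0, noise, len(t))
    return imaging.DffTrace(values=v, f_baseline=1.0, noise_sd=noise,
                            timing=timing)


def decay_benchmark(seed: int = 0) -> dict[str, float]:
    """Decay-constant recovery and the partial-versus-full fit check.

    Part one: tau = 5 s responses at 5% noise on standard 18 s sweeps, 100
    repetitions; the partial (2.5 s) fit should recover tau to a median
    error below half a second.  Part two: late responses with tau drawn
    from 8-11 s on extended 60 s sweeps (long enough for the response to
    return to baseline so the full-profile fit exists); the partial - full
    difference should be centred on zero.
    """
    timing = imaging.TrialTiming()
    errs = []
    for k in range(100):
        rng = np.random.default_rng(seed * 1000 + k)
        dff = _exp_response_dff(timing, 8.0, 5.0, 0.05, rng)
        ev = [e for e in imaging.detect_responses(dff)
              if e.direction == "excitatory"][0]
        est = imaging.fit_decay(dff, ev)
        errs.append(abs(est.tau_partial_s - 5.0))

    long_timing = imaging.TrialTiming(sweep_duration_s=60.0)
    rng = np.random.default_rng(seed + 77)
    diffs = []
    while len(diffs) < 50:
        tau = rng.uniform(8.0, 11.0)
        dff = _exp_response_dff(long_timing, 15.0, tau, 0.05, rng)
        ev = [e for e in imaging.detect_responses(dff)
              if e.direction == "excitatory"][0]
        est = imaging.fit_decay(dff, ev)
        if est.eligible and est.tau_full_s is not None:
            diffs.append(est.tau_partial_s - est.tau_full_s)
    diffs_arr = np.asarray(diffs)
    return {
        "tau_median_abs_error_s": float(np.median(errs)),
        "partial_minus_full_mean_s": float(diffs_arr.mean()),
        "partial_minus_full_pvalue": float(
            sp_stats.ttest_1samp(diffs_arr, 0.0).pvalue),
    }


# ---------------------------------------------------------------------------
# electrophysiology


def ephys_classification_benchmark(seeds=range(1, 6),
                                   n_per_kind: int = 50) -> dict[str, float]:
    """Fraction of noiseless generated spikes classified to ground truth."""
    correct = {"monophasic": 0, "biphasic": 0}
    total = {"monophasic": 0, "biphasic": 0}
    rapidness_mono: list[float] = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        for kind, expected in (("monophasic", "smooth"), ("biphasic", "steep")):
            for _ in range(n_per_kind):
                cfg = synth.sample_ap_config(kind, rng)
                sw = ephys.smooth_trace(synth.gen_ap_sweep(cfg))
                pp = ephys.phase_plane(sw)
                m = ephys.ap_waveform_metrics(sw, pp)
                wc = ephys.waveform_classify(pp, m)
                total[kind] += 1
                correct[kind] += wc.label == expected
                if kind == "monophasic":
                    rapidness_mono.append(m.onset_rapidness_per_ms)
    return {
        "monophasic_smooth_pct": 100.0 * correct["monophasic"]
        / total["monophasic"],
        "biphasic_steep_pct": 100.0 * correct["biphasic"] / total["biphasic"],
        "onset_rapidness_monophasic_per_ms": float(np.mean(rapidness_mono)),
    }


def threshold_analytic_example() -> float:
    """Voltage threshold measured on the analytic logistic rise.

    V(t) = -60 + 80*sigma((t - 1 ms)/0.1 ms); the 10 V/s crossing solves
    800*s*(1 - s) = 10, i.e. V ~ -59.0 mV.
    """
    t = np.arange(0, 3e-3, 5e-6)
    v = -60 + 80 / (1 + np.exp(-(t * 1e3 - 1) / 0.1))
    m = ephys.ap_waveform_metrics(
        ephys.VoltageSweep(time_s=t, vm_mV=v, sample_interval_s=5e-6))
    return float(m.threshold_mV)


def io_slope_example() -> float:
    """IO slope on constructed exactly linear rate-density data."""
    cfg = synth.StepProtocolConfig(count_rule=lambda i: int(i) // 5)
    sweeps = synth.gen_step_protocol(cfg, 10.0, 4, capacitance_pF=10.0)
    return float(ephys.firing_metrics(sweeps).io_slope_hz_per_pA_per_pF)


# ---------------------------------------------------------------------------
# morphometry and classification


def _dense_radial_counts(tree, radii, samples_per_segment=2000):
    counts = np.zeros(len(radii), dtype=int)
    for b in tree.branches:
        pts = []
        for i in range(len(b) - 1):
            ts = np.linspace(0, 1, samples_per_segment, endpoint=False)
            pts.append(b[i][None, :] + ts[:, None] * (b[i + 1] - b[i])[None, :])
        pts.append(b[-1][None, :])
        path = np.concatenate(pts)
        r = np.linalg.norm(path - tree.soma_xy, axis=1)
        for j, radius in enumerate(radii):
            s = np.sign(r - radius)
            counts[j] += int(np.sum(s[:-1] * s[1:] < 0))
    return counts


def sholl_oracle_benchmark(seeds=range(8)) -> dict[str, float]:
    """Exact agreement between Sholl counts and dense radial sampling,
    plus exactness under a rigid rotation."""
    n_match = n_rot = 0
    seeds = list(seeds)
    for seed in seeds:
        tree = synth.gen_random_tree(rng_seed=int(seed))
        p = morpho.sholl_profile(tree)
        if np.array_equal(p.counts, _dense_radial_counts(tree, p.radii_um)):
            n_match += 1
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = morpho.NeuriteTree(soma_xy=rot @ tree.soma_xy,
                                   branches=[b @ rot.T for b in tree.branches])
        if np.array_equal(p.counts, morpho.sholl_profile(moved).counts):
            n_rot += 1
    return {"oracle_agreement_pct": 100.0 * n_match / len(seeds),
            "rotation_invariance_pct": 100.0 * n_rot / len(seeds)}


def classification_benchmark(seed: int = 1) -> dict[str, float]:
    """LOO accuracy and PC variance split on class-centred synthetic data."""
    table, labels = synth.gen_feature_table(seed=seed)
    res = classify.pca_kmeans_classify(table, labels, seed=seed)
    return {
        "loo_accuracy": float(res.loo_accuracy),
        "pc1_variance_pct": 100.0 * float(res.variance_fractions[0]),
        "pc2_variance_pct": 100.0 * float(res.variance_fractions[1]),
    }
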