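# obda

Analysis toolkit for distinguishing the two subtypes of olfactory-bulb (OB)
dopaminergic (DA) interneuron: large, embryonically born cells that carry an
axon initial segment (AIS), and small anaxonic cells produced throughout
life by adult neurogenesis.  The two populations differ in soma size,
dendritic spread, intrinsic excitability and odour-response properties, and
this package implements the complete quantitative stack used to tell them
apart:

* **imaging** — an odour-response pipeline for ROI-level GCaMP fluorescence
  traces: background subtraction, photobleach correction by a
  single-exponential fit `A·exp(−t/τ) + C` to the 7.5 s pre-stimulus
  baseline, Δf/f against the mean fluorescence *f* of the 3 s window before
  odour onset, event detection at the post-onset extremum with amplitude =
  mean Δf/f over a 3 s window centred on the peak, the `|amplitude| ≥ 3σ`
  significance rule (σ = SD of baseline Δf/f), an early/late excitatory
  split at 6 s (derivable from the data by exact 1-D two-means), per-type
  tuning indices (TI = number of odours of 8 with a significant response),
  repeat-reliability statistics (latency CV = sd/mean; mean of the two
  smallest amplitude z-scores), and decay-constant estimates from partial
  (2.5 s) or full post-peak exponential fits.
* **ephys** — spike-waveform analysis from current-clamp sweeps: 20-point
  (100 µs) sliding-mean smoothing, phase-plane plots (dV/dt vs V), voltage
  threshold at the first 10 V/s crossing, onset rapidness (phase-plane slope
  at threshold, ms⁻¹), width at half-height, AHP, and mono- vs biphasic
  classification by the fit-error ratio: linear vs exponential fits to
  initial phase-plane portions up to 40 % of max dV/dt, ratio > 3 = "steep"
  (biphasic, AIS-initiated), < 1 = "smooth" (monophasic).  Plus 500 ms
  current-step excitability: spike counts, rheobase (pA/pF), input–output
  slope (Hz per pA/pF) from rheobase to the maximum-count step, ISI CV.
* **morpho** — 2-D Sholl profiles from SWC reconstructions (first circle
  10 µm, 5 µm steps; exact segment–circle intersection counts), soma-size
  cutoffs from mean ± 2 SD (small < 70 µm², big > 99 µm², strict), and the
  AIS-prevalence estimate (AIS⁺ count over density × volume).
* **classify** — subtype classification from five variables (soma area,
  current threshold, onset rapidness, IO slope, max spike count):
  log-transform of onset rapidness, z-scoring, PCA, two-cluster k-means and
  a leave-one-out validation protocol, packaged as a scikit-learn style
  estimator (`SubtypeClassifier`).
* **synth** — generators for all four input kinds with known ground truth
  (injected GCaMP events, mono/biphasic spike shapes, neurite trees with
  analytic Sholl counts, bimodal soma-size mixtures, labelled feature
  tables), so every stage is testable at desk scale.

## Worked example

```python
import numpy as np
from obda import synth, imaging, ephys, classify, morpho

# simulate a field of view (12 cells x 8 odours x 3 repeats) and analyse it
cfg = synth.GCaMPSimConfig(rng_seed=1)
sweeps, truth = synth.gen_gcamp_fov(cfg)
cells, events = imaging.analyze_fov(sweeps)
print(cells[["cell_id", "size_class", "ti_early", "ti_late", "ti_inhib",
             "baseline_f_norm"]].head(4).to_string(index=False))
print(f"{len(events)} significant events; {len(truth)} injected")

# classify a simulated biphasic spike from its phase plane
sweep = synth.gen_ap_sweep(synth.APSimConfig(kind="biphasic"))
sm = ephys.smooth_trace(sweep)
pp = ephys.phase_plane(sm)
m = ephys.ap_waveform_metrics(sm, pp)
wc = ephys.waveform_classify(pp, m)
print(f"threshold {m.threshold_mV:.1f} mV, onset rapidness "
      f"{m.onset_rapidness_per_ms:.1f} /ms, max ratio {wc.max_ratio:.1f} -> {wc.label}")

# subtype classification with leave-one-out validation
table, labels = synth.gen_feature_table(seed=1)
res = classify.pca_kmeans_classify(table, labels, seed=0)
print(f"PC1 {100*res.variance_fractions[0]:.0f}%, PC2 "
      f"{100*res.variance_fractions[1]:.0f}%, LOO accuracy {res.loo_accuracy:.2f}")

# AIS prevalence from counted AIS+ cells and the estimated TH+ population
print(morpho.prevalence_estimate(morpho.PrevalenceInputs(297, n_th_estimated=11801)), "%")
```

prints

```
  cell_id size_class  ti_early  ti_late  ti_inhib  baseline_f_norm
small_000      small         0        0         0         1.029056
small_001      small         0        1         0         0.998504
small_002      small         0        1         1         1.040475
small_003      small         1        0         0         0.944244
17 significant events; 16 injected
threshold -71.3 mV, onset rapidness 12.1 /ms, max ratio 4.7 -> steep
PC1 86%, PC2 7%, LOO accuracy 1.00
2.5 %
```

The cell table gives each ROI's size class (small/big by the strict
70/99 µm² cutoffs), its tuning indices per response type, and its baseline
fluorescence normalised to the small-cell mean of the field of view.  The
spike is labelled "steep" because an exponential fits its perithreshold
phase plane more than three times better than a line — the signature of
spike initiation away from the recording site, at the AIS.  The two
synthetic feature clusters separate perfectly under leave-one-out k-means.

A thin CLI mirrors the library: `obda simulate gcamp|ephys|tree|features`,
`obda imaging-analyze`, `obda ephys-analyze`, `obda sholl`,
`obda prevalence`, `obda classify` (see `obda --help`).

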