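# Methods

This note documents the models behind each module, the parameter choices
that matter, the numerical decisions, and what the synthetic-data tests do
and do not establish about real recordings.

## Trial timing and conventions

Imaging sweeps follow the standard protocol: 4 Hz frames, 7.5 s baseline,
3 s odour delivery, 7.5 s post-odour acquisition (18 s, 72 frames; eight
odours, three repeats, 24 trials per field of view).  Frame timestamps are
taken at frame start.  The baseline-statistics window is the half-open
interval [onset − 3 s, onset) — exactly 12 frames at 4 Hz — and the peak
search runs from odour onset to sweep end.  The amplitude window is the
half-open 3 s interval centred on the peak frame, truncated at sweep edges
(late events are deliberately not excluded, only truncated).  Ties in the
peak search go to the earliest frame.  Sample standard deviations (n − 1)
are used throughout.

## Photobleach correction

`f(t) = A·exp(−t/τ) + C` is fitted by least squares to the 7.5 s
pre-stimulus baseline only, and the decaying component `A·exp(−t/τ)` is
subtracted over the whole sweep.  The offset C is retained: subtracting
the full fit would drive the baseline fluorescence *f* toward zero and
make Δf/f undefined.  A may be negative (brightening traces).

Numerically, a three-parameter exponential on a 7.5 s window is ill-posed
whenever τ greatly exceeds the window: the exponential becomes
indistinguishable from a constant-plus-slope, A and C trade off freely,
and the *extrapolated* component can be wildly wrong even when the
within-window fit is good.  The fit is therefore computed as a
deterministic grid over τ ∈ [0.25 s, 2 × baseline] (60 log-spaced values)
with (A, C) solved linearly at each τ, followed by a bounded nonlinear
polish; |A| is capped at four times the baseline peak-to-peak excursion.
On noiseless exponential input the fit is exact; a non-convergent fit
falls back to A = 0 with a logged warning.

## Event detection and significance

The mean response trace is formed by averaging the background-subtracted
raw repeats *first*; bleach correction and Δf/f follow on the mean trace.
The per-repeat path (each repeat corrected independently) supplies the
reliability statistics and the baseline noise.  Whether the significance
noise σ should come from the mean trace or from per-repeat SDs is
ambiguous; both are implemented (`noise_mode`), and the default averages
the per-repeat Δf/f SDs, applying that σ to the mean-trace amplitude.

An event is significant when its signed window-mean amplitude reaches
3 σ (inclusive at exactly 3.0).  One guard is added for degenerate input:
with σ exactly zero the rule would promote numerical residuals (~1e−16
Δf/f) to events, so significance additionally requires |amplitude| >
1e−9 Δf/f — far below any physical signal.

Significant excitatory events peaking at or before the cutoff (default
6 s after onset) are early, later ones late.  The cutoff can be re-derived
from data: the exact 1-D two-cluster solution (exhaustive split of the
sorted latencies minimising within-cluster sum of squares), with the
cutoff at the midpoint of the two cluster means.  On well-separated
bimodal latencies (modes 2 s / 10 s) the derived cutoff falls in [4, 8] s.

## Decay constants

The partial fit uses the peak frame plus the following 2.5 s (10 frames)
and the model `amp·exp(−(t − t_peak)/τ)`; the full fit uses the entire
post-peak profile and is reported only when the trace returns to within
one σ of baseline before sweep end.  Inhibitory events are fitted on the
negated trace; events peaking less than 2.5 s before sweep end are
ineligible.  Fits use bounded least squares with three τ starts.

The partial-vs-full validation (difference centred on zero) requires the
full fit to exist.  With 18 s sweeps, a late-peaking response with τ in
the 8–11 s range cannot return to baseline before sweep end, so the
package's validation benchmark uses extended 60 s synthetic sweeps for
this one property; τ recovery itself is benchmarked on standard 18 s
sweeps (τ = 5 s, 5 % noise, median |τ̂ − τ| < 0.5 s over 100 draws).

## Spike-waveform analysis

High-resolution sweeps (5 µs sample interval) are smoothed with a centred
20-point (100 µs) sliding mean (shrinking windows at the edges), then
differentiated by central differences; dV/dt is reported in V/s, which is
numerically identical to mV/ms.  Voltage threshold is Vm at the first
sample where dV/dt reaches 10 V/s, without interpolation.  Onset
rapidness is the slope (ms⁻¹) of a least-squares line through the
phase-plane points with dV/dt ∈ [10, 20] V/s; only the contiguous run
starting at threshold is used, so the somatic rise of a biphasic spike —
which re-enters the band after the first phase — cannot dilute the onset
slope.  Width is measured between the linearly interpolated crossings of
the voltage midway between threshold and peak; if the analysis window
contains no repolarising phase the width is NaN rather than an error.
The AHP is the post-peak minimum.

### Fit-error-ratio classification

Over windows of the phase plane starting at threshold and ending at
increasing fractions (0.05 … 0.40, sixteen steps) of the maximum dV/dt, a
line and an exponential `a·exp((V − V₀)/k) + c` are fitted; the fit error
is the RMS residual, the per-window ratio is linear error over exponential
error floored at 1e−3 × max dV/dt, and the maximum ratio over windows
labels the cell: > 3 steep (biphasic-like), < 1 smooth (monophasic-like),
otherwise unclassified (both criteria deliberately non-inclusive).

The exponential model is constrained to a > 0 and 0 < k ≤ the window's
voltage span.  This keeps it in the convex, sharp-onset family the method
is meant to detect: unconstrained, a three-parameter exponential nests
both convex and concave curves and fits any smooth noiseless segment
almost perfectly, which would inflate the ratio for *every* cell and
destroy the contrast between smooth and steep onsets.  Windows with fewer
than four points are skipped; duplicated window endpoints are evaluated
once; window evaluation stops early once a ratio exceeds 3, since only
the maximum matters.  Very long windows are subsampled to 120 points —
the fits need the curve's shape, not its sampling density.

### Excitability

Spikes are upward 0 mV crossings separated by at least 1 ms.  Counts per
500 ms step convert to rates over the step duration; rheobase is the
lowest current density (pA/pF) with at least one spike; the IO slope is
fitted from the rheobase step to the step of maximum count, because
monophasic-like cells plateau and a global fit would conflate slope and
saturation.  First-spike delay and ISI CV are measured at rheobase; steps
with too few spikes flag these as undefined rather than failing.

## Morphometry

Sholl analysis is two-dimensional, on the projection plane (z in SWC
input is discarded): circles at 10 + 5k µm out to the furthest node, and
counts from the exact segment–circle quadratic.  Roots are counted in the
half-open parameter interval (0, 1] per segment, so a polyline vertex
lying exactly on a circle is counted once (by its incoming segment), and
a tangential touch (double root) counts once.  The area under the Sholl
curve is the trapezoid over all computed radii, including trailing
zero-count circles inside the maximum tip radius — a deterministic
convention where the convention is otherwise open.  Counts agree exactly
with a brute-force oracle (dense radial-distance sampling, counting sign
changes of r(t) − R) on every generated fixture, and are exactly
invariant under rigid motions.

Soma-size cutoffs are mean ∓ 2 SD rounded to the nearest integer µm²
(136.7 − 2×33.2 → 70; 65.6 + 2×16.6 → 99); class assignment is strict
(< 70 small, > 99 big, everything else — including the boundaries —
unclassified and excluded from cell-type contrasts).  The AIS-prevalence
estimate divides the AIS-positive count by the TH-positive population,
either given directly or as density × volume, reported to one decimal as
a percentage.

## Subtype classification

Five variables enter: soma area (µm²), current threshold (pA/pF), onset
rapidness (ms⁻¹, log₁₀-transformed to normality), IO slope (Hz per
pA/pF), and maximum spike count.  Columns are z-scored before PCA and
before k-means: whether standardisation was applied upstream is unstated,
but with raw units PC1 would simply track soma area's scale, so
standardisation is the default (and configurable).  k-means (k = 2) runs
on the standardised five-variable matrix with seeded initialisation and
ten restarts, making results deterministic per seed; PCA scores serve
reporting and visualisation.  Cluster labels are aligned to reference
labels by majority match.  Leave-one-out validation refits k-means on
n − 1 rows, aligns on the training rows, assigns the held-out row to the
nearest centroid, and scores against the reference label (against the
full-fit labels when no references are given).  Outlier removal (|z| > 3,
strict, sample SD; zero-SD samples remove nothing) is provided as a
separate step.

## Synthetic data: what it emulates, and what it does not

The GCaMP generator writes raw traces as
`F·(1 + Σ kernels) + a·F·exp(−t/τ_b) + background + noise`: event kernels
are differences of exponentials, multiplicative on the baseline F so that
their amplitude lives naturally on the Δf/f scale; photobleaching is an
additive decaying exponential — exactly the model the correction stage
fits, so correction can be exact in the noiseless case; frame noise is
i.i.d. normal.  Ground-truth amplitudes are specified as multiples of the
baseline Δf/f noise SD *on the measurement scale*: the kernel is scaled so
the 3 s window mean around its analytic peak equals amplitude × σ, making
injected and detected amplitudes directly comparable.  Ground-truth
latency is the analytic kernel peak.  Early- and late-excitatory events
are mutually exclusive within a trial (the detector reports at most one
excitatory event per trial); inhibitory events are drawn independently, so
combined responses occur.

Defaults define the study conditions: 6 small + 6 big cells per field of
view; big cells brighter (baseline F 200 ± 20 vs 100 ± 10 a.u.) and less
noisy (4 vs 5 a.u.) than small cells; soma areas 140 ± 20 vs 55 ± 8 µm²
(component modes at the two population peaks); bleach 15 % of F with
τ_b = 8 s.  Per-trial event probabilities (early 0.09, late 0.028,
inhibitory 0.034) are back-calculated from the reported fractions of
cells with at least one response of each type over an eight-odour panel
(52 %, 20 %, 24 % via p = 1 − (1 − q)^8).  Late and inhibitory decay
constants are drawn from 8–11 s; early events decay in 1.5–2.5 s.  No
published amplitude distribution exists, so amplitude ranges (3–12 σ)
only aim to span weak-to-clear events; tests that quantify sensitivity
restrict to the ≥ 6 σ subset.

The spike generator builds analytic waveforms: a logistic somatic rise
(plus logistic repolarisation and a slow recovery component shaping the
AHP).  The biphasic kind prepends a small exponential-onset component —
membrane potential following −k·ln(1 − t/τ) up to a ~6 mV cap — whose
phase-plane trace grows exponentially with voltage.  This choice is
deliberate: a logistic foot is locally *linear* in the phase plane
(dV/dt ≈ v/s for small v), so a sum of two logistics produces a double
bump but can never be called steep by the fit-error ratio; the
exponential-onset form is the classic signature of a spike arriving from
a remote initiation site and is exactly what the ratio method detects.
Population simulations jitter amplitudes, slopes and resting potential by
±8 % multiplicative factors.  Step-protocol sweeps place stereotyped
spike templates according to a monotone-then-saturating count rule, so
rheobase, IO slope and saturation are known exactly.

None of the generators emulate optics, indicator binding kinetics,
movement artefacts, correlated noise, neuropil contamination, or
channel-level spike dynamics.  Passing the synthetic benchmarks therefore
establishes that the pipelines recover what they are defined to measure
under the stated noise model — not that those definitions are optimal for
any particular real recording.

## Problem sizes

The validation benchmarks run five fields of view (12 cells × 8 odours,
3 repeats; 480 cell×odour pairs), 100 decay draws plus 50 extended-sweep
draws, 50 spikes per class per seed over five seeds (500 classifications),
eight random trees for the Sholl oracle, and 26-cell feature tables —
sizes chosen so the whole suite completes in about a minute on one CPU
while keeping binomial uncertainty on the rate estimates a few percent.

## Known limitations

* The published population statistics (morphology and intrinsic-property
  tables, tuning-index and amplitude contrasts, the 92 %/7 % PCA variance
  split and 85 % LOO accuracy on the recorded cells) depend on raw
  recordings that are not available; the package validates the methods on
  synthetic ground truth instead and makes no claim to reproduce those
  numbers.
* The visual two-rater mono/biphasic call cannot be reproduced; only the
  quantitative fit-error-ratio route is implemented, and waveforms with
  maximum ratio in [1, 3] stay unclassified by design.
* Sholl analysis is strictly planar; three-dimensional arbours are
  analysed as their projections.
* The early/late cutoff derivation assumes a genuinely bimodal latency
  distribution; on unimodal data the two-means split still returns a
  number, and it is the caller's job to check separation.
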