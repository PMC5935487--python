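"""Odour-response analysis for ROI-level GCaMP fluorescence traces.

The pipeline goes from raw, background-subtracted fluorescence sweeps to
per-cell response events and summary statistics:

1. average the repeats of each cell x odour trial,
2. correct photobleaching by fitting ``A*exp(-t/tau) + C`` to the
   pre-stimulus baseline and subtracting the extrapolated decaying component,
3. convert to fractional fluorescence change (df/f) against the mean of the
   3 s window immediately preceding odour onset,
4. detect the post-onset extremum in each direction and call an event
   significant when its 3 s window-mean amplitude reaches three times the
   baseline noise (SD of baseline df/f),
5. class significant excitatory events as early or late against a latency
   cutoff (6 s by default, derivable from the data by 1-D two-means),
6. summarise each cell with per-type tuning indices, repeat-reliability
   statistics and response decay-constant estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "TrialTiming",
    "SweepSet",
    "BleachFit",
    "DffTrace",
    "ResponseEvent",
    "ReliabilityStats",
    "DecayEstimate",
    "CellProfile",
    "subtract_background",
    "bleach_correct",
    "compute_dff",
    "detect_responses",
    "derive_early_late_cutoff",
    "repeat_reliability",
    "fit_decay",
    "tuning_index",
    "normalize_baseline",
    "analyze_fov",
]

BASELINE_NOISE_WINDOW_S = 3.0  # window defining f and the baseline noise SD
AMPLITUDE_WINDOW_S = 3.0       # window centred on the peak for amplitudes
SIGNIFICANCE_MULTIPLE = 3.0    # |amplitude| >= 3 x baseline noise
DEFAULT_EARLY_LATE_CUTOFF_S = 6.0
PARTIAL_DECAY_FIT_S = 2.5      # 10 timepoints at 4 Hz after the peak
# absolute df/f floor for significance: with exactly zero baseline noise the
# 3-sigma rule would otherwise promote numerical residuals (~1e-16) to events
SIGNIFICANCE_ATOL_DFF = 1e-9


class ConfigurationError(ValueError):
    """Raised for invalid timing or simulation configurations."""


@dataclass(frozen=True)
class TrialTiming:
    """Temporal structure of one imaging sweep.

    Default values follow the standard protocol: 4 Hz frame rate, 7.5 s
    baseline, 3 s odour delivery, 7.5 s post-odour acquisition (18 s total).
    Frame timestamps are taken at frame start.
    """

    frame_rate_hz: float = 4.0
    odor_onset_s: float = 7.5
    odor_duration_s: float = 3.0
    sweep_duration_s: float = 18.0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ConfigurationError("frame_rate_hz must be positive")
        if self.odor_onset_s + self.odor_duration_s >= self.sweep_duration_s:
            raise ConfigurationError(
                "odour onset + duration must fall inside the sweep")
        n = self.sweep_duration_s * self.frame_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("sweep duration x frame rate must be integral")

    @property
    def n_frames(self) -> int:
        return int(round(self.sweep_duration_s * self.frame_rate_hz))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def onset_frame(self) -> int:
        return int(round(self.odor_onset_s * self.frame_rate_hz))

    @property
    def baseline_window(self) -> slice:
        """Frames of the 3 s window immediately preceding odour onset."""
        w = int(round(BASELINE_NOISE_WINDOW_S * self.frame_rate_hz))
        return slice(self.onset_frame - w, self.onset_frame)

    @property
    def prestim_window(self) -> slice:
        """Frames of the full pre-stimulus baseline (bleach-fit window)."""
        return slice(0, self.onset_frame)


@dataclass
class SweepSet:
    """Repeated raw fluorescence sweeps for one cell x odour pair."""

    cell_id: str
    odor_id: str
    repeats: list[np.ndarray]
    timing: TrialTiming
    soma_area_um2: float = float("nan")
    background: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.timing.n_frames
        for r in self.repeats:
            if len(r) != n:
                raise ValueError(
                    f"repeat length {len(r)} does not match timing ({n} frames)")


@dataclass(frozen=True)
class BleachFit:
    """Single-exponential photobleach model f(t) = A*exp(-t/tau) + C."""

    a: float
    tau_s: float
    c: float
    converged: bool = True

    def decaying_component(self, t: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-t / self.tau_s)


@dataclass
class DffTrace:
    """A df/f trace plus its baseline statistics."""

    values: np.ndarray
    f_baseline: float
    noise_sd: float
    timing: TrialTiming


@dataclass
class ResponseEvent:
    direction: Literal["excitatory", "inhibitory"]
    peak_latency_s: float          # relative to odour onset
    peak_frame: int
    amplitude: float               # mean df/f over 3 s centred on the peak
    significant: bool
    timing_class: Literal["early", "late", "n/a"] = "n/a"


@dataclass
class ReliabilityStats:
    latency_cv: float
    weakest2_z: float
    per_repeat_latency_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_repeat_z: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class DecayEstimate:
    eligible: bool
    tau_partial_s: float | None = None
    tau_full_s: float | None = None
    returned_to_baseline: bool = False


@dataclass
class CellProfile:
    cell_id: str
    soma_area_um2: float
    size_class: str
    ti_early: int
    ti_late: int
    ti_inhib: int
    baseline_f: float
    noise_sd: float
    baseline_f_norm: float = float("nan")


# ---------------------------------------------------------------------------
# trace-level operations


def subtract_background(trace: np.ndarray,
                        background: float | np.ndarray) -> np.ndarray:
    """Subtract a scalar or per-frame background from a raw trace."""
    trace = np.asarray(trace, dtype=float)
    bg = np.asarray(background, dtype=float)
    if bg.ndim > 0 and bg.shape != trace.shape:
        raise ValueError("background trace length does not match the sweep")
    return trace - bg


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def bleach_correct(trace: np.ndarray,
                   timing: TrialTiming) -> tuple[np.ndarray, BleachFit]:
    """Fit and subtract the photobleach exponential.

    ``A*exp(-t/tau) + C`` is fitted by least squares on the pre-stimulus
    baseline only, and the decaying component ``A*exp(-t/tau)`` is then
    subtracted over the whole sweep.  The fitted offset ``C`` is retained so
    that the baseline fluorescence (and hence df/f) stays well defined.
    ``A`` may be negative (a brightening trace).  A non-convergent fit falls
    back to A=0, C=baseline mean, and is flagged.
    """
    trace = np.asarray(trace, dtype=float)
    t = timing.frame_times
    win = timing.prestim_window
    tb, yb = t[win], trace[win]
    if len(yb) < 3:
        raise ValueError("baseline window too short for a bleach fit")

    base_mean = float(np.mean(yb))
    # The time constant is bounded at twice the baseline duration: slower
    # exponentials are indistinguishable from a constant over the fit window,
    # which lets A absorb the offset and corrupts the extrapolation.  The fit
    # is a deterministic tau grid with (A, C) solved linearly per tau,
    # polished by a bounded nonlinear refinement.
    tau_lo, tau_hi = 0.25, 2.0 * timing.odor_onset_s
    ptp = float(np.ptp(yb))
    a_max = max(4.0 * ptp, 1e-6)
    best: tuple[float, float, float, float] | None = None  # (rss, a, tau, c)
    for tau in np.geomspace(tau_lo, tau_hi, 60):
        design = np.column_stack([np.exp(-tb / tau), np.ones_like(tb)])
        coef, *_ = np.linalg.lstsq(design, yb, rcond=None)
        a, c = float(coef[0]), float(coef[1])
        if abs(a) > a_max:
            continue
        rss = float(np.sum((design @ coef - yb) ** 2))
        if best is None or rss < best[0]:
            best = (rss, a, tau, c)

    fit = None
    if best is not None:
        _, a0, tau0, c0 = best
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                popt, _ = curve_fit(
                    _exp_model, tb, yb, p0=[a0, tau0, c0],
                    bounds=([-a_max, tau_lo, -np.inf], [a_max, tau_hi, np.inf]),
                    maxfev=10000)
            a, tau, c = (float(v) for v in popt)
        except (RuntimeError, ValueError):
            a, tau, c = a0, tau0, c0
        if all(map(np.isfinite, (a, tau, c))):
            fit = BleachFit(a=a, tau_s=tau, c=c, converged=True)
    if fit is None:
        logger.warning("bleach fit did not converge; falling back to A=0")
        fit = BleachFit(a=0.0, tau_s=timing.odor_onset_s / 3.0,
                        c=base_mean, converged=False)

    corrected = trace - fit.decaying_component(t)
    return corrected, fit


def compute_dff(corrected: np.ndarray, timing: TrialTiming) -> DffTrace:
    """Convert a bleach-corrected trace to df/f.

    f is the mean corrected fluorescence over the 3 s window immediately
    preceding odour onset; noise is the sample SD (n-1) of df/f in that
    window.
    """
    corrected = np.asarray(corrected, dtype=float)
    win = timing.baseline_window
    f = float(np.mean(corrected[win]))
    if f <= 0:
        raise ValueError(f"degenerate baseline fluorescence f={f:.3g} <= 0")
    dff = (corrected - f) / f
    noise_sd = float(np.std(dff[win], ddof=1))
    return DffTrace(values=dff, f_baseline=f, noise_sd=noise_sd, timing=timing)


def _amplitude_window(timing: TrialTiming, peak_frame: int) -> slice:
    """Frames of the 3 s window centred on the peak, truncated at sweep edges.

    The window is the half-open interval [t_peak - 1.5 s, t_peak + 1.5 s),
    i.e. 12 frames at 4 Hz when fully inside the sweep.
    """
    half = int(round(AMPLITUDE_WINDOW_S * timing.frame_rate_hz / 2.0))
    return slice(max(0, peak_frame - half), min(timing.n_frames, peak_frame + half))


def detect_responses(dff: DffTrace,
                     noise_sd: float | None = None,
                     early_late_cutoff_s: float = DEFAULT_EARLY_LATE_CUTOFF_S,
                     ) -> list[ResponseEvent]:
    """Detect up to one excitatory and one inhibitory event in a mean trace.

    The post-onset extremum (argmax for excitatory, argmin for inhibitory,
    earliest frame on ties) defines the peak; the amplitude is the mean df/f
    over the 3 s window centred on it.  An event is significant when
    |amplitude| >= 3 x the baseline noise.  Significant excitatory events
    peaking at or before the cutoff are early, after it late.
    """
    if early_late_cutoff_s <= 0:
        raise ValueError("early/late cutoff must be positive")
    timing = dff.timing
    sigma = dff.noise_sd if noise_sd is None else float(noise_sd)
    search = dff.values[timing.onset_frame:]
    if len(search) == 0:
        raise ValueError("empty post-onset search window")

    events: list[ResponseEvent] = []
    for direction, pick in (("excitatory", np.argmax), ("inhibitory", np.argmin)):
        peak = timing.onset_frame + int(pick(search))
        amp = float(np.mean(dff.values[_amplitude_window(timing, peak)]))
        latency = timing.frame_times[peak] - timing.odor_onset_s
        signed = amp if direction == "excitatory" else -amp
        significant = (signed >= SIGNIFICANCE_MULTIPLE * sigma
                       and signed > SIGNIFICANCE_ATOL_DFF)
        timing_class: str = "n/a"
        if significant and direction == "excitatory":
            timing_class = "early" if latency <= early_late_cutoff_s else "late"
        events.append(ResponseEvent(
            direction=direction, peak_latency_s=float(latency), peak_frame=peak,
            amplitude=amp, significant=bool(significant),
            timing_class=timing_class))
    return events


def derive_early_late_cutoff(latencies: Sequence[float]) -> float:
    """Two-cluster 1-D split of peak latencies by exhaustive search.

    Finds the partition of the sorted latencies into two contiguous groups
    minimising the within-cluster sum of squares (the exact 1-D two-means
    solution) and returns the midpoint of the two cluster means.
    """
    x = np.sort(np.asarray(latencies, dtype=float))
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct latencies")

    csum = np.cumsum(x)
    csum2 = np.cumsum(x ** 2)
    best: tuple[float, float, float] | None = None
    for k in range(1, len(x)):  # left = x[:k], right = x[k:]
        sl, sl2 = csum[k - 1], csum2[k - 1]
        sr, sr2 = csum[-1] - sl, csum2[-1] - sl2
        nl, nr = k, len(x) - k
        wcss = (sl2 - sl ** 2 / nl) + (sr2 - sr ** 2 / nr)
        if best is None or wcss < best[0] - 1e-12:
            best = (wcss, sl / nl, sr / nr)
    assert best is not None
    return (best[1] + best[2]) / 2.0


def repeat_reliability(repeat_dffs: Sequence[DffTrace],
                       direction: Literal["excitatory", "inhibitory"],
                       ) -> ReliabilityStats:
    """Repeat-by-repeat reliability of a response.

    Each repeat is analysed independently (peak latency and window-mean
    amplitude exactly as in :func:`detect_responses`); the latency CV is the
    sample SD over the mean of the per-repeat peak latencies, and each
    repeat's z-score is its amplitude magnitude divided by its own baseline
    noise.  ``weakest2_z`` is the mean of the two smallest z-scores.
    """
    if len(repeat_dffs) < 3:
        raise ValueError("repeat reliability requires at least three repeats")
    latencies, zs = [], []
    for dff in repeat_dffs:
        evs = {e.direction: e for e in detect_responses(dff)}
        ev = evs[direction]
        latencies.append(ev.peak_latency_s)
        if dff.noise_sd <= 0:
            raise ValueError("zero baseline noise: z-score undefined")
        signed = ev.amplitude if direction == "excitatory" else -ev.amplitude
        zs.append(signed / dff.noise_sd)
    lat = np.asarray(latencies)
    z = np.asarray(zs)
    mean_lat = float(np.mean(lat))
    if mean_lat == 0:
        raise ValueError("mean latency is zero: CV undefined")
    cv = float(np.std(lat, ddof=1) / mean_lat)
    weakest2 = float(np.mean(np.sort(z)[:2]))
    return ReliabilityStats(latency_cv=cv, weakest2_z=weakest2,
                            per_repeat_latency_s=lat, per_repeat_z=z)


def _fit_single_exponential(t_rel: np.ndarray, y: np.ndarray) -> float | None:
    """Least-squares fit of amp*exp(-t/tau); returns tau or None."""
    amp0 = y[0] if y[0] > 0 else max(float(np.max(y)), 1e-6)
    span = max(float(t_rel[-1]), 1e-3)
    best_tau, best_err = None, np.inf
    for tau0 in (span / 4, span, 4 * span):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                popt, _ = curve_fit(
                    lambda t, a, tau: a * np.exp(-t / tau), t_rel, y,
                    p0=[amp0, tau0],
                    bounds=([0.0, 1e-3], [np.inf, 1e4]), maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        err = float(np.sum((popt[0] * np.exp(-t_rel / popt[1]) - y) ** 2))
        if err < best_err:
            best_err, best_tau = err, float(popt[1])
    return best_tau


def fit_decay(dff: DffTrace, event: ResponseEvent,
              noise_sd: float | None = None) -> DecayEstimate:
    """Estimate the response decay constant from a single-exponential fit.

    The partial fit uses the peak frame plus the following 2.5 s (10 frames
    at 4 Hz); the full fit uses the entire post-peak profile and is reported
    only when the trace returns to within one noise SD of baseline before
    sweep end.  Inhibitory events are fitted on the negated trace.  Events
    peaking less than 2.5 s before sweep end are ineligible.
    """
    if not event.significant:
        raise ValueError("decay estimated for significant events only")
    timing = dff.timing
    sigma = dff.noise_sd if noise_sd is None else float(noise_sd)
    t = timing.frame_times
    peak = event.peak_frame
    if t[peak] > timing.sweep_duration_s - PARTIAL_DECAY_FIT_S:
        return DecayEstimate(eligible=False)

    y = dff.values.copy()
    if event.direction == "inhibitory":
        y = -y
    post = y[peak:]
    t_rel = t[peak:] - t[peak]

    n_partial = int(round(PARTIAL_DECAY_FIT_S * timing.frame_rate_hz)) + 1
    tau_partial = _fit_single_exponential(t_rel[:n_partial], post[:n_partial])

    returned = bool(np.any(post[1:] <= sigma))
    tau_full = _fit_single_exponential(t_rel, post) if returned else None
    return DecayEstimate(eligible=True, tau_partial_s=tau_partial,
                         tau_full_s=tau_full, returned_to_baseline=returned)


# ---------------------------------------------------------------------------
# cell-level summaries


def tuning_index(events_by_odor: dict[str, list[ResponseEvent]],
                 ) -> tuple[int, int, int]:
    """Count odours with a significant response of each type.

    Returns (TI_early, TI_late, TI_inhib).  Non-responding cells simply get
    zeros; they are retained in downstream analyses.
    """
    ti_early = ti_late = ti_inhib = 0
    for events in events_by_odor.values():
        for ev in events:
            if not ev.significant:
                continue
            if ev.direction == "inhibitory":
                ti_inhib += 1
            elif ev.timing_class == "early":
                ti_early += 1
            elif ev.timing_class == "late":
                ti_late += 1
    return ti_early, ti_late, ti_inhib


def normalize_baseline(cells: pd.DataFrame) -> pd.DataFrame:
    """Normalise baseline F by the small-cell mean of the field of view.

    Adds a ``baseline_f_norm`` column; the normalised mean over small cells
    is exactly 1.  Raises if the field of view contains no small cells.
    """
    small = cells[cells["size_class"] == "small"]
    if len(small) == 0:
        raise ValueError("no small cells in field of view: cannot normalise")
    ref = float(small["baseline_f"].mean())
    out = cells.copy()
    out["baseline_f_norm"] = out["baseline_f"] / ref
    return out


def _analyze_sweepset(ss: SweepSet,
                      early_late_cutoff_s: float,
                      noise_mode: str) -> tuple[list[ResponseEvent], float, float,
                                                DffTrace]:
    """Run the mean-trace pipeline on one cell x odour SweepSet.

    Returns (events, mean per-presentation baseline F, noise SD, mean df/f).
    """
    raws = [np.asarray(r, dtype=float) for r in ss.repeats]
    if ss.background is not None:
        raws = [subtract_background(r, ss.background) for r in raws]

    # mean response trace first, then bleach correction and df/f
    mean_raw = np.mean(raws, axis=0)
    corrected, _ = bleach_correct(mean_raw, ss.timing)
    dff_mean = compute_dff(corrected, ss.timing)

    # per-presentation path: each repeat independently corrected
    per_f, per_noise = [], []
    for r in raws:
        c, _ = bleach_correct(r, ss.timing)
        d = compute_dff(c, ss.timing)
        per_f.append(d.f_baseline)
        per_noise.append(d.noise_sd)

    if noise_mode == "per_repeat":
        sigma = float(np.mean(per_noise))
    elif noise_mode == "mean_trace":
        sigma = dff_mean.noise_sd
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")

    events = detect_responses(dff_mean, noise_sd=sigma,
                              early_late_cutoff_s=early_late_cutoff_s)
    return events, float(np.mean(per_f)), sigma, dff_mean


def analyze_fov(sweep_sets: Iterable[SweepSet],
                early_late_cutoff_s: float = DEFAULT_EARLY_LATE_CUTOFF_S,
                small_max_um2: float = 70.0,
                big_min_um2: float = 99.0,
                noise_mode: str = "per_repeat",
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse a field of view and return tidy (cells, events) tables.

    Repeats of the background-subtracted raw traces are averaged first, then
    bleach-corrected, converted to df/f and scanned for events; the
    per-repeat path contributes the baseline statistics (and, elsewhere,
    reliability).  By default the significance noise is the per-presentation
    noise SD averaged across presentations (``noise_mode='per_repeat'``);
    ``'mean_trace'`` uses the mean trace's own baseline SD instead.

    Size classes use strict cutoffs: area < ``small_max_um2`` is small,
    area > ``big_min_um2`` is big, everything else unclassified.
    """
    from .morpho import SizeCutoffs, assign_size_class

    cutoffs = SizeCutoffs(small_max_um2=small_max_um2, big_min_um2=big_min_um2)
    by_cell: dict[str, dict] = {}
    event_rows: list[dict] = []

    for ss in sweep_sets:
        info = by_cell.setdefault(ss.cell_id, {
            "soma_area_um2": ss.soma_area_um2,
            "events_by_odor": {}, "f": [], "noise": [], "failed": False})
        try:
            events, f_mean, sigma, _ = _analyze_sweepset(
                ss, early_late_cutoff_s, noise_mode)
        except Exception as exc:  # flag, do not abort the field of view
            logger.warning("cell %s odour %s failed: %s", ss.cell_id, ss.odor_id, exc)
            info["failed"] = True
            continue
        info["events_by_odor"][ss.odor_id] = events
        info["f"].append(f_mean)
        info["noise"].append(sigma)
        for ev in events:
            if ev.significant:
                event_rows.append({
                    "cell_id": ss.cell_id, "odor_id": ss.odor_id,
                    "direction": ev.direction, "timing_class": ev.timing_class,
                    "peak_latency_s": ev.peak_latency_s,
                    "amplitude": ev.amplitude, "noise_sd": sigma,
                    "z": abs(ev.amplitude) / sigma if sigma > 0 else np.nan})

    cell_rows = []
    for cell_id, info in by_cell.items():
        ti_early, ti_late, ti_inhib = tuning_index(info["events_by_odor"])
        area = info["soma_area_um2"]
        cell_rows.append({
            "cell_id": cell_id,
            "soma_area_um2": area,
            "size_class": (assign_size_class(area, cutoffs)
                           if np.isfinite(area) else "unclassified"),
            "ti_early": ti_early, "ti_late": ti_late, "ti_inhib": ti_inhib,
            "baseline_f": float(np.mean(info["f"])) if info["f"] else np.nan,
            "noise_sd": float(np.mean(info["noise"])) if info["noise"] else np.nan,
            "flagged": info["failed"],
        })
    cells = pd.DataFrame(cell_rows)
    if len(cells) and (cells["size_class"] == "small").any():
        cells = normalize_baseline(cells)
    else:
        cells["baseline_f_norm"] = np.nan
    events = pd.DataFrame(event_rows, columns=[
        "cell_id", "odor_id", "direction", "timing_class", "peak_latency_s",
        "amplitude", "noise_sd", "z"])
    return cells, events
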