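"""Spike-waveform and excitability analysis from current-clamp sweeps.

Covers the single-spike pathway (smoothing, phase-plane plots, waveform
metrics, mono/biphasic classification by fit-error ratio) and the
repetitive-firing pathway (spike counting, rheobase, input-output curves).

The phase plane plots dV/dt (V/s, equivalently mV/ms) against membrane
potential.  A spike initiated away from the soma (at an axon initial
segment) produces a biphasic, "double-bumped" phase plane; the fit-error
ratio quantifies this by comparing linear and exponential fits to the
initial portion of the plot: ratio > 3 is "steep" (biphasic-like), < 1 is
"smooth" (monophasic-like), anything between stays unclassified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "VoltageSweep",
    "PhasePlane",
    "APMetrics",
    "WaveformClass",
    "FiringMetrics",
    "NoSpikeError",
    "smooth_trace",
    "phase_plane",
    "ap_waveform_metrics",
    "waveform_classify",
    "label_from_ratio",
    "count_spikes",
    "firing_metrics",
]

SMOOTH_POINTS = 20               # 100 us at the native 5 us sample interval
THRESHOLD_DVDT_V_PER_S = 10.0    # dV/dt crossing defining voltage threshold
RAPIDNESS_BAND_V_PER_S = (10.0, 20.0)
STEEP_RATIO = 3.0
SMOOTH_RATIO = 1.0
CLASSIFY_MAX_FRACTION = 0.4      # windows end at <= 40% of max dV/dt
SPIKE_DETECT_MV = 0.0            # upward 0 mV crossing counts a spike
SPIKE_REFRACTORY_S = 1e-3


class NoSpikeError(ValueError):
    """Raised when a sweep contains no countable action potential."""


@dataclass
class VoltageSweep:
    """A membrane-potential recording with its stimulus metadata."""

    time_s: np.ndarray
    vm_mV: np.ndarray
    sample_interval_s: float
    injected_current_pA: float = float("nan")
    capacitance_pF: float = float("nan")
    step_onset_s: float = 0.0
    step_duration_s: float = float("nan")
    kind: str | None = None      # ground-truth label when simulated

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.vm_mV = np.asarray(self.vm_mV, dtype=float)
        if self.time_s.shape != self.vm_mV.shape:
            raise ValueError("time and Vm arrays differ in length")

    @property
    def current_density_pA_per_pF(self) -> float:
        if not (self.capacitance_pF > 0):
            raise ValueError("current density needs a positive capacitance")
        return self.injected_current_pA / self.capacitance_pF


@dataclass
class PhasePlane:
    """Paired (Vm, dV/dt) samples in time order; dV/dt in V/s == mV/ms."""

    vm_mV: np.ndarray
    dvdt_V_per_s: np.ndarray


@dataclass
class APMetrics:
    threshold_mV: float
    threshold_index: int
    max_dvdt_V_per_s: float
    peak_mV: float
    amplitude_mV: float
    width_ms: float
    onset_rapidness_per_ms: float
    ahp_mV: float
    ahp_rel_threshold_mV: float


@dataclass
class WaveformClass:
    ratios: np.ndarray
    max_ratio: float
    label: Literal["steep", "smooth", "unclassified"]


@dataclass
class FiringMetrics:
    counts: np.ndarray
    densities_pA_per_pF: np.ndarray
    rates_hz: np.ndarray
    rheobase_pA_per_pF: float
    io_slope_hz_per_pA_per_pF: float
    max_spikes: int
    first_spike_delay_ms: float
    isi_cv: float
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def smooth_trace(sweep: VoltageSweep, n_points: int = SMOOTH_POINTS) -> VoltageSweep:
    """Centred sliding-mean filter (20 points = 100 us at 5 us sampling).

    Edges use a shrinking window; the output length equals the input length.
    """
    v = sweep.vm_mV
    n = len(v)
    if n < n_points:
        raise ValueError(f"trace shorter than the {n_points}-point filter")
    lo = (n_points - 1) // 2          # window [i-lo, i+hi], n_points wide
    hi = n_points - 1 - lo
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    starts = np.maximum(idx - lo, 0)
    stops = np.minimum(idx + hi + 1, n)
    sm = (csum[stops] - csum[starts]) / (stops - starts)
    out = VoltageSweep(
        time_s=sweep.time_s, vm_mV=sm, sample_interval_s=sweep.sample_interval_s,
        injected_current_pA=sweep.injected_current_pA,
        capacitance_pF=sweep.capacitance_pF, step_onset_s=sweep.step_onset_s,
        step_duration_s=sweep.step_duration_s, kind=sweep.kind)
    return out


def phase_plane(sweep: VoltageSweep) -> PhasePlane:
    """Differentiate Vm by central differences and pair with Vm.

    dV/dt is expressed in V/s, numerically identical to mV/ms.
    """
    dvdt_mV_per_s = np.gradient(sweep.vm_mV, sweep.time_s)
    return PhasePlane(vm_mV=sweep.vm_mV.copy(), dvdt_V_per_s=dvdt_mV_per_s / 1e3)


def ap_waveform_metrics(sweep: VoltageSweep,
                        pp: PhasePlane | None = None) -> APMetrics:
    """Single-spike waveform metrics from a (pre-smoothed) sweep.

    Threshold is Vm at the first sample where dV/dt reaches 10 V/s; onset
    rapidness is the slope (1/ms) of a least-squares line through the
    phase-plane points with dV/dt in [10, 20] V/s on the rising phase; width
    is measured between the interpolated crossings of the voltage midway
    between threshold and peak; the AHP is the post-peak Vm minimum.
    """
    if pp is None:
        pp = phase_plane(sweep)
    v, dvdt = pp.vm_mV, pp.dvdt_V_per_s
    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    if peak <= SPIKE_DETECT_MV or not np.any(dvdt >= THRESHOLD_DVDT_V_PER_S):
        raise NoSpikeError("dV/dt never reaches 10 V/s with Vm > 0 mV")

    above = np.flatnonzero(dvdt >= THRESHOLD_DVDT_V_PER_S)
    thr_idx = int(above[0])
    threshold = float(v[thr_idx])
    dvdt_peak_idx = thr_idx + int(np.argmax(dvdt[thr_idx:peak_idx + 1]))
    max_dvdt = float(dvdt[dvdt_peak_idx])

    # contiguous run of phase-plane samples at threshold: stop at the first
    # sample above the band so later re-entries (e.g. the somatic rise of a
    # biphasic spike) cannot dilute the onset slope
    lo, hi = RAPIDNESS_BAND_V_PER_S
    run = dvdt[thr_idx:dvdt_peak_idx + 1]
    stop = np.flatnonzero(run > hi)
    run_end = int(stop[0]) if len(stop) else len(run)
    band = np.flatnonzero((run[:run_end] >= lo) & (run[:run_end] <= hi)) + thr_idx
    if len(band) >= 2:
        rapidness = float(np.polyfit(v[band], dvdt[band], 1)[0])
    else:  # fall back to a local finite difference at threshold
        j = min(thr_idx + 1, len(v) - 1)
        dv = v[j] - v[thr_idx]
        rapidness = float((dvdt[j] - dvdt[thr_idx]) / dv) if dv != 0 else np.nan

    half = (threshold + peak) / 2.0
    t = sweep.time_s

    def _interp_crossing(i0: int, i1: int) -> float:
        f = (half - v[i0]) / (v[i1] - v[i0])
        return t[i0] + f * (t[i1] - t[i0])

    up = np.flatnonzero((v[thr_idx:peak_idx] < half) & (v[thr_idx + 1:peak_idx + 1] >= half))
    dn = np.flatnonzero((v[peak_idx:-1] >= half) & (v[peak_idx + 1:] < half))
    if len(up) and len(dn):
        t_up = _interp_crossing(thr_idx + up[0], thr_idx + up[0] + 1)
        t_dn = _interp_crossing(peak_idx + dn[0], peak_idx + dn[0] + 1)
        width_ms = (t_dn - t_up) * 1e3
    else:  # no repolarising phase in the window: width undefined
        width_ms = float("nan")

    ahp = float(np.min(v[peak_idx:]))
    return APMetrics(
        threshold_mV=threshold, threshold_index=thr_idx,
        max_dvdt_V_per_s=max_dvdt, peak_mV=peak,
        amplitude_mV=peak - threshold, width_ms=float(width_ms),
        onset_rapidness_per_ms=rapidness, ahp_mV=ahp,
        ahp_rel_threshold_mV=threshold - ahp)


def _exp_rss(v: np.ndarray, y: np.ndarray) -> float:
    """Best RMS residual of y = a*exp((v-v0)/k) + c with a > 0, 0 < k <= span.

    The convexity constraint (positive a, bounded k) keeps the model in the
    sharp-onset family: unconstrained, three free parameters would fit any
    smooth noiseless segment almost perfectly and the error ratio would lose
    its meaning.
    """
    v0 = v[0]
    x = v - v0
    span = max(float(x[-1] - x[0]), 1e-6)
    ymax = float(np.max(np.abs(y))) + 1e-12
    best = np.inf
    for k0 in (span / 8, span / 2):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                popt, _ = curve_fit(
                    lambda xx, a, k, c: a * np.exp(xx / k) + c, x, y,
                    p0=[max(y[-1] - y[0], 1e-3), k0, float(y[0])],
                    bounds=([1e-9, span / 50, -2 * ymax], [np.inf, span, 2 * ymax]),
                    maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        resid = popt[0] * np.exp(x / popt[1]) + popt[2] - y
        best = min(best, float(np.sqrt(np.mean(resid ** 2))))
    return best


def waveform_classify(pp: PhasePlane,
                      metrics: APMetrics,
                      n_windows: int = 16) -> WaveformClass:
    """Mono/biphasic classification by linear-vs-exponential fit-error ratio.

    Over windows of the phase plane starting at voltage threshold and ending
    at increasing fractions of the maximum dV/dt (up to 40%), fit a line and
    a constrained exponential; the per-window ratio is the linear RMS error
    over the exponential RMS error (floored at 1e-3 x max dV/dt).  The
    maximum ratio over windows labels the cell: > 3 steep, < 1 smooth,
    otherwise unclassified.
    """
    v, dvdt = pp.vm_mV, pp.dvdt_V_per_s
    thr = metrics.threshold_index
    dvdt_peak_idx = thr + int(np.argmax(dvdt[thr:]))
    max_dvdt = float(dvdt[dvdt_peak_idx])
    eps = 1e-3 * max_dvdt

    fractions = np.linspace(0.05, CLASSIFY_MAX_FRACTION, n_windows)
    ratios = []
    rising = dvdt[thr:dvdt_peak_idx + 1]
    seen_stops: set[int] = set()
    for frac in fractions:
        stop_rel = np.flatnonzero(rising >= frac * max_dvdt)
        stop = thr + (int(stop_rel[0]) if len(stop_rel) else len(rising) - 1)
        if stop - thr + 1 < 4 or stop in seen_stops:
            continue
        seen_stops.add(stop)
        vi, yi = v[thr:stop + 1], dvdt[thr:stop + 1]
        if len(vi) > 120:  # subsample evenly: the fits need shape, not density
            sel = np.unique(np.linspace(0, len(vi) - 1, 120).astype(int))
            vi, yi = vi[sel], yi[sel]
        lin = np.polyfit(vi, yi, 1)
        lin_err = float(np.sqrt(np.mean((np.polyval(lin, vi) - yi) ** 2)))
        exp_err = _exp_rss(vi, yi)
        ratios.append(lin_err / max(exp_err, eps))
        if ratios[-1] > STEEP_RATIO:
            break  # the label depends only on the maximum ratio

    if len(ratios) == 0:
        warnings.warn("fewer than 4 phase-plane points before 40% of max dV/dt; "
                      "waveform left unclassified", stacklevel=2)
        return WaveformClass(ratios=np.empty(0), max_ratio=float("nan"),
                             label="unclassified")
    ratios_arr = np.asarray(ratios)
    max_ratio = float(np.max(ratios_arr))
    return WaveformClass(ratios=ratios_arr, max_ratio=max_ratio,
                         label=label_from_ratio(max_ratio))


def label_from_ratio(max_ratio: float,
                     ) -> Literal["steep", "smooth", "unclassified"]:
    """Non-inclusive labelling rule: > 3 steep, < 1 smooth, else unclassified."""
    if max_ratio > STEEP_RATIO:
        return "steep"
    if max_ratio < SMOOTH_RATIO:
        return "smooth"
    return "unclassified"


def count_spikes(sweep: VoltageSweep) -> tuple[int, np.ndarray]:
    """Count spikes as upward 0 mV crossings separated by >= 1 ms.

    Returns the count and the interpolated crossing times (s).
    """
    v, t = sweep.vm_mV, sweep.time_s
    up = np.flatnonzero((v[:-1] < SPIKE_DETECT_MV) & (v[1:] >= SPIKE_DETECT_MV))
    times = []
    for i in up:
        frac = (SPIKE_DETECT_MV - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if times and tc - times[-1] < SPIKE_REFRACTORY_S:
            continue
        times.append(float(tc))
    return len(times), np.asarray(times)


def firing_metrics(sweeps: Sequence[VoltageSweep]) -> FiringMetrics:
    """Excitability metrics from a family of 500 ms current steps.

    Spike counts per step convert to rates over the step duration; rheobase
    is the lowest current density evoking at least one spike; the IO slope
    is the least-squares slope of rate against density from the rheobase
    step up to the step of maximum count (monophasic-like cells plateau, so
    a global fit would conflate slope and saturation).  First-spike delay
    and inter-spike-interval CV are measured at rheobase.
    """
    if len(sweeps) < 2:
        raise ValueError("need at least two current steps")
    flags: list[str] = []
    dens, counts, spike_times = [], [], []
    for sw in sweeps:
        dens.append(sw.current_density_pA_per_pF)
        c, st = count_spikes(sw)
        counts.append(c)
        spike_times.append(st)
    order = np.argsort(dens)
    dens_arr = np.asarray(dens)[order]
    counts_arr = np.asarray(counts)[order]
    spike_times = [spike_times[i] for i in order]
    durations = np.asarray([sweeps[i].step_duration_s for i in order])
    rates = counts_arr / durations

    spiking = np.flatnonzero(counts_arr >= 1)
    if len(spiking) == 0:
        flags.append("no spiking step: rheobase undefined")
        return FiringMetrics(
            counts=counts_arr, densities_pA_per_pF=dens_arr, rates_hz=rates,
            rheobase_pA_per_pF=float("nan"),
            io_slope_hz_per_pA_per_pF=float("nan"), max_spikes=0,
            first_spike_delay_ms=float("nan"), isi_cv=float("nan"), flags=flags)

    rheo_idx = int(spiking[0])
    rheobase = float(dens_arr[rheo_idx])
    max_idx = int(np.argmax(counts_arr))
    fit_lo = min(rheo_idx, max_idx)
    if max_idx > fit_lo:
        io_slope = float(np.polyfit(dens_arr[fit_lo:max_idx + 1],
                                    rates[fit_lo:max_idx + 1], 1)[0])
    else:
        io_slope = float("nan")
        flags.append("single spiking step: IO slope undefined")

    st = spike_times[rheo_idx]
    onset = sweeps[order[rheo_idx]].step_onset_s
    delay_ms = float((st[0] - onset) * 1e3) if len(st) else float("nan")
    if len(st) >= 3:
        isis = np.diff(st)
        isi_cv = float(np.std(isis, ddof=1) / np.mean(isis))
    else:
        isi_cv = float("nan")
        flags.append("fewer than three spikes at rheobase: ISI CV undefined")

    return FiringMetrics(
        counts=counts_arr, densities_pA_per_pF=dens_arr, rates_hz=rates,
        rheobase_pA_per_pF=rheobase, io_slope_hz_per_pA_per_pF=io_slope,
        max_spikes=int(np.max(counts_arr)), first_spike_delay_ms=delay_ms,
        isi_cv=isi_cv, flags=flags)
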