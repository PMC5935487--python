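"""Synthetic-data generators with known ground truth.

Every downstream stage of the package can be exercised without external
data: the generators emulate (1) ROI-level GCaMP fluorescence sweeps with
injected odour-response events, photobleaching and frame noise, (2)
single-spike and current-step voltage sweeps with monophasic or biphasic
(double-bumped phase-plane) action-potential shapes, (3) planar neurite
trees with analytically known Sholl crossings, (4) bimodal soma-size
populations, and (5) labelled electrophysiology feature tables.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .imaging import ConfigurationError, SweepSet, TrialTiming
from .ephys import VoltageSweep
from .morpho import NeuriteTree
from .classify import FEATURE_COLUMNS

__all__ = [
    "EventTypeParams",
    "GCaMPSimConfig",
    "APSimConfig",
    "StepProtocolConfig",
    "SomaMixture",
    "SomaPopulation",
    "gen_gcamp_fov",
    "gen_ap_sweep",
    "sample_ap_config",
    "gen_step_protocol",
    "gen_neurite_tree",
    "gen_random_tree",
    "gen_soma_population",
    "gen_feature_table",
    "FEATURE_COLUMNS",
    "TABLE_FEATURE_PARAMS",
]

# Class centres for the five subtype-classification variables
# (monophasic/putative AIS-negative vs biphasic/putative AIS-positive),
# with the corresponding standard errors used as default spreads.
TABLE_FEATURE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "monophasic": {
        "soma_area_um2": (57.0, 4.8),
        "current_threshold_pA_per_pF": (7.5, 1.0),
        "onset_rapidness_per_ms": (3.95, 0.28),
        "io_slope_hz_per_pA_per_pF": (1.85, 0.54),
        "max_spikes": (10.0, 2.0),
    },
    "biphasic": {
        "soma_area_um2": (89.0, 6.8),
        "current_threshold_pA_per_pF": (4.6, 0.4),
        "onset_rapidness_per_ms": (8.22, 1.66),
        "io_slope_hz_per_pA_per_pF": (3.53, 0.48),
        "max_spikes": (21.0, 4.0),
    },
}


# ---------------------------------------------------------------------------
# GCaMP field-of-view simulation


@dataclass(frozen=True)
class EventTypeParams:
    """One odour-response event type.

    Amplitudes are expressed in multiples of the baseline df/f noise SD and
    refer to the 3 s window mean around the analytic peak, i.e. directly on
    the scale measured by the detection stage.  Onset latencies are seconds
    after odour onset for the kernel foot; the reported ground-truth latency
    is the analytic kernel peak.
    """

    probability: float
    amp_range: tuple[float, float]
    onset_range_s: tuple[float, float]
    rise_s: float
    decay_range_s: tuple[float, float]

    def peak_offset_s(self, decay_s: float) -> float:
        r, d = self.rise_s, decay_s
        return r * d / (d - r) * math.log(d / r)


@dataclass(frozen=True)
class GCaMPSimConfig:
    """Study-scale GCaMP simulation: 4 Hz frames, 7.5/3/7.5 s trials,
    8 odours x 3 repeats, big cells brighter and less noisy than small."""

    frame_rate_hz: float = 4.0
    sweep_duration_s: float = 18.0
    baseline_s: float = 7.5
    odor_s: float = 3.0
    n_odors: int = 8
    n_repeats: int = 3
    n_small_cells: int = 6
    n_big_cells: int = 6
    small_baseline_f_mean: float = 100.0
    small_baseline_f_sd: float = 10.0
    small_noise_sd: float = 5.0
    big_baseline_f_mean: float = 200.0
    big_baseline_f_sd: float = 20.0
    big_noise_sd: float = 4.0
    small_soma_mean_um2: float = 55.0
    small_soma_sd_um2: float = 8.0
    big_soma_mean_um2: float = 140.0
    big_soma_sd_um2: float = 20.0
    bleach_fraction: float = 0.15
    bleach_tau_s: float = 8.0
    background_au: float = 10.0
    early: EventTypeParams = EventTypeParams(
        probability=0.09, amp_range=(3.0, 12.0), onset_range_s=(0.2, 3.5),
        rise_s=0.3, decay_range_s=(1.5, 2.5))
    late: EventTypeParams = EventTypeParams(
        probability=0.028, amp_range=(3.0, 9.0), onset_range_s=(3.0, 5.5),
        rise_s=2.0, decay_range_s=(8.0, 11.0))
    inhib: EventTypeParams = EventTypeParams(
        probability=0.034, amp_range=(3.0, 8.0), onset_range_s=(2.0, 5.0),
        rise_s=1.5, decay_range_s=(8.0, 11.0))
    # df/f per amplitude unit; defaults to each cell's noise SD on the df/f
    # scale (amplitudes in noise multiples).  Set explicitly for noiseless
    # simulations, where the noise-multiple scale would collapse to zero.
    amp_scale_dff: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_s + self.odor_s > self.sweep_duration_s:
            raise ConfigurationError("baseline + odour must fit in the sweep")
        for name in ("small_baseline_f_mean", "big_baseline_f_mean",
                     "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.small_noise_sd < 0 or self.big_noise_sd < 0:
            raise ConfigurationError("noise SDs must be nonnegative")
        for ev in (self.early, self.late, self.inhib):
            if not 0.0 <= ev.probability <= 1.0:
                raise ConfigurationError("event probabilities must lie in [0, 1]")
            if ev.rise_s >= ev.decay_range_s[0]:
                raise ConfigurationError("event rise must be faster than decay")
        # the early/late latency ranges must respect the 6 s class boundary
        for d in self.early.decay_range_s:
            if self.early.onset_range_s[1] + self.early.peak_offset_s(d) > 6.0:
                raise ConfigurationError("early-event peaks must stay <= 6 s")
        for d in self.late.decay_range_s:
            if self.late.onset_range_s[0] + self.late.peak_offset_s(d) <= 6.0:
                raise ConfigurationError("late-event peaks must stay > 6 s")

    @property
    def timing(self) -> TrialTiming:
        return TrialTiming(frame_rate_hz=self.frame_rate_hz,
                           odor_onset_s=self.baseline_s,
                           odor_duration_s=self.odor_s,
                           sweep_duration_s=self.sweep_duration_s)


def _doe_kernel(t: np.ndarray, t0: float, rise: float, decay: float) -> np.ndarray:
    """Unit difference-of-exponentials kernel starting at t0."""
    s = t - t0
    out = np.where(s > 0, np.exp(-np.maximum(s, 0) / decay)
                   - np.exp(-np.maximum(s, 0) / rise), 0.0)
    return out


def _window_mean(params: EventTypeParams, t0_abs: float, decay_s: float,
                 sweep_end_s: float, half_s: float = 1.5) -> tuple[float, float]:
    """(kernel window mean, absolute peak time) on a dense grid.

    The 3 s averaging window is centred on the analytic peak and truncated
    at the sweep end, matching the detection stage.
    """
    t_pk = t0_abs + params.peak_offset_s(decay_s)
    w0, w1 = t_pk - half_s, min(t_pk + half_s, sweep_end_s)
    grid = np.linspace(w0, w1, 512)
    vals = _doe_kernel(grid, t0_abs, params.rise_s, decay_s)
    return float(np.mean(vals)), t_pk


def gen_gcamp_fov(config: GCaMPSimConfig,
                  ) -> tuple[list[SweepSet], pd.DataFrame]:
    """Simulate a field of view: one SweepSet per cell x odour, plus the
    ground-truth event table.

    Raw traces follow ``F*(1 + sum of event kernels) + a*F*exp(-t/tau_b) +
    background + noise``: events are multiplicative on the baseline (so
    their amplitude lives naturally on the df/f scale) and photobleaching is
    an additive decaying exponential, exactly the model the correction stage
    fits.  Early- and late-excitatory events are mutually exclusive within a
    trial; inhibitory events are drawn independently.
    """
    rng = np.random.default_rng(config.rng_seed)
    timing = config.timing
    t = timing.frame_times
    onset = timing.odor_onset_s

    cells = []
    for i in range(config.n_small_cells + config.n_big_cells):
        big = i >= config.n_small_cells
        f = rng.normal(config.big_baseline_f_mean if big else config.small_baseline_f_mean,
                       config.big_baseline_f_sd if big else config.small_baseline_f_sd)
        area = rng.normal(config.big_soma_mean_um2 if big else config.small_soma_mean_um2,
                          config.big_soma_sd_um2 if big else config.small_soma_sd_um2)
        noise = config.big_noise_sd if big else config.small_noise_sd
        cells.append({
            "cell_id": f"{'big' if big else 'small'}_{i:03d}",
            "baseline_f": max(float(f), 1.0),
            "noise_sd": noise,
            "soma_area_um2": max(float(area), 1.0),
            "is_big": big,
        })

    sweep_sets: list[SweepSet] = []
    gt_rows: list[dict] = []
    for cell in cells:
        sigma_dff = (config.amp_scale_dff if config.amp_scale_dff is not None
                     else cell["noise_sd"] / cell["baseline_f"])
        for o in range(config.n_odors):
            odor_id = f"odor{o}"
            kernels = np.zeros_like(t)

            drawn: list[tuple[str, EventTypeParams, float]] = []
            u = rng.uniform()
            if u < config.early.probability:
                drawn.append(("early_exc", config.early, 1.0))
            elif u < config.early.probability + config.late.probability:
                drawn.append(("late_exc", config.late, 1.0))
            if rng.uniform() < config.inhib.probability:
                drawn.append(("inhib", config.inhib, -1.0))

            for etype, params, sign in drawn:
                amp = rng.uniform(*params.amp_range)
                t0 = onset + rng.uniform(*params.onset_range_s)
                decay = rng.uniform(*params.decay_range_s)
                wmean, t_pk = _window_mean(params, t0, decay,
                                           timing.sweep_duration_s)
                scale = sign * amp * sigma_dff / wmean
                kernels += scale * _doe_kernel(t, t0, params.rise_s, decay)
                gt_rows.append({
                    "cell_id": cell["cell_id"], "odor_id": odor_id,
                    "type": etype, "true_latency_s": t_pk - onset,
                    "true_amplitude": amp, "true_decay_s": decay,
                })

            clean = (cell["baseline_f"] * (1.0 + kernels)
                     + config.bleach_fraction * cell["baseline_f"]
                     * np.exp(-t / config.bleach_tau_s)
                     + config.background_au)
            repeats = [clean + rng.normal(0.0, cell["noise_sd"], size=len(t))
                       if cell["noise_sd"] > 0 else clean.copy()
                       for _ in range(config.n_repeats)]
            sweep_sets.append(SweepSet(
                cell_id=cell["cell_id"], odor_id=odor_id, repeats=repeats,
                timing=timing, soma_area_um2=cell["soma_area_um2"],
                background=config.background_au))

    gt = pd.DataFrame(gt_rows, columns=["cell_id", "odor_id", "type",
                                        "true_latency_s", "true_amplitude",
                                        "true_decay_s"])
    return sweep_sets, gt


# ---------------------------------------------------------------------------
# action-potential simulation


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class APSimConfig:
    """Analytic single-spike waveform with monophasic or biphasic onset.

    The somatic depolarisation is a logistic rise; a repolarising logistic
    plus a slow recovery component shape the downstroke and
    afterhyperpolarisation.  The biphasic kind prepends a small
    exponential-onset component (membrane potential following
    ``-k*ln(1 - t/tau)`` up to a cap), the waveform signature of a spike
    arriving from the axon initial segment: in the phase plane its dV/dt
    grows exponentially with voltage, producing the sharp first bump and an
    inflection before the somatic peak.  A monophasic spike has no such
    component and its phase-plane onset is smooth.
    """

    kind: Literal["monophasic", "biphasic"] = "monophasic"
    sample_interval_s: float = 5e-6
    duration_s: float = 0.012
    rest_mV: float = -75.0
    onset_ms: float = 2.0
    soma_amp_mV: float | None = None
    soma_slope_ms: float | None = None
    ais_amp_mV: float = 6.0
    ais_k_mV: float = 0.9
    ais_dvdt0_V_per_s: float = 0.5
    handover_delay_ms: float = 0.8
    ahp_depth_mV: float = 20.0
    repol_delay_ms: float = 1.5
    repol_slope_ms: float = 0.3
    recovery_delay_ms: float = 5.0
    recovery_slope_ms: float = 2.0
    noise_sd_mV: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_interval_s <= 0:
            raise ConfigurationError("sample interval must be positive")
        if self.kind not in ("monophasic", "biphasic"):
            raise ConfigurationError(f"unknown AP kind {self.kind!r}")
        if self.soma_amp_mV is None:
            object.__setattr__(self, "soma_amp_mV",
                               105.0 if self.kind == "monophasic" else 95.0)
        if self.soma_slope_ms is None:
            object.__setattr__(self, "soma_slope_ms",
                               0.23 if self.kind == "monophasic" else 0.16)
        total = self.soma_amp_mV + (self.ais_amp_mV
                                    if self.kind == "biphasic" else 0.0)
        if self.rest_mV + total <= 0:
            raise ConfigurationError("simulated peak Vm must exceed 0 mV")

    @property
    def _ais_cap_ms(self) -> float:
        """Time for the exponential-onset component to reach its cap."""
        tau = self.ais_k_mV / self.ais_dvdt0_V_per_s  # mV / (mV/ms) = ms
        return tau * (1.0 - math.exp(-self.ais_amp_mV / self.ais_k_mV))

    @property
    def _soma_centre_ms(self) -> float:
        if self.kind == "monophasic":
            return self.onset_ms
        return self.onset_ms + self._ais_cap_ms + self.handover_delay_ms

    def waveform(self, t_s: np.ndarray) -> np.ndarray:
        """Noiseless membrane potential at arbitrary times (mV)."""
        t_ms = np.asarray(t_s, dtype=float) * 1e3
        v = np.full_like(t_ms, self.rest_mV)
        total = self.soma_amp_mV
        if self.kind == "biphasic":
            tau = self.ais_k_mV / self.ais_dvdt0_V_per_s
            s = t_ms - self.onset_ms
            frac = np.clip(s / tau, 0.0, 1.0 - 1e-12)
            ais = np.where(s <= 0, 0.0,
                           np.minimum(-self.ais_k_mV * np.log1p(-frac),
                                      self.ais_amp_mV))
            v = v + ais
            total += self.ais_amp_mV
        centre = self._soma_centre_ms
        v = v + self.soma_amp_mV * _sigmoid((t_ms - centre) / self.soma_slope_ms)
        repol = total + self.ahp_depth_mV
        v = v - repol * _sigmoid(
            (t_ms - centre - self.repol_delay_ms) / self.repol_slope_ms)
        v = v + self.ahp_depth_mV * _sigmoid(
            (t_ms - centre - self.recovery_delay_ms) / self.recovery_slope_ms)
        return v


def gen_ap_sweep(config: APSimConfig) -> VoltageSweep:
    """Simulate one single-spike sweep at high temporal resolution."""
    n = int(round(config.duration_s / config.sample_interval_s))
    t = np.arange(n) * config.sample_interval_s
    v = config.waveform(t)
    if config.noise_sd_mV > 0:
        rng = np.random.default_rng(config.rng_seed)
        v = v + rng.normal(0.0, config.noise_sd_mV, size=n)
    return VoltageSweep(time_s=t, vm_mV=v,
                        sample_interval_s=config.sample_interval_s,
                        kind=config.kind)


def sample_ap_config(kind: Literal["monophasic", "biphasic"],
                     rng: np.random.Generator,
                     jitter: float = 0.08,
                     noise_sd_mV: float = 0.0) -> APSimConfig:
    """Draw a cell-to-cell variant of the default waveform of one kind.

    Waveform shape parameters are scaled by independent multiplicative
    factors ``1 + jitter*N(0,1)`` (clipped at +/-2.5 SD).
    """

    def f() -> float:
        return 1.0 + jitter * float(np.clip(rng.standard_normal(), -2.0, 2.0))

    base = APSimConfig(kind=kind)
    return replace(
        base,
        soma_amp_mV=base.soma_amp_mV * f(),
        soma_slope_ms=base.soma_slope_ms * max(f(), 0.5),
        ais_amp_mV=base.ais_amp_mV * f(),
        ais_k_mV=base.ais_k_mV * max(f(), 0.5),
        rest_mV=base.rest_mV + 3.0 * (f() - 1.0) / max(jitter, 1e-9),
        noise_sd_mV=noise_sd_mV,
        rng_seed=int(rng.integers(0, 2**31 - 1)))


# ---------------------------------------------------------------------------
# current-step protocol


@dataclass(frozen=True)
class StepProtocolConfig:
    """500 ms current-step family with a configured count rule.

    The ground-truth spike-count rule is monotone then saturating:
    ``min(max_spikes, 1 + floor(spikes_per_pA * (I - rheobase_pA)))`` for
    currents at or above rheobase, zero below; a custom ``count_rule``
    callable (pA -> count) overrides it.
    """

    sample_interval_s: float = 2e-5
    step_onset_s: float = 0.1
    step_duration_s: float = 0.5
    total_duration_s: float = 0.7
    rest_mV: float = -70.0
    plateau_mV: float = -55.0
    rheobase_pA: float = 20.0
    spikes_per_pA: float = 0.25
    max_spikes: int = 20
    first_spike_delay_s: float = 0.02
    jitter_s: float = 0.0
    count_rule: Callable[[float], int] | None = None
    rng_seed: int = 0

    def spike_count(self, current_pA: float) -> int:
        if self.count_rule is not None:
            return int(self.count_rule(current_pA))
        if current_pA < self.rheobase_pA:
            return 0
        return min(self.max_spikes,
                   1 + int(math.floor(self.spikes_per_pA
                                      * (current_pA - self.rheobase_pA))))


def _spike_template(t_s: np.ndarray, t0: float) -> np.ndarray:
    """A 1.5 ms triangular spike transient peaking 95 mV above baseline."""
    rise, fall = 5e-4, 1e-3
    s = t_s - t0
    up = np.clip(s / rise, 0.0, 1.0)
    down = np.clip(1.0 - (s - rise) / fall, 0.0, 1.0)
    return 95.0 * np.where(s < rise, up, np.where(s < rise + fall, down, 0.0))


def gen_step_protocol(config: StepProtocolConfig,
                      step_increment_pA: float,
                      n_steps: int,
                      capacitance_pF: float) -> list[VoltageSweep]:
    """Simulate a family of 500 ms steps of increasing current from 0 pA."""
    if n_steps < 1:
        raise ConfigurationError("need at least one step")
    rng = np.random.default_rng(config.rng_seed)
    n = int(round(config.total_duration_s / config.sample_interval_s))
    t = np.arange(n) * config.sample_interval_s
    in_step = (t >= config.step_onset_s) & (t < config.step_onset_s
                                            + config.step_duration_s)
    sweeps = []
    for j in range(n_steps):
        current = j * step_increment_pA
        count = config.spike_count(current)
        v = np.full(n, config.rest_mV)
        if current > 0:
            depol = (config.plateau_mV - config.rest_mV) * min(
                current / max(config.rheobase_pA, 1e-9), 1.0)
            v = v + np.where(in_step, depol, 0.0)
        if count > 0:
            avail = config.step_duration_s - config.first_spike_delay_s - 2e-3
            isi = avail / count
            for k in range(count):
                t0 = (config.step_onset_s + config.first_spike_delay_s
                      + k * isi)
                if config.jitter_s > 0:
                    t0 += float(np.clip(rng.normal(0.0, config.jitter_s),
                                        -isi / 3, isi / 3))
                v = v + _spike_template(t, t0)
        sweeps.append(VoltageSweep(
            time_s=t, vm_mV=v, sample_interval_s=config.sample_interval_s,
            injected_current_pA=current, capacitance_pF=capacitance_pF,
            step_onset_s=config.step_onset_s,
            step_duration_s=config.step_duration_s, kind="step"))
    return sweeps


# ---------------------------------------------------------------------------
# neurite trees


def gen_neurite_tree(branches: Sequence[np.ndarray] | Sequence[Sequence],
                     soma_xy: Sequence[float] = (0.0, 0.0)) -> NeuriteTree:
    """Build a tree from a branch plan of polylines.

    Each polyline must start at the soma centre or at a node of an earlier
    branch; anything else raises a structural error.  An empty plan yields a
    soma-only tree.
    """
    soma = np.asarray(soma_xy, dtype=float).reshape(2)
    polylines = [np.asarray(b, dtype=float).reshape(-1, 2) for b in branches]
    known = [soma]
    for i, b in enumerate(polylines):
        if len(b) < 2:
            raise ValueError(f"branch {i} needs at least two nodes")
        start = b[0]
        if not any(np.allclose(start, k, atol=1e-9) for k in known):
            raise ValueError(
                f"branch {i} is disconnected: start {start} matches no node")
        known.extend(b)
    return NeuriteTree(soma_xy=soma, branches=polylines)


def gen_random_tree(n_branches: int = 6,
                    segment_length_um: float = 6.0,
                    n_segments: tuple[int, int] = (3, 10),
                    rng_seed: int = 0) -> NeuriteTree:
    """A random planar tree for oracle cross-checks.

    Branches grow outward as persistent random walks; later branches may
    attach at a node of an earlier branch.
    """
    rng = np.random.default_rng(rng_seed)
    soma = np.zeros(2)
    branches: list[np.ndarray] = []
    attach_points = [soma]
    for _ in range(n_branches):
        start = attach_points[rng.integers(len(attach_points))]
        heading = rng.uniform(0, 2 * np.pi)
        pts = [start.copy()]
        for _ in range(int(rng.integers(n_segments[0], n_segments[1] + 1))):
            heading += rng.normal(0.0, 0.5)
            step = segment_length_um * np.array([np.cos(heading), np.sin(heading)])
            pts.append(pts[-1] + step)
        b = np.asarray(pts)
        branches.append(b)
        attach_points.extend(list(b[1:]))
    return NeuriteTree(soma_xy=soma, branches=branches)


# ---------------------------------------------------------------------------
# soma-size mixture and feature tables


@dataclass(frozen=True)
class SomaMixture:
    """Two-component normal mixture of soma areas (um^2).

    Defaults put the component modes at 55 and 140 um^2 (the small- and
    big-cell peaks of the overall population), with most mass small.
    """

    weights: tuple[float, float] = (0.85, 0.15)
    means_um2: tuple[float, float] = (55.0, 140.0)
    sds_um2: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError("component weights must sum to 1")
        if any(w < 0 for w in self.weights) or any(s < 0 for s in self.sds_um2):
            raise ConfigurationError("weights and SDs must be nonnegative")


@dataclass
class SomaPopulation:
    areas_um2: np.ndarray
    labels: np.ndarray  # 0 = small component, 1 = big component


def gen_soma_population(mix: SomaMixture = SomaMixture(),
                        n: int = 500,
                        seed: int = 0) -> SomaPopulation:
    """Draw soma areas from the mixture with ground-truth component labels."""
    rng = np.random.default_rng(seed)
    labels = (rng.uniform(size=n) >= mix.weights[0]).astype(int)
    areas = np.where(labels == 0,
                     rng.normal(mix.means_um2[0], mix.sds_um2[0], size=n),
                     rng.normal(mix.means_um2[1], mix.sds_um2[1], size=n))
    return SomaPopulation(areas_um2=areas, labels=labels)


def gen_feature_table(class_params: dict[str, dict[str, tuple[float, float]]]
                      | None = None,
                      n_per_class: int = 13,
                      seed: int = 0,
                      sd_scale: float = 1.0,
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Two labelled clusters of the five classification variables.

    Defaults centre on the monophasic/biphasic class means with their
    standard errors as spreads, giving well-separated clusters; ``sd_scale``
    inflates the spreads (e.g. 5x for overlap experiments).  Labels are 0
    for monophasic, 1 for biphasic.
    """
    params = class_params if class_params is not None else TABLE_FEATURE_PARAMS
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for label, cname in enumerate(params):
        for _ in range(n_per_class):
            row = {}
            for col in FEATURE_COLUMNS:
                mean, sd = params[cname][col]
                val = rng.normal(mean, sd * sd_scale)
                if col == "onset_rapidness_per_ms":
                    val = max(val, 0.05)
                if col == "max_spikes":
                    val = max(round(val), 0)
                row[col] = val
            rows.append(row)
            labels.append(label)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS), np.asarray(labels)
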