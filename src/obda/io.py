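"""Plain-text readers and writers for the package's data formats.

GCaMP fields of view travel as a wide TSV (one time column plus one column
per ROI; rows are the 24 trials concatenated in acquisition order) with a
JSON sidecar holding trial timing, trial order, ROI soma areas and the
background.  Voltage sweeps travel as two-column TSV (time_s, vm_mV) with a
JSON sidecar of stimulus metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import VoltageSweep
from .imaging import SweepSet, TrialTiming

__all__ = [
    "write_gcamp_fov",
    "read_gcamp_fov",
    "write_sweep",
    "read_sweep",
]


def write_gcamp_fov(sweep_sets: list[SweepSet],
                    traces_path: str | Path,
                    meta_path: str | Path) -> None:
    """Write a field of view as wide TSV + JSON sidecar.

    Trials are ordered block by block (all odours once per block), matching
    the acquisition protocol; the sidecar records the per-trial odour ids.
    """
    if not sweep_sets:
        raise ValueError("empty field of view")
    timing = sweep_sets[0].timing
    by_cell: dict[str, dict[str, SweepSet]] = {}
    odor_ids: list[str] = []
    for ss in sweep_sets:
        by_cell.setdefault(ss.cell_id, {})[ss.odor_id] = ss
        if ss.odor_id not in odor_ids:
            odor_ids.append(ss.odor_id)
    cells = list(by_cell)
    n_repeats = len(sweep_sets[0].repeats)

    trial_odors = odor_ids * n_repeats          # block-major order
    nf = timing.n_frames
    cols: dict[str, np.ndarray] = {
        "time_s": np.tile(timing.frame_times, len(trial_odors))}
    for cell in cells:
        chunks = []
        for rep in range(n_repeats):
            for odor in odor_ids:
                chunks.append(np.asarray(by_cell[cell][odor].repeats[rep]))
        cols[cell] = np.concatenate(chunks)
    pd.DataFrame(cols).to_csv(traces_path, sep="\t", index=False,
                              float_format="%.6f")

    bg = sweep_sets[0].background
    meta = {
        "frame_rate_hz": timing.frame_rate_hz,
        "odor_onset_s": timing.odor_onset_s,
        "odor_duration_s": timing.odor_duration_s,
        "sweep_duration_s": timing.sweep_duration_s,
        "n_repeats": n_repeats,
        "trial_odors": trial_odors,
        "rois": {c: by_cell[c][odor_ids[0]].soma_area_um2 for c in cells},
        "background": None if bg is None else float(np.asarray(bg).mean()
                                                    if np.ndim(bg) else bg),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_gcamp_fov(traces_path: str | Path,
                   meta_path: str | Path) -> list[SweepSet]:
    meta = json.loads(Path(meta_path).read_text())
    timing = TrialTiming(
        frame_rate_hz=meta["frame_rate_hz"], odor_onset_s=meta["odor_onset_s"],
        odor_duration_s=meta["odor_duration_s"],
        sweep_duration_s=meta["sweep_duration_s"])
    df = pd.read_csv(traces_path, sep="\t")
    nf = timing.n_frames
    trial_odors = meta["trial_odors"]
    if len(df) != nf * len(trial_odors):
        raise ValueError("trace table length does not match sidecar timing")

    sweep_sets = []
    for cell, area in meta["rois"].items():
        values = df[cell].to_numpy(dtype=float)
        per_odor: dict[str, list[np.ndarray]] = {}
        for k, odor in enumerate(trial_odors):
            per_odor.setdefault(odor, []).append(values[k * nf:(k + 1) * nf])
        for odor, repeats in per_odor.items():
            sweep_sets.append(SweepSet(
                cell_id=cell, odor_id=odor, repeats=repeats, timing=timing,
                soma_area_um2=float(area), background=meta.get("background")))
    return sweep_sets


def write_sweep(sweep: VoltageSweep, tsv_path: str | Path,
                meta_path: str | Path | None = None) -> None:
    pd.DataFrame({"time_s": sweep.time_s, "vm_mV": sweep.vm_mV}).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.9g")
    if meta_path is not None:
        meta = {
            "sample_interval_s": sweep.sample_interval_s,
            "injected_current_pA": sweep.injected_current_pA,
            "capacitance_pF": sweep.capacitance_pF,
            "step_onset_s": sweep.step_onset_s,
            "step_duration_s": sweep.step_duration_s,
            "kind": sweep.kind,
        }
        Path(meta_path).write_text(json.dumps(
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in meta.items()}, indent=1))


def read_sweep(tsv_path: str | Path,
               meta_path: str | Path | None = None) -> VoltageSweep:
    df = pd.read_csv(tsv_path, sep="\t")
    t = df["time_s"].to_numpy(dtype=float)
    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())

    def _num(key, default):
        v = meta.get(key)
        return default if v is None else float(v)

    dt = _num("sample_interval_s", float(np.median(np.diff(t))) if len(t) > 1
              else float("nan"))
    return VoltageSweep(
        time_s=t, vm_mV=df["vm_mV"].to_numpy(dtype=float),
        sample_interval_s=dt,
        injected_current_pA=_num("injected_current_pA", float("nan")),
        capacitance_pF=_num("capacitance_pF", float("nan")),
        step_onset_s=_num("step_onset_s", 0.0),
        step_duration_s=_num("step_duration_s", float("nan")),
        kind=meta.get("kind"))
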