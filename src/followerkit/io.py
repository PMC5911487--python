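"""Readers and writers for recordings, thresholds and results.

On-disk layouts
---------------
HDF5 container (one FOV per file)::

    /traces                cells x frames, float64, 1 + dF/F scale
    /schedule/onsets       seconds
    /schedule/offsets      seconds
    /cell_positions        optional, (cells, 2) micrometers
    /interneuron_flags     optional, bool per cell
    attrs: frame_rate, condition_label, patched_cell (-1 when absent)

Ground truth (synthetic recordings only) goes to a ``<stem>.ground_truth.json``
sidecar.  The flat-CSV alternative is a traces matrix plus a schedule table
with columns ``onset_s,offset_s`` and a small JSON metadata sidecar.

Results are a TSV (cell_id, mean_z, label, n_trials, threshold_upper,
threshold_lower, threshold_mode, seed) plus JSON run metadata (config hash,
package version).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .data import MIN_TRIAL_GAP_S, FovRecording, StimSchedule
from .exceptions import SchemaError
from .follower_stats import MeanZResult, Thresholds

__all__ = [
    "write_recording",
    "read_recording",
    "write_recording_csv",
    "read_recording_csv",
    "write_results",
    "read_results",
    "write_thresholds",
    "read_thresholds",
]


def _gt_path(path: Path) -> Path:
    return path.with_suffix(".ground_truth.json")


def _check_gaps(schedule: StimSchedule, origin: str):
    gap = schedule.min_gap()
    if gap < MIN_TRIAL_GAP_S:
        warnings.warn(
            f"{origin}: smallest inter-trial gap is {gap:g} s (< "
            f"{MIN_TRIAL_GAP_S:g} s); calcium transients may not return to "
            f"baseline between trials",
            stacklevel=3,
        )


def write_recording(rec: FovRecording, path) -> Path:
    """Write a FOV recording as an HDF5 container (+ ground-truth sidecar)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces)
        g = f.create_group("schedule")
        g.create_dataset("onsets", data=rec.schedule.onsets)
        g.create_dataset("offsets", data=rec.schedule.offsets)
        if rec.cell_positions is not None:
            f.create_dataset("cell_positions", data=rec.cell_positions)
        if rec.interneuron_flags is not None:
            f.create_dataset("interneuron_flags", data=rec.interneuron_flags)
        f.attrs["frame_rate"] = rec.frame_rate
        f.attrs["condition_label"] = rec.condition_label
        f.attrs["patched_cell"] = -1 if rec.patched_cell is None else rec.patched_cell
    if rec.ground_truth is not None:
        gt = {
            "efficacy": np.asarray(rec.ground_truth["efficacy"]).tolist(),
            "spikes": np.asarray(rec.ground_truth["spikes"]).tolist(),
            "inserted_trials": [
                np.asarray(t).tolist()
                for t in rec.ground_truth.get("inserted_trials", [])
            ],
        }
        _gt_path(path).write_text(json.dumps(gt))
    return path


def read_recording(path, raw_fluorescence: bool = False) -> FovRecording:
    """Read an HDF5 FOV recording.

    ``raw_fluorescence=True`` rescales the traces by their per-cell session
    mean, bringing raw-F inputs onto the package's ``1 + dF/F``-like positive
    scale (the per-trial ratio response is invariant under this rescaling).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("traces", "schedule/onsets", "schedule/offsets"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset /{name}")
        traces = f["traces"][()]
        schedule = StimSchedule(
            onsets=f["schedule/onsets"][()], offsets=f["schedule/offsets"][()]
        )
        positions = f["cell_positions"][()] if "cell_positions" in f else None
        flags = f["interneuron_flags"][()] if "interneuron_flags" in f else None
        frame_rate = float(f.attrs["frame_rate"])
        label = str(f.attrs.get("condition_label", "sham"))
        patched = int(f.attrs.get("patched_cell", -1))
    _check_gaps(schedule, str(path))
    if raw_fluorescence:
        traces = traces / traces.mean(axis=1, keepdims=True)
    ground_truth = None
    gt_path = _gt_path(path)
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        ground_truth = {
            "efficacy": np.asarray(raw["efficacy"], dtype=float),
            "spikes": np.asarray(raw["spikes"], dtype=float),
            "inserted_trials": [
                np.asarray(t, dtype=int) for t in raw.get("inserted_trials", [])
            ],
        }
    return FovRecording(
        traces=traces,
        frame_rate=frame_rate,
        schedule=schedule,
        patched_cell=None if patched < 0 else patched,
        cell_positions=positions,
        interneuron_flags=flags,
        condition_label=label,
        ground_truth=ground_truth,
    )


def write_recording_csv(rec: FovRecording, traces_path, schedule_path,
                        meta_path) -> None:
    """Flat-CSV alternative: traces matrix, schedule table, JSON metadata."""
    np.savetxt(traces_path, rec.traces, delimiter=",", fmt="%.17g")
    pd.DataFrame(
        {"onset_s": rec.schedule.onsets, "offset_s": rec.schedule.offsets}
    ).to_csv(schedule_path, index=False)
    Path(meta_path).write_text(
        json.dumps(
            {
                "frame_rate": rec.frame_rate,
                "condition_label": rec.condition_label,
                "patched_cell": rec.patched_cell,
            }
        )
    )


def read_recording_csv(traces_path, schedule_path, meta_path) -> FovRecording:
    traces = np.atleast_2d(np.loadtxt(traces_path, delimiter=","))
    sched_df = pd.read_csv(schedule_path)
    for col in ("onset_s", "offset_s"):
        if col not in sched_df.columns:
            raise SchemaError(f"{schedule_path}: missing column {col}")
    schedule = StimSchedule(
        onsets=sched_df["onset_s"].to_numpy(),
        offsets=sched_df["offset_s"].to_numpy(),
    )
    meta = json.loads(Path(meta_path).read_text())
    _check_gaps(schedule, str(schedule_path))
    return FovRecording(
        traces=traces,
        frame_rate=float(meta["frame_rate"]),
        schedule=schedule,
        patched_cell=meta.get("patched_cell"),
        condition_label=meta.get("condition_label", "sham"),
    )


def write_results(
    results: list[MeanZResult],
    path,
    seed: int | None = None,
    config: AnalysisConfig | None = None,
) -> Path:
    """Write per-cell results as TSV plus a JSON run-metadata sidecar."""
    path = Path(path)
    thr = results[0].thresholds if results else None
    pd.DataFrame(
        {
            "cell_id": [r.cell for r in results],
            "mean_z": [r.mean_z for r in results],
            "label": [r.label for r in results],
            "n_trials": [r.n_trials for r in results],
            "threshold_upper": [r.thresholds.upper for r in results],
            "threshold_lower": [r.thresholds.lower for r in results],
            "threshold_mode": [r.thresholds.provenance for r in results],
            "seed": [seed for _ in results],
        }
    ).to_csv(path, sep="\t", index=False)
    meta = {
        "package_version": __version__,
        "seed": seed,
        "thresholds": None
        if thr is None
        else {"upper": thr.upper, "lower": thr.lower, "mode": thr.provenance},
        "config": config.to_dict() if config is not None else None,
        "config_hash": config.hash() if config is not None else None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "mean_z", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
    return df


def write_thresholds(thr: Thresholds, path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {"upper": thr.upper, "lower": thr.lower, "provenance": thr.provenance}
        )
    )
    return path


def read_thresholds(path) -> Thresholds:
    raw = json.loads(Path(path).read_text())
    for key in ("upper", "lower"):
        if key not in raw:
            raise SchemaError(f"{path}: missing key {key}")
    return Thresholds(
        upper=float(raw["upper"]),
        lower=float(raw["lower"]),
        provenance=raw.get("provenance", "recalibrated"),
    )
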