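"""Shared file I/O: marker tracks, TRC, NIfTI volumes + sidecars, reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .relaxometry import EchoVolume

__all__ = [
    "write_marker_tracks",
    "read_marker_tracks",
    "read_trc",
    "write_echo_volume",
    "read_echo_volume",
    "write_json",
    "read_json",
    "write_dof_csv",
]


def _track_columns(labels):
    cols = ["frame", "time_s"]
    for lab in labels:
        cols += [f"{lab}_x", f"{lab}_y", f"{lab}_z"]
    return cols


def write_marker_tracks(path, times: np.ndarray, tracks: np.ndarray, labels) -> None:
    """Delimited marker file: ``frame,time_s,<marker>_x,<marker>_y,<marker>_z,...`` (mm)."""
    n_frames, n_markers, _ = tracks.shape
    if len(labels) != n_markers:
        raise ValueError("label count mismatch")
    flat = tracks.reshape(n_frames, n_markers * 3)
    df = pd.DataFrame(flat, columns=_track_columns(labels)[2:])
    df.insert(0, "time_s", times)
    df.insert(0, "frame", np.arange(n_frames))
    df.to_csv(path, index=False, float_format="%.6f")


def read_marker_tracks(path):
    """Returns ``(times, tracks (n, m, 3), labels)``."""
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy()
    coord_cols = [c for c in df.columns if c not in ("frame", "time_s")]
    labels = []
    for c in coord_cols[::3]:
        if not c.endswith("_x"):
            raise ValueError(f"unexpected column order near {c!r}")
        labels.append(c[:-2])
    tracks = df[coord_cols].to_numpy().reshape(len(df), len(labels), 3)
    return times, tracks, labels


def read_trc(path):
    """Minimal TRC reader (tab-delimited Motion Analysis convention), mm.

    Returns ``(times, tracks (n, m, 3), labels)``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header_idx = next(i for i, ln in enumerate(lines) if ln.startswith("Frame#"))
    fields = lines[header_idx].split("\t")
    labels = [f for f in fields[2:] if f.strip()]
    data = []
    for ln in lines[header_idx + 2 :]:
        parts = ln.split("\t")
        if len(parts) < 2 or not parts[0].strip():
            continue
        data.append([float(x) if x.strip() else np.nan for x in parts])
    arr = np.asarray(data)
    times = arr[:, 1]
    tracks = arr[:, 2 : 2 + 3 * len(labels)].reshape(len(arr), len(labels), 3)
    return times, tracks, labels


def write_echo_volume(base_path, volume: EchoVolume) -> None:
    """NIfTI-1 volume (4th dim = echo) plus a JSON sidecar with echo times."""
    base = Path(base_path)
    img = nib.Nifti1Image(volume.grid.astype(np.float32), volume.affine)
    nib.save(img, str(base.with_suffix(".nii")))
    write_json(
        base.with_suffix(".json"),
        {"echo_times_ms": list(map(float, volume.echo_times)),
         "voxel_size_mm": list(map(float, volume.voxel_size))},
    )


def read_echo_volume(base_path) -> EchoVolume:
    base = Path(base_path)
    img = nib.load(str(base.with_suffix(".nii")))
    side = read_json(base.with_suffix(".json"))
    grid = np.asarray(img.dataobj, dtype=np.float64)
    if grid.ndim != 4:
        raise ValueError("expected a 4-D multi-echo NIfTI")
    if len(side["echo_times_ms"]) != grid.shape[3]:
        raise ValueError("echo count mismatch between NIfTI and sidecar")
    return EchoVolume(
        grid,
        echo_times=np.asarray(side["echo_times_ms"], dtype=float),
        affine=np.asarray(img.affine, dtype=float),
        voxel_size=tuple(side.get("voxel_size_mm", (1.0, 1.0, 1.0))),
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_dof_csv(path, values: np.ndarray, frame_rate: float = 120.0) -> None:
    """DOF trace CSV (mm and degrees) with a units comment header."""
    from .kinematics import DOF_NAMES

    df = pd.DataFrame(values, columns=list(DOF_NAMES))
    df.insert(0, "frame", np.arange(len(df)))
    with open(path, "w") as fh:
        fh.write(f"# translations mm, rotations deg, frame rate {frame_rate} Hz\n")
        df.to_csv(fh, index=False, float_format="%.8f")
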