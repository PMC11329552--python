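"""Disk formats: ASCII PLY point-cloud frames, CSV traces, PNG masks.

A dataset directory contains per-frame PLY files with a ``frames.csv``
manifest (frame_id, timestamp_s, path), traces as CSV
(timestamp_s, si_mm[, ap_mm]), masks as 8-bit PNG (0/255) with their own
manifest, and a ``dataset.json`` with the generation parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import trimesh

from .errors import InvalidArgumentError
from .signals import DisplacementTrace
from .surrogate import SurrogateSeries, TimedPointCloud
from .ustrack import BinaryMask

__all__ = [
    "write_cloud_sequence",
    "read_cloud_sequence",
    "write_trace",
    "read_trace",
    "write_mask_sequence",
    "read_mask_sequence",
    "write_surrogate_series",
    "read_surrogate_series",
    "write_manifest",
]


def write_cloud_sequence(clouds: list[TimedPointCloud], out_dir) -> Path:
    """Write ASCII PLY frames plus a ``frames.csv`` manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cloud in clouds:
        name = f"frame_{cloud.frame_id:05d}.ply"
        trimesh.PointCloud(cloud.points).export(
            out_dir / name, file_type="ply", encoding="ascii"
        )
        rows.append(
            {"frame_id": cloud.frame_id, "timestamp_s": cloud.timestamp, "path": name}
        )
    manifest = out_dir / "frames.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cloud_sequence(manifest) -> list[TimedPointCloud]:
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    clouds = []
    for _, row in table.iterrows():
        mesh = trimesh.load(manifest.parent / row["path"])
        clouds.append(
            TimedPointCloud(
                points=np.asarray(mesh.vertices, dtype=float),
                timestamp=float(row["timestamp_s"]),
                frame_id=int(row["frame_id"]),
            )
        )
    return clouds


def write_trace(trace: DisplacementTrace, path) -> Path:
    path = Path(path)
    data = {"timestamp_s": trace.timestamps, "si_mm": trace.si_mm}
    if trace.ap_mm is not None:
        data["ap_mm"] = trace.ap_mm
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_trace(path) -> DisplacementTrace:
    table = pd.read_csv(path)
    if "timestamp_s" not in table or "si_mm" not in table:
        raise InvalidArgumentError("trace CSV needs timestamp_s and si_mm columns")
    return DisplacementTrace(
        timestamps=table["timestamp_s"].to_numpy(),
        si_mm=table["si_mm"].to_numpy(),
        ap_mm=table["ap_mm"].to_numpy() if "ap_mm" in table else None,
    )


def write_mask_sequence(masks: list[BinaryMask], out_dir) -> Path:
    """Write masks as 8-bit PNGs (0/255) plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for mask in masks:
        name = f"mask_{mask.frame_id:05d}.png"
        iio.imwrite(out_dir / name, (mask.data.astype(np.uint8) * 255))
        rows.append(
            {
                "frame_id": mask.frame_id,
                "timestamp_s": mask.timestamp,
                "path": name,
                "pixel_spacing_cm": mask.pixel_spacing,
            }
        )
    manifest = out_dir / "frames.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_mask_sequence(manifest) -> list[BinaryMask]:
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    masks = []
    for _, row in table.iterrows():
        img = iio.imread(manifest.parent / row["path"])
        masks.append(
            BinaryMask(
                data=img > 127,
                pixel_spacing=float(row["pixel_spacing_cm"]),
                timestamp=float(row["timestamp_s"]),
                frame_id=int(row["frame_id"]),
            )
        )
    return masks


def write_surrogate_series(series: SurrogateSeries, path) -> Path:
    """CSV of the surrogate plus a JSON sidecar with its conventions."""
    path = Path(path)
    pd.DataFrame(
        {"timestamp_s": series.timestamps, "surrogate_mm": series.values_mm}
    ).to_csv(path, index=False)
    sidecar = {
        "reference_frame_id": series.reference_frame_id,
        "signed": series.signed,
        "units": "mm",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_surrogate_series(path) -> SurrogateSeries:
    path = Path(path)
    table = pd.read_csv(path)
    kwargs = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kwargs = {
            "reference_frame_id": meta.get("reference_frame_id", 0),
            "signed": meta.get("signed", False),
        }
    return SurrogateSeries(
        timestamps=table["timestamp_s"].to_numpy(),
        values_mm=table["surrogate_mm"].to_numpy(),
        **kwargs,
    )


def write_manifest(path, **params) -> Path:
    """``dataset.json`` with every generation parameter."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    path.write_text(json.dumps(params, indent=2, default=_default))
    return path
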