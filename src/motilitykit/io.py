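"""Readers and writers for the standard on-disk formats.

Image stacks travel as multi-page grayscale TIFF (one page per frame)
with a YAML sidecar (``<stem>.meta.yaml``) carrying the frame interval,
pixel size, seed and any ground truth. Tracks travel as CSV with the
header ``track_id,frame,t_hours,x_px,y_px``. Times are hours and
positions pixels on disk; micrometer conversion happens in the analysis
layer only. Floating-point CSV output is formatted at fixed precision so
seeded reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from motilitykit.errors import FormatError, InputError
from motilitykit.scratch import ImageStack
from motilitykit.tracks import CellTrack

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "read_tracks",
    "write_tracks",
    "FLOAT_FORMAT",
]

logger = logging.getLogger("motilitykit")

FLOAT_FORMAT = "%.6f"

TRACK_COLUMNS = ["track_id", "frame", "t_hours", "x_px", "y_px"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def write_image_stack(
    stack: ImageStack,
    path: "str | Path",
    metadata: dict | None = None,
) -> Path:
    """Write a stack as 8-bit multi-page TIFF plus a YAML sidecar.

    Intensities are clipped to [0, 255] and rounded on export; keep
    analysis in memory when exact float math matters.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(stack.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "timestamps_hours": [float(t) for t in stack.timestamps],
        "pixel_size_um": stack.pixel_size,
        "well_id": stack.well_id,
    }
    if metadata:
        meta.update(metadata)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_image_stack(
    path: "str | Path",
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Timestamps come from the YAML sidecar when present, else are
    ``k * frame_interval``. Pages must be single-channel and share one
    shape; offending pages are named in the error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise FormatError(f"{path}: empty TIFF")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(f"{path}: page {i} is not single-channel grayscale")
        if page.shape != shape0:
            raise FormatError(
                f"{path}: page {i} has shape {page.shape}, expected {shape0}"
            )
    frames = np.stack(pages).astype(np.float64)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if "timestamps_hours" in meta:
        times = np.asarray(meta["timestamps_hours"], dtype=np.float64)
    else:
        if frame_interval is None:
            raise InputError(
                f"{path}: no sidecar timestamps; pass frame_interval explicitly"
            )
        times = np.arange(len(pages)) * frame_interval
    return ImageStack(
        frames=frames,
        timestamps=times,
        pixel_size=meta.get("pixel_size_um"),
        well_id=str(meta.get("well_id", path.stem)),
    )


def write_tracks(tracks: list[CellTrack], path: "str | Path") -> Path:
    """Write tracks as CSV with header track_id,frame,t_hours,x_px,y_px."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in tracks:
        for k in range(tr.n_points):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": k,
                    "t_hours": tr.t[k],
                    "x_px": tr.x[k],
                    "y_px": tr.y[k],
                }
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )
    return path


def read_tracks(path: "str | Path", pixel_size: float = 1.0) -> list[CellTrack]:
    """Read an ADAPT-style track CSV.

    Rows are grouped by ``track_id`` and sorted by time within a track;
    rows with missing coordinates are dropped (count logged). Duplicate
    ``(track_id, t_hours)`` rows are an input error naming the offenders.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    n_before = len(df)
    df = df.dropna(subset=["t_hours", "x_px", "y_px"])
    dropped = n_before - len(df)
    if dropped:
        logger.warning("DROPPED_ROWS file=%s count=%d reason=missing-coordinates",
                       path, dropped)
    dup = df.duplicated(subset=["track_id", "t_hours"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["track_id", "t_hours"]].drop_duplicates()
        raise InputError(
            f"{path}: duplicate (track_id, t_hours) rows: "
            + "; ".join(f"{r.track_id}@{r.t_hours}" for r in offenders.itertuples())
        )
    tracks = []
    for track_id, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("t_hours")
        tracks.append(
            CellTrack(
                track_id=str(track_id),
                t=sub["t_hours"].to_numpy(),
                x=sub["x_px"].to_numpy(),
                y=sub["y_px"].to_numpy(),
                pixel_size=pixel_size,
            )
        )
    return tracks


def dataclass_to_jsonable(obj) -> dict:
    """Dataclass -> plain dict with numpy arrays as lists (for JSON dumps)."""
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[f.name] = v
    return out
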