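"""Containers and file I/O for timelapse stacks, displacement fields and traces.

Image stacks travel as multi-page TIFF (one page per timepoint) with a JSON
sidecar carrying the physical metadata (``pixel_size_um``, ``frame_interval_h``
and, for synthetic data, the generator seed).  Tabular data (displacement
fields, series, creep traces, force curves, outlines) is plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageSequence",
    "DeformationTrace",
    "ForceCurve",
    "read_image_sequence",
    "write_image_sequence",
    "read_traces",
    "write_trace",
    "read_force_curve",
    "write_force_curve",
    "read_outlines",
    "write_outlines",
]


@dataclass
class ImageSequence:
    """Timed stack of 2-D frames with a physical pixel size.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, ny, nx)
        Intensity images, all the same shape.
    times : ndarray, shape (n_frames,)
        Acquisition times in hours, strictly increasing.
    pixel_size : float
        Lateral pixel size in micrometres per pixel.
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (n_frames, ny, nx) array")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DeformationTrace:
    """Optical-stretcher creep trace: relative deformation (strain) vs time."""

    times: np.ndarray  # s
    strain: np.ndarray  # dimensionless relative deformation
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.strain.shape:
            raise ValueError("times and strain must be 1-D and equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.strain)):
            raise ValueError("strain must be finite")


@dataclass
class ForceCurve:
    """AFM force-indentation curve (approach segment)."""

    indentation: np.ndarray  # um
    force: np.ndarray  # nN
    position: tuple[float, float] | None = None  # (x, y) um

    def __post_init__(self) -> None:
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.shape != self.force.shape:
            raise ValueError("indentation and force must be equal length")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force must be finite")


# ---------------------------------------------------------------------------
# Stacks


def write_image_sequence(seq: ImageSequence, tiff_path: str | Path) -> Path:
    """Write a multi-page TIFF plus a JSON sidecar next to it."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, seq.frames, photometric="minisblack")
    sidecar = {
        "pixel_size_um": float(seq.pixel_size),
        "times_h": [float(t) for t in seq.times],
        **{k: v for k, v in seq.meta.items() if _json_safe(v)},
    }
    if len(seq.times) > 1:
        sidecar["frame_interval_h"] = float(seq.times[1] - seq.times[0])
    side_path = tiff_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return side_path


def read_image_sequence(tiff_path: str | Path) -> ImageSequence:
    """Read a stack written by :func:`write_image_sequence`.

    Without a sidecar, a pixel size and frame interval of 1 are assumed and a
    warning is placed in ``meta``.
    """
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    side_path = tiff_path.with_suffix(".json")
    if side_path.exists():
        meta = json.loads(side_path.read_text())
        pixel_size = float(meta["pixel_size_um"])
        if "times_h" in meta:
            times = np.asarray(meta["times_h"], dtype=float)
        else:
            times = np.arange(len(frames)) * float(meta.get("frame_interval_h", 1.0))
    else:
        meta = {"warning": f"no sidecar found for {tiff_path.name}; assuming unit metadata"}
        pixel_size = 1.0
        times = np.arange(len(frames), dtype=float)
    return ImageSequence(frames=frames, times=times, pixel_size=pixel_size, meta=meta)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# Traces


def write_trace(trace: DeformationTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": trace.cell_id, "t_s": trace.times, "strain": trace.strain}
    ).to_csv(path, index=False, float_format="%.9g")


def read_traces(path: str | Path) -> list[DeformationTrace]:
    """Read per-cell creep traces from a CSV file or a directory of them.

    Expected columns: ``cell_id, t_s, strain``.  Rows that fail to parse are
    dropped (robustness against truncated exports); the count of dropped rows
    is recorded on each trace's ``meta``-free via a module-level warning.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    traces: list[DeformationTrace] = []
    for f in files:
        df = pd.read_csv(f, dtype={"cell_id": str})
        n_raw = len(df)
        for col in ("t_s", "strain"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df = df.dropna(subset=["t_s", "strain"])
        if len(df) < n_raw:
            import warnings

            warnings.warn(f"{f.name}: skipped {n_raw - len(df)} unparsable rows")
        for cid, sub in df.groupby("cell_id", sort=True):
            sub = sub.sort_values("t_s")
            traces.append(
                DeformationTrace(
                    times=sub["t_s"].to_numpy(),
                    strain=sub["strain"].to_numpy(),
                    cell_id=str(cid),
                )
            )
    return traces


# ---------------------------------------------------------------------------
# Force curves


def write_force_curve(curve: ForceCurve, path: str | Path) -> None:
    pd.DataFrame({"delta_um": curve.indentation, "force_nN": curve.force}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_force_curve(path: str | Path, position: tuple[float, float] | None = None) -> ForceCurve:
    df = pd.read_csv(path)
    return ForceCurve(
        indentation=df["delta_um"].to_numpy(),
        force=df["force_nN"].to_numpy(),
        position=position,
    )


# ---------------------------------------------------------------------------
# Outlines


def write_outlines(outlines: Sequence, path: str | Path) -> None:
    """Write cell outlines as long-format CSV (cell_id, frame_id, x_um, y_um)."""
    rows = []
    for o in outlines:
        for x, y in o.vertices:
            rows.append({"cell_id": o.cell_id, "frame_id": o.frame_id, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_outlines(path: str | Path) -> list:
    """Read outlines written by :func:`write_outlines` (or any CSV/JSON with
    cell_id, frame_id, x_um, y_um vertex rows in order)."""
    from .shape import CellOutline

    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [
            CellOutline(
                vertices=np.asarray(d["vertices"], dtype=float),
                cell_id=str(d.get("cell_id", i)),
                frame_id=int(d.get("frame_id", 0)),
            )
            for i, d in enumerate(data)
        ]
    df = pd.read_csv(path)
    outlines = []
    for (cid, fid), sub in df.groupby(["cell_id", "frame_id"], sort=True):
        outlines.append(
            CellOutline(
                vertices=sub[["x_um", "y_um"]].to_numpy(),
                cell_id=str(cid),
                frame_id=int(fid),
            )
        )
    return outlines
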