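"""Cell-covered area segmentation and the normalized equivalent spreading radius.

Cell escape from a spheroid or tumour explant is quantified through the area A
covered by the fluorescently labelled cells: the equivalent radius
R_eq = sqrt(A / pi) is computed per frame and normalized to its initial value,
so a compact aggregate stays at 1 while wetting (collective spreading) or
evaporation (single-cell escape) drives the curve upward.  All fluorescent
components above a minimum size count toward A — escaped single cells
included, which is what makes the metric sensitive to the evaporation regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .io import ImageSequence

__all__ = [
    "AreaMaskSeries",
    "SpreadingSeries",
    "segment_cell_area",
    "segment_sequence",
    "equivalent_radius",
    "spreading_curve",
    "spreading_rate",
    "rasterize_polygon_masks",
    "write_spreading_csv",
]


@dataclass
class AreaMaskSeries:
    """Per-frame boolean cell masks with physical metadata."""

    masks: np.ndarray  # (n, ny, nx) bool
    times: np.ndarray  # h
    pixel_size: float  # um/px

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.times = np.asarray(self.times, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def areas(self) -> np.ndarray:
        """Covered area per frame in um^2 (pixel count times pixel_size^2)."""
        return self.masks.sum(axis=(1, 2)) * self.pixel_size**2


@dataclass
class SpreadingSeries:
    times: np.ndarray  # h
    R_eq: np.ndarray  # um
    areas: np.ndarray  # um^2

    @property
    def R_eq0(self) -> float:
        return float(self.R_eq[0])

    @property
    def normalized(self) -> np.ndarray:
        return self.R_eq / self.R_eq0


def segment_cell_area(frame: np.ndarray, min_size: int = 9) -> np.ndarray:
    """Segment the cell-covered area of one fluorescence frame.

    Otsu threshold, morphological closing (disk radius 2), hole filling, then
    removal of components below ``min_size`` pixels.  All surviving components
    are kept so escaping single cells count toward the area.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("expected a single-channel 2-D frame")
    if np.ptp(frame) == 0:
        warnings.warn("constant frame: empty foreground")
        return np.zeros(frame.shape, dtype=bool)
    mask = frame > threshold_otsu(frame)
    if not mask.any():
        warnings.warn("empty foreground after thresholding")
        return mask
    mask = ndimage.binary_closing(mask, structure=disk(2))
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum(mask, labels, range(1, n + 1))
        small = np.flatnonzero(sizes < min_size) + 1
        mask[np.isin(labels, small)] = False
    return mask


def segment_sequence(seq: ImageSequence, min_size: int = 9) -> AreaMaskSeries:
    masks = np.stack([segment_cell_area(f, min_size=min_size) for f in seq.frames])
    return AreaMaskSeries(masks=masks, times=seq.times, pixel_size=seq.pixel_size)


def equivalent_radius(area: float) -> float:
    """R_eq = sqrt(A / pi); the radius of the circle with the covered area."""
    if np.any(np.asarray(area) < 0):
        raise ValueError("area must be non-negative")
    return np.sqrt(np.asarray(area) / math.pi)


def spreading_curve(mask_series: AreaMaskSeries) -> SpreadingSeries:
    """Equivalent radius per frame, normalized to the first frame."""
    if len(mask_series.masks) < 2:
        raise ValueError("need at least two frames")
    areas = mask_series.areas
    R = equivalent_radius(areas)
    if R[0] == 0:
        raise ValueError("empty first-frame mask: cannot normalize")
    return SpreadingSeries(times=mask_series.times, R_eq=R, areas=areas)


def spreading_rate(mask_series: AreaMaskSeries) -> float:
    """OLS slope of A(t)/A(0) versus time: the fractional area growth in 1/h."""
    t = mask_series.times
    if len(t) < 2:
        raise ValueError("need at least two frames")
    if np.ptp(t) == 0:
        raise ValueError("constant time vector")
    areas = mask_series.areas
    if areas[0] == 0:
        raise ValueError("empty first-frame mask")
    return float(np.polyfit(t, areas / areas[0], 1)[0])


def rasterize_polygon_masks(
    polygons: pd.DataFrame,
    shape: tuple[int, int],
    times: np.ndarray,
    pixel_size: float,
) -> AreaMaskSeries:
    """Rasterize hand-drawn boundary polygons (long CSV format) into masks.

    ``polygons`` columns: frame_index, vertex_x_um, vertex_y_um; one polygon
    per frame (explant boundaries traced by hand).
    """
    from skimage.draw import polygon as draw_polygon

    masks = np.zeros((len(times), *shape), dtype=bool)
    for fi, sub in polygons.groupby("frame_index", sort=True):
        fi = int(fi)
        if fi >= len(times):
            raise ValueError(f"frame_index {fi} outside sequence")
        rr, cc = draw_polygon(
            sub["vertex_y_um"].to_numpy() / pixel_size,
            sub["vertex_x_um"].to_numpy() / pixel_size,
            shape=shape,
        )
        masks[fi, rr, cc] = True
    return AreaMaskSeries(masks=masks, times=times, pixel_size=pixel_size)


def write_spreading_csv(series: SpreadingSeries, path) -> None:
    pd.DataFrame(
        {
            "t_h": series.times,
            "area_um2": series.areas,
            "req_um": series.R_eq,
            "req_norm": series.normalized,
        }
    ).to_csv(path, index=False, float_format="%.6g")
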