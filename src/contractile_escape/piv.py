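"""Particle image velocimetry for collagen displacement quantification.

Incremental displacement fields are estimated between consecutive frames by
windowed, mean-subtracted FFT cross-correlation with 3-point Gaussian subpixel
refinement, then summed per grid point into cumulative displacements, and
finally reduced to the mean cumulative displacement magnitude |u| over a
region of interest, normalized to the initial spheroid radius R0.

The interrogation grid is fixed in the laboratory frame: cumulative
displacement at a grid point is the sum of the incremental displacements
observed at that point, which is the Eulerian readout used for contracting
collagen gels (material slowly advects through the windows, but per-step
increments stay well below the window size).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ImageSequence

__all__ = [
    "PIVSettings",
    "DisplacementField",
    "DisplacementSeries",
    "SquareRoi",
    "explant_roi",
    "estimate_frame_displacement",
    "estimate_sequence",
    "accumulate",
    "displacement_curve",
    "displacement_rate",
    "piv_grid",
    "write_fields_csv",
    "read_fields_csv",
    "write_series_csv",
]


@dataclass(frozen=True)
class PIVSettings:
    """Interrogation settings.

    window : int
        Interrogation window side in pixels; power of two, >= 8.
    overlap : float
        Window overlap fraction in [0, 1).
    search_margin : int
        Maximum displacement magnitude searched, in pixels (per axis).
    subpixel : str
        "gaussian" (3-point, default) or "parabolic".
    outlier_threshold : float
        Normalized median test threshold (Westerweel–Scarano), default 2.0.
    """

    window: int = 32
    overlap: float = 0.5
    search_margin: int | None = None
    subpixel: str = "gaussian"
    outlier_threshold: float = 2.0
    passes: int = 3

    def __post_init__(self) -> None:
        if self.window < 8 or (self.window & (self.window - 1)) != 0:
            raise ValueError("window must be a power of two >= 8")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def step(self) -> int:
        return max(1, int(round(self.window * (1 - self.overlap))))


@dataclass
class DisplacementField:
    """Gridded displacement vectors in micrometres on a regular grid.

    ``grid_x``/``grid_y`` are 1-D window-centre coordinates (um); ``ux``/``uy``
    are (ny, nx) displacement components (um); ``valid`` flags vectors backed
    by an unambiguous correlation peak; ``imputed`` flags vectors replaced by
    the median of their neighbours (outliers) or zero-filled in accumulation.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    valid: np.ndarray
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = np.zeros_like(self.valid, dtype=bool)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)

    def same_grid(self, other: "DisplacementField") -> bool:
        return (
            self.grid_x.shape == other.grid_x.shape
            and self.grid_y.shape == other.grid_y.shape
            and np.allclose(self.grid_x, other.grid_x)
            and np.allclose(self.grid_y, other.grid_y)
        )


@dataclass
class DisplacementSeries:
    """Mean cumulative displacement magnitude |u| over time, and |u|/R0."""

    times: np.ndarray  # h
    mean_mag: np.ndarray  # um
    R0: float  # um
    roi: str = "fov"

    @property
    def normalized(self) -> np.ndarray:
        return self.mean_mag / self.R0


@dataclass(frozen=True)
class SquareRoi:
    """Axis-aligned square region of interest (physical units, um)."""

    center: tuple[float, float]
    side: float


def explant_roi(center: tuple[float, float], R0: float) -> SquareRoi:
    """Explant-mode ROI: square of side 3*R0 centred on the explant centroid."""
    return SquareRoi(center=center, side=3.0 * R0)


# ---------------------------------------------------------------------------
# Grid and windows


def piv_grid(shape: tuple[int, int], settings: PIVSettings, pixel_size: float = 1.0):
    """Window-centre coordinates (x, y in um) for an image of given shape."""
    w, s = settings.window, settings.step
    ys = np.arange(0, shape[0] - w + 1, s)
    xs = np.arange(0, shape[1] - w + 1, s)
    cy = (ys + (w - 1) / 2.0) * pixel_size
    cx = (xs + (w - 1) / 2.0) * pixel_size
    return cx, cy, xs, ys


def _window_stack(img: np.ndarray, xs: np.ndarray, ys: np.ndarray, w: int) -> np.ndarray:
    """All interrogation windows as a (n_windows, w, w) stack."""
    out = np.empty((len(ys), len(xs), w, w), dtype=np.float64)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            out[i, j] = img[y : y + w, x : x + w]
    return out.reshape(-1, w, w)


def _sample_windows_subset(img, xs, ys, w, off_x, off_y, subset):
    """Offset-sampled windows for a subset of the flattened window index."""
    from scipy import ndimage

    nx = len(xs)
    iy, ix = np.mgrid[0:w, 0:w]
    rows = np.empty((len(subset), w, w))
    cols = np.empty((len(subset), w, w))
    for k, s in enumerate(subset):
        i, j = divmod(s, nx)
        rows[k] = ys[i] + iy + off_y[s]
        cols[k] = xs[j] + ix + off_x[s]
    return ndimage.map_coordinates(
        img, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(-1, w, w)


def _correlation_peak(wa, wb, margin: int, subpixel: str):
    """Displacement of the unbiased cross-covariance peak for each window pair.

    The zero-padded linear correlation is divided by the lag overlap count,
    removing the triangular bias of the finite window; the peak is then
    refined with a three-point fit per axis.
    """
    w = wa.shape[-1]
    ma = wa.mean(axis=(1, 2), keepdims=True)
    mb = wb.mean(axis=(1, 2), keepdims=True)
    n = 2 * w
    fa = np.fft.rfft2(wa - ma, s=(n, n))
    fb = np.fft.rfft2(wb - mb, s=(n, n))
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(n, n))
    corr = np.fft.fftshift(corr, axes=(1, 2))  # zero displacement at (w, w)
    lags = np.arange(-w, w)
    overlap = np.maximum(w - np.abs(lags), 1).astype(np.float64)
    corr /= np.outer(overlap, overlap)

    margin = min(margin, w - 1)
    sub = corr[:, w - margin : w + margin + 1, w - margin : w + margin + 1]
    flat = sub.reshape(len(sub), -1)
    peak = np.argmax(flat, axis=1)
    side = 2 * margin + 1
    py, px = np.divmod(peak, side)
    dx = (px - margin).astype(np.float64)
    dy = (py - margin).astype(np.float64)

    interior = (px > 0) & (px < side - 1) & (py > 0) & (py < side - 1)
    idx = np.nonzero(interior)[0]
    if idx.size:
        c = sub[idx, py[idx], px[idx]]
        cl = sub[idx, py[idx], px[idx] - 1]
        cr = sub[idx, py[idx], px[idx] + 1]
        cu = sub[idx, py[idx] - 1, px[idx]]
        cd = sub[idx, py[idx] + 1, px[idx]]
        dx[idx] += _subpixel_offset(cl, c, cr, subpixel)
        dy[idx] += _subpixel_offset(cu, c, cd, subpixel)
    return dx, dy


def estimate_frame_displacement(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    settings: PIVSettings = PIVSettings(),
    pixel_size: float = 1.0,
) -> DisplacementField:
    """Estimate the displacement field from ``frame_a`` to ``frame_b``.

    Multi-pass interrogation with symmetric window offsets (central-difference
    scheme): the first pass locates the unbiased cross-covariance peak with a
    three-point subpixel fit; subsequent passes re-sample both windows offset
    by -d/2 and +d/2 so the residual displacement is measured near zero lag,
    where the subpixel estimator is most accurate.  Vectors failing the
    normalized median test are replaced by the median of their valid
    neighbours and flagged ``imputed``; (near-)constant windows are invalid.
    """
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have identical shapes")
    w = settings.window
    if min(frame_a.shape) < w:
        raise ValueError("frame smaller than interrogation window")
    cx, cy, xs, ys = piv_grid(frame_a.shape, settings, pixel_size)
    n_win = len(ys) * len(xs)

    wa0 = _window_stack(frame_a, xs, ys, w)
    wb0 = _window_stack(frame_b, xs, ys, w)
    valid = (wa0.std(axis=(1, 2)) > 1e-12) & (wb0.std(axis=(1, 2)) > 1e-12)

    margin0 = settings.search_margin or (w // 2 - 1)
    dx, dy = _correlation_peak(wa0, wb0, margin0, settings.subpixel)
    # Refine only windows with substantial displacement: for |d| < 0.5 px the
    # first-pass peak-centred fit is already unbiased, and the fractional
    # window resampling of the refinement would add interpolation bias.
    refine = (np.hypot(dx, dy) >= 0.5) & valid
    if refine.any():
        for _ in range(max(settings.passes - 1, 0)):
            sub = np.nonzero(refine)[0]
            wa = _sample_windows_subset(frame_a, xs, ys, w, -dx / 2, -dy / 2, sub)
            wb = _sample_windows_subset(frame_b, xs, ys, w, dx / 2, dy / 2, sub)
            rdx, rdy = _correlation_peak(wa, wb, 3, settings.subpixel)
            dx[sub] += rdx
            dy[sub] += rdy

    dx[~valid] = 0.0
    dy[~valid] = 0.0
    g = (len(ys), len(xs))
    ux = dx.reshape(g)
    uy = dy.reshape(g)
    valid = valid.reshape(g)

    ux, uy, outlier = _median_filter_outliers(ux, uy, valid, settings.outlier_threshold)

    return DisplacementField(
        grid_x=cx,
        grid_y=cy,
        ux=ux * pixel_size,
        uy=uy * pixel_size,
        valid=valid,
        imputed=outlier,
    )


def _subpixel_offset(cl, c, cr, method: str) -> np.ndarray:
    """Offset of the correlation maximum from three samples around the peak."""
    if method == "gaussian":
        # requires positive values; shift so the smallest neighbour is positive
        floor = np.minimum(np.minimum(cl, cr), c)
        shift = np.where(floor <= 0, -floor + 1e-12 + 1e-6 * np.abs(c), 0.0)
        l, m, r = np.log(cl + shift), np.log(c + shift), np.log(cr + shift)
    elif method == "parabolic":
        l, m, r = cl, c, cr
    else:
        raise ValueError(f"unknown subpixel method {method!r}")
    denom = l - 2 * m + r
    off = np.where(np.abs(denom) > 1e-300, 0.5 * (l - r) / denom, 0.0)
    return np.clip(off, -1.0, 1.0)


def _median_filter_outliers(ux, uy, valid, threshold: float, eps: float = 0.1):
    """Normalized median test; outliers replaced by valid-neighbour median."""
    ny, nx = ux.shape
    outlier = np.zeros_like(valid)
    med_x = np.full_like(ux, np.nan)
    med_y = np.full_like(uy, np.nan)
    res = np.zeros_like(ux)
    for i in range(ny):
        for j in range(nx):
            if not valid[i, j]:
                continue
            nbx, nby = [], []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < ny and 0 <= b < nx and valid[a, b]:
                        nbx.append(ux[a, b])
                        nby.append(uy[a, b])
            if len(nbx) < 3:
                continue
            nbx = np.asarray(nbx)
            nby = np.asarray(nby)
            mx, my = np.median(nbx), np.median(nby)
            med_x[i, j], med_y[i, j] = mx, my
            rm = np.median(np.hypot(nbx - mx, nby - my))
            res[i, j] = np.hypot(ux[i, j] - mx, uy[i, j] - my) / (rm + eps)
    bad = valid & (res > threshold)
    ux = ux.copy()
    uy = uy.copy()
    fixable = bad & np.isfinite(med_x)
    ux[fixable] = med_x[fixable]
    uy[fixable] = med_y[fixable]
    outlier[fixable] = True
    return ux, uy, outlier


def estimate_sequence(
    seq: ImageSequence, settings: PIVSettings = PIVSettings()
) -> list[DisplacementField]:
    """Incremental fields between all consecutive frame pairs of a sequence."""
    if len(seq) < 2:
        raise ValueError("need at least two frames")
    return [
        estimate_frame_displacement(seq.frames[k], seq.frames[k + 1], settings, seq.pixel_size)
        for k in range(len(seq) - 1)
    ]


# ---------------------------------------------------------------------------
# Accumulation and reduction


def accumulate(fields: list[DisplacementField]) -> list[DisplacementField]:
    """Per-grid-point cumulative sum of incremental displacement fields.

    ``cumulative[k] = sum(incremental[0..k])``.  Invalid vectors contribute
    zero and mark the point ``imputed`` from that step onward.
    """
    if not fields:
        raise ValueError("no fields to accumulate")
    first = fields[0]
    for f in fields[1:]:
        if not f.same_grid(first):
            raise ValueError("all fields must share one grid")
    cum_ux = np.zeros_like(first.ux)
    cum_uy = np.zeros_like(first.uy)
    imputed = np.zeros_like(first.valid, dtype=bool)
    out = []
    for f in fields:
        cum_ux = cum_ux + np.where(f.valid, f.ux, 0.0)
        cum_uy = cum_uy + np.where(f.valid, f.uy, 0.0)
        imputed = imputed | ~f.valid | f.imputed
        out.append(
            DisplacementField(
                grid_x=first.grid_x,
                grid_y=first.grid_y,
                ux=cum_ux.copy(),
                uy=cum_uy.copy(),
                valid=np.ones_like(first.valid, dtype=bool),
                imputed=imputed.copy(),
            )
        )
    return out


def _roi_mask(f: DisplacementField, roi: SquareRoi | None) -> np.ndarray:
    if roi is None:
        return np.ones((len(f.grid_y), len(f.grid_x)), dtype=bool)
    gx, gy = np.meshgrid(f.grid_x, f.grid_y)
    half = roi.side / 2.0
    return (np.abs(gx - roi.center[0]) <= half) & (np.abs(gy - roi.center[1]) <= half)


def displacement_curve(
    cumulative_fields: list[DisplacementField],
    R0: float,
    times: np.ndarray | None = None,
    roi: SquareRoi | None = None,
) -> DisplacementSeries:
    """Mean cumulative displacement magnitude over an ROI, normalized to R0.

    ``roi=None`` averages over the full field of view (spheroid mode);
    pass :func:`explant_roi` for the 3*R0 square of explant mode.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    mags = []
    for f in cumulative_fields:
        sel = _roi_mask(f, roi) & f.valid
        if not sel.any():
            raise ValueError("ROI contains no valid grid points")
        mags.append(float(f.magnitude[sel].mean()))
    if times is None:
        times = np.arange(1, len(cumulative_fields) + 1, dtype=float)
    return DisplacementSeries(
        times=np.asarray(times, dtype=float),
        mean_mag=np.asarray(mags),
        R0=float(R0),
        roi="fov" if roi is None else f"square(side={roi.side:g})",
    )


def displacement_rate(series: DisplacementSeries) -> float:
    """OLS slope of the unnormalized mean displacement |u| (um) vs time (h)."""
    t = series.times
    if len(t) < 2:
        raise ValueError("need at least two timepoints")
    if np.ptp(t) == 0:
        raise ValueError("constant time vector")
    return float(np.polyfit(t, series.mean_mag, 1)[0])


# ---------------------------------------------------------------------------
# CSV I/O


def write_fields_csv(fields: list[DisplacementField], times, path: str | Path) -> None:
    """Long-format CSV: t, x_um, y_um, ux_um, uy_um, valid."""
    rows = []
    for t, f in zip(times, fields):
        gx, gy = np.meshgrid(f.grid_x, f.grid_y)
        rows.append(
            pd.DataFrame(
                {
                    "t_h": t,
                    "x_um": gx.ravel(),
                    "y_um": gy.ravel(),
                    "ux_um": f.ux.ravel(),
                    "uy_um": f.uy.ravel(),
                    "valid": f.valid.ravel().astype(int),
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False, float_format="%.6g")


def read_fields_csv(path: str | Path) -> tuple[list[DisplacementField], np.ndarray]:
    df = pd.read_csv(path)
    fields, times = [], []
    for t, sub in df.groupby("t_h", sort=True):
        gx = np.unique(sub["x_um"])
        gy = np.unique(sub["y_um"])
        shape = (len(gy), len(gx))
        fields.append(
            DisplacementField(
                grid_x=gx,
                grid_y=gy,
                ux=sub["ux_um"].to_numpy().reshape(shape),
                uy=sub["uy_um"].to_numpy().reshape(shape),
                valid=sub["valid"].to_numpy().reshape(shape).astype(bool),
            )
        )
        times.append(t)
    return fields, np.asarray(times)


def write_series_csv(series: DisplacementSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_h": series.times,
            "mean_mag_um": series.mean_mag,
            "normalized": series.normalized,
        }
    ).to_csv(path, index=False, float_format="%.6g")
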