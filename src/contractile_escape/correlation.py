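"""Angular relation between local ECM displacement and local cell escape.

Around one aggregate, the cumulative collagen displacement magnitude is
averaged per angular bin over an annulus just outside the initial boundary,
and the local cell escape is the radial boundary expansion (final minus
initial maximum radial extent of the cell mask) in the same bin.  The Pearson
correlation between the two angular profiles quantifies whether escape
happens where the matrix is pulled hardest (positive) or avoided there
(negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .piv import DisplacementField
from .spreading import equivalent_radius

__all__ = ["AngularProfile", "angular_profile", "escape_displacement_correlation"]


@dataclass
class AngularProfile:
    bin_centers: np.ndarray  # rad, n_bins uniform over [0, 2*pi)
    disp_mag: np.ndarray  # um, mean |u| per bin (nan = missing)
    boundary_expansion: np.ndarray  # um per bin (nan = missing)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.disp_mag) | np.isnan(self.boundary_expansion)


def _max_radial_extent(mask: np.ndarray, center_px, angles_edges, pixel_size: float):
    """Per-bin maximum radius (um) of mask pixels; nan for empty bins."""
    yy, xx = np.nonzero(mask)
    if len(xx) == 0:
        return np.full(len(angles_edges) - 1, np.nan)
    dx = xx - center_px[0]
    dy = yy - center_px[1]
    theta = np.mod(np.arctan2(dy, dx), 2 * math.pi)
    r = np.hypot(dx, dy) * pixel_size
    idx = np.digitize(theta, angles_edges) - 1
    out = np.full(len(angles_edges) - 1, np.nan)
    for b in range(len(out)):
        sel = idx == b
        if sel.any():
            out[b] = r[sel].max()
    return out


def angular_profile(
    cumulative_field: DisplacementField,
    mask_first: np.ndarray,
    mask_last: np.ndarray,
    center: tuple[float, float],
    n_bins: int = 36,
    pixel_size: float = 1.0,
    R0: float | None = None,
    band: float | None = None,
) -> AngularProfile:
    """Angular profiles of ECM displacement and boundary expansion.

    Displacement: mean |u| over valid grid points in the annulus
    [R0, R0 + band] (band defaults to R0/2) per angular bin.  Expansion: the
    per-bin maximum radial extent of ``mask_last`` minus that of
    ``mask_first`` (robust for non-star-shaped masks and detached escapers).
    ``center`` is in um; R0 defaults to the equivalent radius of the first
    mask.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    center_px = (center[0] / pixel_size, center[1] / pixel_size)
    iy = int(round(center_px[1]))
    ix = int(round(center_px[0]))
    if not (0 <= iy < mask_first.shape[0] and 0 <= ix < mask_first.shape[1]) or not mask_first[iy, ix]:
        raise ValueError("center must lie inside the initial mask")
    if R0 is None:
        R0 = float(equivalent_radius(mask_first.sum() * pixel_size**2))
    if band is None:
        band = R0 / 2.0

    edges = np.linspace(0.0, 2 * math.pi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    gx, gy = np.meshgrid(cumulative_field.grid_x, cumulative_field.grid_y)
    dx = gx - center[0]
    dy = gy - center[1]
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2 * math.pi)
    in_annulus = (r >= R0) & (r <= R0 + band) & cumulative_field.valid
    mag = cumulative_field.magnitude
    bin_idx = np.digitize(theta, edges) - 1

    disp = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = in_annulus & (bin_idx == b)
        if sel.any():
            disp[b] = mag[sel].mean()

    r_first = _max_radial_extent(mask_first, center_px, edges, pixel_size)
    r_last = _max_radial_extent(mask_last, center_px, edges, pixel_size)
    expansion = r_last - r_first
    return AngularProfile(bin_centers=centers, disp_mag=disp, boundary_expansion=expansion)


def escape_displacement_correlation(profile: AngularProfile) -> float:
    """Pearson r between displacement strength and boundary expansion.

    Missing bins are excluded; returns nan when fewer than 3 bins remain or
    either profile has zero variance (correlation undefined).
    """
    ok = ~profile.missing
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing bins")
    x = profile.disp_mag[ok]
    y = profile.boundary_expansion[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
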