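"""Hertz-model analysis of AFM force–indentation curves and elasticity maps.

For a spherical indenter of radius R pressed a depth delta into an elastic
half-space with Young's modulus E and Poisson ratio nu, the Hertz force is

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2).

Working units are um for lengths and nN for forces (E stays in Pa): with R
and delta in metres the expression yields newtons, so the conversion factor
is 1e9 * (1e-6)^2 = 1e-3 from (Pa, um) to nN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import ForceCurve

__all__ = ["HertzFit", "hertz_force", "fit_hertz", "elasticity_map"]

_UM2_TO_NN = 1e-3  # Pa * um^2 -> nN


@dataclass
class HertzFit:
    E: float  # Pa
    nu: float
    R: float  # um bead radius
    contact_offset: float  # um
    residual_rms: float  # nN
    position: tuple[float, float] | None = None


def hertz_force(E: float, nu: float, R: float, delta) -> np.ndarray:
    """Hertz force (nN) at indentation depth delta (um).

    E in Pa, bead radius R in um; nu in [0, 0.5].
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be non-negative")
    if not 0 <= nu <= 0.5:
        raise ValueError("nu must lie in [0, 0.5]")
    if E <= 0 or R <= 0:
        raise ValueError("E and R must be positive")
    return (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R) * delta**1.5 * _UM2_TO_NN


def fit_hertz(
    curve: ForceCurve,
    R: float,
    nu: float = 0.5,
    force_cap: float = 5.0,
) -> HertzFit:
    """Fit E and the contact offset to the approach segment below the force cap.

    The contact point is initialized where the force first exceeds the
    pre-contact baseline spread, then refined jointly with E by least squares
    on F = hertz(delta - offset) (zero before contact).
    """
    d = np.asarray(curve.indentation, dtype=float)
    F = np.asarray(curve.force, dtype=float)
    sel = F <= force_cap
    d, F = d[sel], F[sel]
    if len(d) < 10:
        raise ValueError("need at least 10 points below the force cap")

    fmax = F.max()
    if fmax <= 0:
        raise ValueError("no contact detected (force never rises above zero)")
    baseline_sd = np.std(F[F < 0.05 * fmax]) if (F < 0.05 * fmax).sum() > 3 else 0.0
    above = np.nonzero(F > max(3 * baseline_sd, 0.02 * fmax))[0]
    if above.size == 0:
        raise ValueError("no contact detected")
    off0 = d[above[0]]
    # crude E init from the deepest point
    span = max(d[-1] - off0, 1e-6)
    E0 = max(F[-1] / ((4 / 3) / (1 - nu**2) * np.sqrt(R) * span**1.5 * _UM2_TO_NN), 1.0)

    def residual(theta):
        logE, off = theta
        dd = np.clip(d - off, 0.0, None)
        return hertz_force(np.exp(logE), nu, R, dd) - F

    res = least_squares(
        residual,
        np.array([np.log(E0), off0]),
        bounds=(np.array([np.log(1e-2), d.min() - 1.0]), np.array([np.log(1e8), d.max()])),
        xtol=1e-14,
        ftol=1e-14,
    )
    E = float(np.exp(res.x[0]))
    return HertzFit(
        E=E,
        nu=nu,
        R=R,
        contact_offset=float(res.x[1]),
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
        position=curve.position,
    )


def elasticity_map(
    fits: list[HertzFit],
    x_edges: np.ndarray,
    y_edges: np.ndarray,
) -> np.ndarray:
    """Grid the fitted moduli into a (ny, nx) map by nearest-neighbour fill.

    Each fit is snapped to the grid cell containing its position (duplicates:
    last-written wins, with a warning); empty cells take the modulus of the
    nearest filled cell.  No interpolation between measurements is performed.
    """
    positioned = [f for f in fits if f.position is not None]
    if not positioned:
        raise ValueError("need at least one positioned fit")
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    grid = np.full((ny, nx), np.nan)
    seen: set[tuple[int, int]] = set()
    for f in positioned:
        j = int(np.clip(np.searchsorted(x_edges, f.position[0], side="right") - 1, 0, nx - 1))
        i = int(np.clip(np.searchsorted(y_edges, f.position[1], side="right") - 1, 0, ny - 1))
        if (i, j) in seen:
            warnings.warn(f"duplicate position in cell {(i, j)}; last value wins")
        seen.add((i, j))
        grid[i, j] = f.E

    if np.isnan(grid).any():
        from scipy.spatial import cKDTree

        cx = 0.5 * (x_edges[:-1] + x_edges[1:])
        cy = 0.5 * (y_edges[:-1] + y_edges[1:])
        gx, gy = np.meshgrid(cx, cy)
        filled = ~np.isnan(grid)
        tree = cKDTree(np.column_stack([gx[filled], gy[filled]]))
        _, idx = tree.query(np.column_stack([gx[~filled], gy[~filled]]))
        grid[~filled] = grid[filled][idx]
    return grid
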