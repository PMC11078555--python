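"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the experiments:

* speckle-textured collagen images advected by a radially contracting,
  time-growing displacement field (PIV stage oracle),
* a central fluorescent cell mass that stays compact, wets outward, or emits
  escaping single cells (spreading/escape oracle),
* active-SLS creep traces under the 1 s trap / 5 s stretch / 2 s trap
  protocol with additive Gaussian noise (rheology oracle),
* Hertzian force-indentation curves (AFM oracle).

Default imaging geometry is a scaled-down timelapse: 256 x 256 px at
4 um/px, 241 frames every 0.25 h (60 h total observation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .afm import hertz_force
from .io import DeformationTrace, ForceCurve, ImageSequence
from .piv import DisplacementField, PIVSettings, piv_grid
from .spreading import AreaMaskSeries
from .stretcher import SLSParams, StretchProtocol, creep_response

__all__ = [
    "FieldSpec",
    "SpreadMode",
    "NoiseSpec",
    "eval_field",
    "make_speckle_frame",
    "make_collagen_sequence",
    "make_translation_sequence",
    "make_spreading_sequence",
    "make_stretcher_trace",
    "make_population",
    "make_hertz_curve",
    "CLASS_BANDS",
]

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class FieldSpec:
    """Radially contracting displacement field around a spheroid.

    The cumulative displacement at time t (h) of a point at distance d from
    the centre points inward with magnitude

        rate * t * exp(-max(0, d - edge_radius) / decay_length),

    i.e. it grows linearly in time, is strongest at and under the spheroid
    edge (radius ``edge_radius``) and decays exponentially beyond it.
    """

    rate: float  # um/h cumulative growth at the edge
    edge_radius: float = 100.0  # um (spheroid radius R0)
    decay_length: float = 100.0  # um
    center: tuple[float, float] | None = None  # um; None -> image centre

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclass(frozen=True)
class SpreadMode:
    """Spreading regime of the fluorescent cell mass.

    compact: constant disk.  wetting: disk area grows as A0*(1+area_rate*t).
    evaporation: constant core disk plus point-like escapers appearing at
    radially increasing positions so that the total covered area tracks
    A0*(1+area_rate*t); ``n_escapers`` (per hour) overrides the area-derived
    spawn rate, ``escape_speed`` adds outward drift to spawned escapers.
    """

    mode: str = "compact"
    area_rate: float = 0.0  # 1/h
    n_escapers: float | None = None  # per hour (evaporation only)
    escape_speed: float = 0.0  # um/h

    def __post_init__(self) -> None:
        if self.mode not in ("compact", "wetting", "evaporation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.area_rate < 0 or self.escape_speed < 0:
            raise ValueError("rates must be non-negative")
        if self.mode == "compact" and self.area_rate != 0:
            raise ValueError("compact mode requires area_rate = 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise (signal units) and the seed that fixes it."""

    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Displacement field oracle


def eval_field(spec: FieldSpec, point, t: float, center=None):
    """Ground-truth cumulative displacement (um) at ``point`` (um) and time t (h).

    Vectors point from the point toward the centre; a point exactly at the
    centre gets the zero vector.  ``point`` may be (2,) or (n, 2).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    c = np.asarray(center if center is not None else spec.center, dtype=float)
    p = np.atleast_2d(np.asarray(point, dtype=float))
    delta = c - p
    d = np.hypot(delta[:, 0], delta[:, 1])
    mag = spec.rate * t * np.exp(-np.maximum(0.0, d - spec.edge_radius) / spec.decay_length)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 0, delta / np.where(d == 0, 1.0, d)[:, None], 0.0)
    u = unit * mag[:, None]
    return u[0] if np.asarray(point).ndim == 1 else u


def make_speckle_frame(
    shape: tuple[int, int], density: float = 0.08, seed: int = 0
) -> np.ndarray:
    """8-bit speckle texture: random bright dots blurred with a 1 px Gaussian."""
    if not 0 < density < 1:
        raise ValueError("speckle density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    dots = (rng.random(shape) < density).astype(float)
    img = ndimage.gaussian_filter(dots, 1.0)
    img = img / img.max() if img.max() > 0 else img
    return (img * 255).astype(np.uint8)


def _truth_fields(u_cum_px_x, u_cum_px_y, settings, pixel_size, shape):
    """Reduce the pixel-resolution cumulative displacement to the PIV grid.

    The on-grid truth is the mean displacement over each interrogation
    window — the estimand of window-correlation PIV — not the point value at
    the window centre.
    """
    w = settings.window
    mx = ndimage.uniform_filter(u_cum_px_x, w, mode="nearest")
    my = ndimage.uniform_filter(u_cum_px_y, w, mode="nearest")
    cx, cy, xs, ys = piv_grid(shape, settings, pixel_size)
    ix = xs + w // 2  # uniform_filter at this index spans exactly the window
    iy = ys + w // 2
    ux = mx[np.ix_(iy, ix)] * pixel_size
    uy = my[np.ix_(iy, ix)] * pixel_size
    valid = np.ones(ux.shape, dtype=bool)
    return DisplacementField(grid_x=cx, grid_y=cy, ux=ux, uy=uy, valid=valid)


def make_collagen_sequence(
    spec: FieldSpec,
    n_frames: int = 241,
    frame_interval: float = 0.25,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 4.0,
    speckle_density: float = 0.08,
    noise: NoiseSpec = NoiseSpec(),
    piv_settings: PIVSettings = PIVSettings(),
) -> tuple[ImageSequence, list[DisplacementField], list[DisplacementField]]:
    """Speckle timelapse advected by the radial field, with ground truth.

    Frame k is frame 0 backward-warped (bilinear) by the cumulative field at
    t = k * frame_interval.  Returns the sequence plus the ground-truth
    incremental (k -> k+1) and cumulative fields on the PIV grid.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    frame0 = make_speckle_frame(shape, speckle_density, noise.seed)
    rng = noise.rng()

    center = (
        np.asarray(spec.center, dtype=float)
        if spec.center is not None
        else np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0]) * pixel_size
    )
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    px = np.column_stack([xx.ravel() * pixel_size, yy.ravel() * pixel_size])
    u1 = eval_field(spec, px, 1.0, center=center)  # field at t=1 h; linear in t
    u1x = (u1[:, 0] / pixel_size).reshape(shape)
    u1y = (u1[:, 1] / pixel_size).reshape(shape)

    inc_per_frame = frame_interval * np.hypot(u1x, u1y).max()
    if inc_per_frame > piv_settings.window / 2:
        warnings.warn(
            f"per-frame displacement {inc_per_frame:.1f} px exceeds half the "
            f"PIV window ({piv_settings.window} px): not trackable"
        )

    times = np.arange(n_frames) * frame_interval
    base = frame0.astype(np.float64)
    frames = np.empty((n_frames, *shape), dtype=np.uint8)
    cumulative, incremental = [], []
    prev = None
    for k, t in enumerate(times):
        if t == 0:
            warped = base
        else:
            coords = np.array([yy - u1y * t, xx - u1x * t])
            warped = ndimage.map_coordinates(base, coords, order=1, mode="constant", cval=0.0)
        if noise.additive_sd > 0:
            warped = warped + rng.normal(0.0, noise.additive_sd, shape)
        frames[k] = np.clip(np.round(warped), 0, 255).astype(np.uint8)
        tf = _truth_fields(u1x * t, u1y * t, piv_settings, pixel_size, shape)
        cumulative.append(tf)
        if prev is not None:
            incremental.append(
                DisplacementField(
                    grid_x=tf.grid_x,
                    grid_y=tf.grid_y,
                    ux=tf.ux - prev.ux,
                    uy=tf.uy - prev.uy,
                    valid=np.ones_like(tf.valid),
                )
            )
        prev = tf

    seq = ImageSequence(
        frames=frames,
        times=times,
        pixel_size=pixel_size,
        meta={"generator": "collagen", "rate_um_per_h": spec.rate, "seed": noise.seed},
    )
    return seq, incremental, cumulative[1:]


def make_translation_sequence(
    shift_px_per_frame: tuple[float, float],
    n_frames: int = 5,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 4.0,
    speckle_density: float = 0.08,
    seed: int = 0,
) -> ImageSequence:
    """Uniform-translation variant: frame k is frame 0 shifted by k * shift.

    A pure-shift control for PIV (backward-warped with bilinear interpolation,
    exact at integer shifts away from the inflow border).
    """
    frame0 = make_speckle_frame(shape, speckle_density, seed).astype(np.float64)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    sx, sy = shift_px_per_frame
    frames = [frame0]
    for k in range(1, n_frames):
        coords = np.array([yy - sy * k, xx - sx * k])
        frames.append(ndimage.map_coordinates(frame0, coords, order=1, mode="constant"))
    return ImageSequence(
        frames=np.clip(np.round(frames), 0, 255).astype(np.uint8),
        times=np.arange(n_frames, dtype=float),
        pixel_size=pixel_size,
        meta={"generator": "translation", "shift_px": list(shift_px_per_frame)},
    )


# ---------------------------------------------------------------------------
# Fluorescent cell mass


_ESCAPER_RADIUS_PX = 4


def _disk_mask(shape, center_px, radius_px):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center_px[0]) ** 2 + (yy - center_px[1]) ** 2 <= radius_px**2


def make_spreading_sequence(
    mode: SpreadMode,
    R0: float = 100.0,
    n_frames: int = 61,
    frame_interval: float = 1.0,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 4.0,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[ImageSequence, AreaMaskSeries]:
    """Fluorescence timelapse of a spreading cell mass plus pixel-exact truth.

    Returns the rendered (noisy) sequence and the ground-truth binary mask
    series; the true area per frame is the mask pixel count times
    pixel_size^2.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    rng = noise.rng()
    center_px = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    half_extent = min(center_px) * pixel_size
    times = np.arange(n_frames) * frame_interval
    R0_px = R0 / pixel_size
    A0_px = math.pi * R0_px**2

    # escaper spawn schedule (evaporation mode)
    esc_area_px = float(_disk_mask((17, 17), (8, 8), _ESCAPER_RADIUS_PX).sum())
    if mode.mode == "evaporation":
        t_end = times[-1]
        if mode.n_escapers is not None:
            spawn_rate = mode.n_escapers  # per hour
        else:
            spawn_rate = mode.area_rate * A0_px / esc_area_px
        n_total = int(math.ceil(spawn_rate * t_end))
        # golden-angle annulus packing: radially increasing, non-overlapping
        r_min_px = R0_px + _ESCAPER_RADIUS_PX + 2
        # packing pitch leaves >= 6 px between dot rims so blur + closing in
        # the segmentation stage cannot merge neighbouring escapers
        pack_px = (2 * _ESCAPER_RADIUS_PX + 6) ** 2
        esc_angle = GOLDEN_ANGLE * np.arange(n_total)
        esc_base_r = np.sqrt(r_min_px**2 + np.arange(n_total) * pack_px / math.pi)
        esc_spawn_t = (np.arange(n_total) + 1) / spawn_rate if n_total else np.array([])

    masks = np.empty((n_frames, *shape), dtype=bool)
    frames = np.empty((n_frames, *shape), dtype=np.uint8)
    for k, t in enumerate(times):
        if mode.mode == "wetting":
            R_t = R0 * math.sqrt(1.0 + mode.area_rate * t)
        else:
            R_t = R0
        if R_t >= half_extent:
            raise ValueError(f"cell mass (R={R_t:.0f} um) leaves the frame at t={t:g} h")
        m = _disk_mask(shape, center_px, R_t / pixel_size)
        if mode.mode == "evaporation" and n_total:
            alive = esc_spawn_t <= t
            r_px = esc_base_r[alive] + mode.escape_speed * (t - esc_spawn_t[alive]) / pixel_size
            if r_px.size and (r_px.max() + _ESCAPER_RADIUS_PX) * pixel_size >= half_extent:
                raise ValueError(f"escapers leave the frame at t={t:g} h")
            ex = center_px[0] + r_px * np.cos(esc_angle[alive])
            ey = center_px[1] + r_px * np.sin(esc_angle[alive])
            yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
            for x0, y0 in zip(ex, ey):
                m |= (xx - x0) ** 2 + (yy - y0) ** 2 <= _ESCAPER_RADIUS_PX**2
        masks[k] = m
        img = 10.0 + 190.0 * ndimage.gaussian_filter(m.astype(float), 1.0)
        if noise.additive_sd > 0:
            img = img + rng.normal(0.0, noise.additive_sd, shape)
        frames[k] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    seq = ImageSequence(
        frames=frames,
        times=times,
        pixel_size=pixel_size,
        meta={"generator": "spreading", "mode": mode.mode, "seed": noise.seed},
    )
    return seq, AreaMaskSeries(masks=masks, times=times, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Optical stretcher


def make_stretcher_trace(
    params: SLSParams,
    protocol: StretchProtocol = StretchProtocol(),
    noise: NoiseSpec = NoiseSpec(),
    cell_id: str = "cell",
) -> DeformationTrace:
    """Creep trace from the active SLS model plus additive Gaussian noise."""
    params.validate(protocol.t_stretch)
    t = protocol.times()
    strain = creep_response(params, protocol, t)
    if noise.additive_sd > 0:
        strain = strain + noise.rng().normal(0.0, noise.additive_sd, t.shape)
    return DeformationTrace(times=t, strain=strain, cell_id=cell_id)


CLASS_BANDS = {"non": (0.0, 0.1), "moderate": (0.1, 0.8), "high": (0.8, 2.0)}

_DEFAULT_PARAM_RANGES = {
    "k_series": (25.0, 60.0),  # Pa -> instantaneous strain ~0.02-0.04 at 1 Pa
    "k_parallel": (25.0, 60.0),
    "eta": (30.0, 120.0),  # Pa s -> retardation time ~1-3 s
    "t_on": (1.0, 3.0),  # s; contraction sets in a couple of seconds in
}


def make_population(
    fractions: tuple[float, float, float],
    n: int,
    param_ranges: dict | None = None,
    seed: int = 0,
    protocol: StretchProtocol = StretchProtocol(),
    noise_sd: float = 0.002,
) -> tuple[list[DeformationTrace], list[SLSParams], list[str]]:
    """Cohort of creep traces with class structure (non, moderate, high).

    Class counts are round(n * fraction) with the remainder assigned to the
    largest fraction; sigma_int is drawn uniformly within the class band
    (non < 0.1 Pa, moderate in [0.1, 0.8] Pa, high in (0.8, 2.0] Pa).
    Returns traces, the true parameters, and the true class labels.
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0) or fr.sum() <= 0:
        raise ValueError("fractions must be non-negative and not all zero")
    if n < 1:
        raise ValueError("n must be >= 1")
    fr = fr / fr.sum()
    counts = np.round(n * fr).astype(int)
    counts[np.argmax(fr)] += n - counts.sum()

    ranges = {**_DEFAULT_PARAM_RANGES, **(param_ranges or {})}
    rng = np.random.default_rng(seed)
    traces, truth, labels = [], [], []
    i = 0
    for cls, count in zip(("non", "moderate", "high"), counts):
        lo, hi = CLASS_BANDS[cls]
        for _ in range(count):
            p = SLSParams(
                k_series=rng.uniform(*ranges["k_series"]),
                k_parallel=rng.uniform(*ranges["k_parallel"]),
                eta=rng.uniform(*ranges["eta"]),
                sigma_int=rng.uniform(lo, hi),
                t_on=rng.uniform(*ranges["t_on"]),
            )
            tr = make_stretcher_trace(
                p,
                protocol,
                NoiseSpec(additive_sd=noise_sd, seed=int(rng.integers(2**31))),
                cell_id=f"cell_{i:04d}",
            )
            traces.append(tr)
            truth.append(p)
            labels.append(cls)
            i += 1
    return traces, truth, labels


# ---------------------------------------------------------------------------
# AFM


def make_hertz_curve(
    E: float,
    nu: float = 0.45,
    R: float = 22.5,
    max_force: float = 5.0,
    noise: NoiseSpec = NoiseSpec(),
    contact_offset: float = 0.3,
    n_points: int = 200,
    position: tuple[float, float] | None = None,
) -> ForceCurve:
    """Hertzian force curve (nN vs um) up to ``max_force`` plus noise.

    The indentation grid starts 0.5 um before contact (zero-force baseline)
    and ends where the noise-free force reaches ``max_force``.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("nu must lie in [0, 0.5)")
    k = (4.0 / 3.0) * E / (1.0 - nu**2) * math.sqrt(R) * 1e-3  # nN / um^1.5
    d_max = (max_force / k) ** (2.0 / 3.0) + contact_offset
    delta = np.linspace(contact_offset - 0.5, d_max, n_points)
    F = k * np.clip(delta - contact_offset, 0.0, None) ** 1.5
    if noise.additive_sd > 0:
        F = F + noise.rng().normal(0.0, noise.additive_sd, F.shape)
    return ForceCurve(indentation=delta, force=F, position=position)
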