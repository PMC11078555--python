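"""Active standard-linear-solid (SLS) creep rheology for the optical stretcher.

The passive cell is a standard linear solid in Kelvin–Voigt representation: a
spring ``k_parallel`` and dashpot ``eta`` in parallel, in series with a second
spring ``k_series``.  Its creep compliance is

    J(t) = 1/k_series + (1/k_parallel) * (1 - exp(-t * k_parallel / eta)).

The optical stretcher applies a rectangular stress pulse of height ``sigma0``
during the stretch phase (trap phases carry zero net stress).  Active cortical
contractility is an internal stress ``sigma_int`` opposing the optical pull:
it ramps linearly from zero at onset time ``t_on`` (measured from stretch
start) to ``sigma_int`` at stretch end and is then held constant, so the
effective stress is ``sigma_eff(t) = sigma_ext(t) - sigma_active(t)``.  Strain
follows by Boltzmann superposition, evaluated in closed form.

Cells are classified from the fitted ``sigma_int``: non-contractile below
0.1 Pa, highly contractile above 0.8 Pa, moderate in between (the boundary
values themselves count as moderate, matching the strict inequalities of the
classification rule).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .io import DeformationTrace

__all__ = [
    "StretchProtocol",
    "SLSParams",
    "SLSFit",
    "creep_response",
    "fit_trace",
    "classify_contractility",
    "population_fractions",
    "cohort_summary",
    "SIGMA_NON_MAX",
    "SIGMA_HIGH_MIN",
]

SIGMA_NON_MAX = 0.1  # Pa; below -> non-contractile
SIGMA_HIGH_MIN = 0.8  # Pa; above -> highly contractile


@dataclass(frozen=True)
class StretchProtocol:
    """Trap–stretch–trap timing and the peak optical stress.

    Defaults follow the standard protocol: 1 s trap, 5 s stretch, 2 s trap,
    with a peak stress on the order of 1 Pa during the stretch.
    """

    t_trap1: float = 1.0  # s
    t_stretch: float = 5.0  # s
    t_trap2: float = 2.0  # s
    sigma0: float = 1.0  # Pa
    sample_rate: float = 30.0  # Hz

    def __post_init__(self) -> None:
        if min(self.t_trap1, self.t_stretch, self.t_trap2) <= 0:
            raise ValueError("protocol durations must be positive")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")

    @property
    def total(self) -> float:
        return self.t_trap1 + self.t_stretch + self.t_trap2

    def times(self) -> np.ndarray:
        n = int(round(self.total * self.sample_rate)) + 1
        return np.arange(n) / self.sample_rate


@dataclass(frozen=True)
class SLSParams:
    """Active-SLS parameters: two springs (Pa), a dashpot (Pa s), the internal
    contractile stress reached at stretch end (Pa) and its onset time (s,
    measured from stretch start)."""

    k_series: float
    k_parallel: float
    eta: float
    sigma_int: float = 0.0
    t_on: float = 0.0

    def validate(self, t_stretch: float = np.inf) -> None:
        if min(self.k_series, self.k_parallel, self.eta) <= 0:
            raise ValueError("k_series, k_parallel, eta must be positive")
        if self.sigma_int < 0:
            raise ValueError("sigma_int must be non-negative")
        if not 0 <= self.t_on <= t_stretch:
            raise ValueError("t_on must lie within the stretch phase")


@dataclass
class SLSFit:
    params: SLSParams
    residual_rms: float
    sigma_eff_end: float  # sigma0 - sigma_int
    converged: bool
    cell_id: str = ""

    @property
    def contractility_class(self) -> str:
        return classify_contractility(self.params.sigma_int)


def creep_response(
    params: SLSParams,
    protocol: StretchProtocol,
    times: np.ndarray,
    active_hold: bool = True,
) -> np.ndarray:
    """Strain response of the active SLS to the trap–stretch–trap protocol.

    Evaluated analytically: the stress history decomposes into steps and a
    linear ramp, each of which convolves with the creep compliance in closed
    form.  ``active_hold=False`` switches the internal stress off at stretch
    end instead of holding it through the final trap phase.
    """
    params.validate(protocol.t_stretch)
    t = np.asarray(times, dtype=float)
    C = 1.0 / params.k_series
    D = 1.0 / params.k_parallel
    tau = params.eta / params.k_parallel

    t1 = protocol.t_trap1
    t2 = t1 + protocol.t_stretch

    strain = _step(t, t1, protocol.sigma0, C, D, tau)
    strain -= _step(t, t2, protocol.sigma0, C, D, tau)

    if params.sigma_int > 0:
        ramp_len = protocol.t_stretch - params.t_on
        if ramp_len <= 1e-9:
            # onset at stretch end degenerates to a step
            strain -= _step(t, t2, params.sigma_int, C, D, tau)
        else:
            slope = params.sigma_int / ramp_len
            strain -= _ramp(t, t1 + params.t_on, t2, slope, C, D, tau)
        if not active_hold:
            strain += _step(t, t2, params.sigma_int, C, D, tau)
    return strain


def _step(t, t0, h, C, D, tau):
    """Strain from a stress step of height h at time t0."""
    s = t - t0
    active = s > 0
    out = np.zeros_like(t)
    out[active] = h * (C + D * (1.0 - np.exp(-s[active] / tau)))
    return out


def _ramp(t, a, b, slope, C, D, tau):
    """Strain from a stress ramp of given slope on [a, b], constant after b."""
    out = np.zeros_like(t)
    active = t > a
    u = np.minimum(t[active], b)
    ta = t[active]
    out[active] = slope * (
        (C + D) * (u - a) - D * tau * (np.exp(-(ta - u) / tau) - np.exp(-(ta - a) / tau))
    )
    return out


# ---------------------------------------------------------------------------
# Fitting

_BOUNDS_LO = np.array([1e-2, 1e-2, 1e-2, 0.0, 0.0])
_BOUNDS_HI = np.array([1e3, 1e3, 1e3, 10.0, np.nan])  # t_on upper set per protocol


def _feature_init(trace: DeformationTrace, protocol: StretchProtocol) -> np.ndarray:
    """Initial parameters from trace features: the instantaneous jump gives
    k_series, the late-stretch plateau gives k_parallel, the early creep slope
    gives eta."""
    t, eps = trace.times, trace.strain
    t1, ts = protocol.t_trap1, protocol.t_stretch
    s0 = protocol.sigma0
    base = eps[t < t1].mean() if (t < t1).any() else 0.0
    early = t[(t > t1) & (t < t1 + 0.3)]
    jump = (np.interp(t1 + 0.15, t, eps) - base) if early.size else 0.01
    k1 = np.clip(s0 / max(jump, 1e-4), 1.0, 500.0)
    end = np.interp(t1 + ts - 0.1, t, eps) - base
    k2 = np.clip(s0 / max(end - s0 / k1, 1e-4), 1.0, 500.0)
    win = (t > t1 + 0.2) & (t < t1 + 1.2)
    slope = np.polyfit(t[win], eps[win], 1)[0] if win.sum() > 3 else 0.01
    eta = np.clip(s0 / max(slope, 1e-4), 0.5, 500.0)
    return np.array([k1, k2, eta, 0.3, ts / 2.0])


def fit_trace(
    trace: DeformationTrace,
    protocol: StretchProtocol = StretchProtocol(),
    n_starts: int = 5,
    seed: int = 0,
    active_hold: bool = True,
) -> SLSFit:
    """Fit the active SLS model to one creep trace by bounded least squares.

    Multi-start: the first start comes from trace features, the rest are
    seeded log-uniform perturbations; the best-residual solution is kept.
    ``converged`` is False if no start converged or the mechanical parameters
    ended pinned at a box bound (degenerate trace).
    """
    t, eps = trace.times, trace.strain
    if len(t) < 20:
        raise ValueError("need at least 20 samples")
    if t[-1] < protocol.t_trap1 + protocol.t_stretch - 1e-9:
        raise ValueError("trace does not cover the stretch phase")

    lo = _BOUNDS_LO.copy()
    hi = _BOUNDS_HI.copy()
    hi[4] = protocol.t_stretch

    def residual(theta):
        p = SLSParams(*theta)
        return creep_response(p, protocol, t, active_hold=active_hold) - eps

    rng = np.random.default_rng(seed)
    x0 = np.clip(_feature_init(trace, protocol), lo + 1e-9, hi - 1e-9)
    starts = [x0]
    for _ in range(n_starts - 1):
        mech = x0[:3] * np.exp(rng.normal(0, 0.7, size=3).clip(-2, 2))
        pert = np.array(
            [mech[0], mech[1], mech[2], rng.uniform(0, 2.0), rng.uniform(0, protocol.t_stretch)]
        )
        starts.append(np.clip(pert, lo + 1e-9, hi - 1e-9))

    best = None
    for s in starts:
        try:
            res = least_squares(
                residual, s, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    theta = best.x
    params = SLSParams(*theta)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    at_bound = any(
        theta[i] <= lo[i] * (1 + 1e-6) + 1e-12 or theta[i] >= hi[i] * (1 - 1e-6)
        for i in range(3)  # mechanical parameters only
    )
    return SLSFit(
        params=params,
        residual_rms=rms,
        sigma_eff_end=float(protocol.sigma0 - params.sigma_int),
        converged=bool(best.success and not at_bound),
        cell_id=trace.cell_id,
    )


# ---------------------------------------------------------------------------
# Classification and cohort statistics


def classify_contractility(sigma_int: float) -> str:
    """'non' below 0.1 Pa, 'high' above 0.8 Pa, 'moderate' otherwise
    (boundaries inclusive to moderate)."""
    if sigma_int < 0:
        raise ValueError("sigma_int must be non-negative")
    if sigma_int < SIGMA_NON_MAX:
        return "non"
    if sigma_int > SIGMA_HIGH_MIN:
        return "high"
    return "moderate"


def population_fractions(fits: Sequence[SLSFit]) -> dict:
    """Class percentages (0–100 scale) over converged fits.

    Returns a dict with n, pct_non, pct_moderate, pct_high and the number of
    excluded (non-converged) fits.
    """
    if not fits:
        raise ValueError("empty fit list")
    ok = [f for f in fits if f.converged]
    excluded = len(fits) - len(ok)
    if not ok:
        raise ValueError("no converged fits")
    classes = [f.contractility_class for f in ok]
    n = len(ok)
    return {
        "n": n,
        "pct_non": 100.0 * classes.count("non") / n,
        "pct_moderate": 100.0 * classes.count("moderate") / n,
        "pct_high": 100.0 * classes.count("high") / n,
        "excluded": excluded,
    }


def cohort_summary(fits: Sequence[SLSFit]) -> dict:
    """Population fractions plus the median and quartiles of sigma_int."""
    out = population_fractions(fits)
    sig = np.array([f.params.sigma_int for f in fits if f.converged])
    q25, q50, q75 = np.percentile(sig, [25, 50, 75])
    out.update(
        median_sigma_int=float(q50),
        q25_sigma_int=float(q25),
        q75_sigma_int=float(q75),
    )
    return out
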