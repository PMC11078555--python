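"""Active-SLS creep model, trace fitting and contractility classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contractile_escape import (
    NoiseSpec,
    SLSParams,
    StretchProtocol,
    classify_contractility,
    creep_response,
    fit_trace,
    make_population,
    make_stretcher_trace,
    population_fractions,
)
from contractile_escape.io import DeformationTrace


PROTOCOL = StretchProtocol()


def boltzmann_numeric(params, protocol, times, dt=1e-3):
    """Independent Boltzmann-superposition oracle: the two external stress
    jumps enter exactly via J(t - t_jump), the active ramp is integrated by
    the trapezoid rule at 1 kHz."""
    C = 1 / params.k_series
    D = 1 / params.k_parallel
    tau = params.eta / params.k_parallel
    t1, ts = protocol.t_trap1, protocol.t_stretch
    t2 = t1 + ts

    def J(s):
        # creep compliance with J(0+) = C (instantaneous elastic response)
        return np.where(s >= 0, C + D * (1 - np.exp(-np.clip(s, 0, None) / tau)), 0.0)

    out = np.where(times > t1, protocol.sigma0 * J(times - t1), 0.0)
    out -= np.where(times > t2, protocol.sigma0 * J(times - t2), 0.0)
    if params.sigma_int > 0:
        a = t1 + params.t_on
        slope = params.sigma_int / (ts - params.t_on)
        grid = np.arange(a, t2, dt)
        for i, t in enumerate(times):
            tend = min(t, t2)
            if tend <= a:
                continue
            g = np.append(grid[grid < tend], tend)
            out[i] -= slope * np.trapezoid(J(t - g), g)
    return out


class TestCreepResponse:
    def test_passive_sls_limits(self):
        p = SLSParams(40.0, 20.0, 10.0, sigma_int=0.0)
        t = np.array([1.0 + 1e-9, 5.999])
        eps = creep_response(p, PROTOCOL, t)
        # instantaneous jump sigma0/k_series; plateau sigma0*(1/k1 + 1/k2)
        assert eps[0] == pytest.approx(1.0 / 40.0, rel=1e-4)
        assert eps[1] == pytest.approx(1.0 / 40.0 + 1.0 / 20.0, rel=1e-2)

    def test_rigid_limit_zero_strain(self):
        p = SLSParams(1e12, 1e12, 50.0, sigma_int=0.0)
        eps = creep_response(p, PROTOCOL, PROTOCOL.times())
        assert np.abs(eps).max() < 1e-10

    def test_contractile_slope_negative_at_stretch_end(self):
        p = SLSParams(40.0, 40.0, 60.0, sigma_int=1.5, t_on=2.0)
        t = np.linspace(5.5, 5.99, 20)
        eps = creep_response(p, PROTOCOL, t)
        assert np.all(np.diff(eps) < 0)

    def test_linearity_in_stress(self):
        p1 = SLSParams(40.0, 30.0, 50.0, sigma_int=0.6, t_on=1.0)
        p2 = SLSParams(40.0, 30.0, 50.0, sigma_int=1.2, t_on=1.0)
        prot1 = StretchProtocol(sigma0=1.0)
        prot2 = StretchProtocol(sigma0=2.0)
        t = PROTOCOL.times()
        assert np.allclose(2 * creep_response(p1, prot1, t), creep_response(p2, prot2, t))

    @pytest.mark.parametrize(
        "params",
        [
            SLSParams(40.0, 40.0, 60.0, 0.0, 0.0),
            SLSParams(30.0, 55.0, 90.0, 0.5, 2.0),
            SLSParams(55.0, 30.0, 40.0, 1.3, 1.5),
        ],
    )
    def test_analytic_matches_numeric_convolution(self, params):
        t = np.linspace(0.0, PROTOCOL.total, 30)
        analytic = creep_response(params, PROTOCOL, t)
        numeric = boltzmann_numeric(params, PROTOCOL, t)
        scale = np.abs(analytic).max()
        assert np.abs(analytic - numeric).max() / scale < 1e-5

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            creep_response(SLSParams(-1.0, 40.0, 60.0), PROTOCOL, PROTOCOL.times())
        with pytest.raises(ValueError):
            creep_response(SLSParams(40.0, 40.0, 60.0, t_on=9.0), PROTOCOL, PROTOCOL.times())


class TestFitTrace:
    @pytest.mark.parametrize(
        "params",
        [
            SLSParams(40.0, 40.0, 60.0, 0.0, 0.0),
            SLSParams(30.0, 55.0, 90.0, 0.5, 2.0),
            SLSParams(55.0, 30.0, 40.0, 1.3, 1.5),
            SLSParams(45.0, 50.0, 100.0, 0.09, 2.5),
        ],
    )
    def test_noise_free_recovery_within_one_percent(self, params):
        tr = make_stretcher_trace(params, PROTOCOL, NoiseSpec(0.0, 0))
        fit = fit_trace(tr, PROTOCOL, seed=0)
        for name in ("k_series", "k_parallel", "eta", "sigma_int"):
            true = getattr(params, name)
            est = getattr(fit.params, name)
            assert abs(est - true) <= 0.01 * max(true, 0.01), name
        assert fit.converged
        assert fit.sigma_eff_end == pytest.approx(1.0 - params.sigma_int, abs=0.02)

    def test_flat_trace_degenerate_semantics(self):
        # zero deformation under 1 Pa pull: either the fit compensates with
        # sigma_int ~ sigma0 or a stiffness pins at its bound and is flagged
        t = PROTOCOL.times()
        tr = DeformationTrace(times=t, strain=np.zeros_like(t), cell_id="flat")
        fit = fit_trace(tr, PROTOCOL, seed=0)
        assert (abs(fit.params.sigma_int - 1.0) < 0.2) or (not fit.converged)

    def test_short_trace_rejected(self):
        tr = DeformationTrace(times=np.linspace(0, 8, 10), strain=np.zeros(10))
        with pytest.raises(ValueError):
            fit_trace(tr, PROTOCOL)


class TestClassification:
    @pytest.mark.parametrize(
        "sigma,expected",
        [
            (1.09, "high"),
            (0.15, "moderate"),
            (0.39, "moderate"),
            (0.05, "non"),
            (0.8, "moderate"),
            (0.1, "moderate"),
        ],
    )
    def test_printed_thresholds(self, sigma, expected):
        assert classify_contractility(sigma) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_contractility(-0.1)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=10.0, allow_nan=False))
    def test_sign_criterion_matches_sigma_eff(self, sigma_int):
        # sigma_eff_end < 0 exactly when contraction exceeds the 1 Pa pull
        assert (1.0 - sigma_int < 0) == (sigma_int > 1.0)


class TestPopulationFractions:
    def test_all_high_cohort(self):
        from contractile_escape import SLSFit

        fits = [
            SLSFit(SLSParams(40, 40, 60, 1.0, 2.0), 0.0, 0.0, True) for _ in range(10)
        ]
        out = population_fractions(fits)
        assert out["n"] == 10
        assert out["pct_high"] == 100.0
        assert out["pct_non"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            population_fractions([])

    def test_percentages_sum_to_100(self):
        from contractile_escape import SLSFit

        rng = np.random.default_rng(0)
        fits = [
            SLSFit(SLSParams(40, 40, 60, s, 2.0), 0.0, 1 - s, True)
            for s in rng.uniform(0, 2, 37)
        ]
        out = population_fractions(fits)
        assert out["pct_non"] + out["pct_moderate"] + out["pct_high"] == pytest.approx(100.0)


def test_recovery_bias_small_at_low_noise():
    # bias of fitted sigma_int under mild noise, moderate cohort size
    traces, truth, _ = make_population(
        (0.0, 0.0, 1.0), 40, seed=11, noise_sd=0.001
    )
    fits = [fit_trace(tr, PROTOCOL, seed=i) for i, tr in enumerate(traces)]
    errs = np.array([f.params.sigma_int - p.sigma_int for f, p in zip(fits, truth)])
    rel_bias = abs(errs.mean()) / np.mean([p.sigma_int for p in truth])
    assert rel_bias < 0.05
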