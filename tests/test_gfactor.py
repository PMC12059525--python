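"""G-factor engines: closed forms, recursion, hybrid, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eqdx.gfactor import (
    OVERFLOW_EXPONENT,
    GFactorBreakdown,
    IntegrationConfig,
    NumericalOverflowError,
    g_analytic_biexp,
    g_hybrid,
    g_mono,
    g_numerical,
    g_oracle,
)
from eqdx.models import (
    BiexponentialDoseRate,
    DoseRateSample,
    MonoexponentialDoseRate,
    PiecewiseLinExpDoseRate,
    RadiobiologicalParams,
)


class TestAnalyticBiexp:
    def test_known_value_from_quadrature(self):
        # frozen from the independent double-quadrature oracle
        p = RadiobiologicalParams(alpha_beta=10.0, trep=1.5)
        m = BiexponentialDoseRate(r0=1.0, lambda_e1=0.01, lambda_e2=0.1)
        assert g_analytic_biexp(m, p) == pytest.approx(0.0195990, abs=5e-7)

    def test_no_repair_gives_unity(self, biexp, params_no_repair):
        assert g_analytic_biexp(biexp, params_no_repair) == 1.0

    def test_matches_oracle(self, biexp, params):
        go = g_oracle(biexp.ddot, params, horizon=2000.0)
        assert g_analytic_biexp(biexp, params) == pytest.approx(go, rel=1e-6)

    @given(
        r0=st.floats(0.01, 100.0),
        l1=st.floats(0.001, 0.2),
        ratio=st.floats(1.1, 100.0),
        trep=st.floats(0.2, 10.0),
    )
    def test_amplitude_invariance_and_range(self, r0, l1, ratio, trep):
        p = RadiobiologicalParams(alpha_beta=10.0, trep=trep)
        g1 = g_analytic_biexp(
            BiexponentialDoseRate(1.0, l1, l1 * ratio), p
        )
        g2 = g_analytic_biexp(
            BiexponentialDoseRate(r0, l1, l1 * ratio), p
        )
        assert g1 == g2
        assert 0.0 < g1 <= 1.0

    def test_strictly_decreasing_in_repair_rate(self, biexp):
        mus = np.linspace(0.0, 3.0, 31)
        gs = [
            g_analytic_biexp(biexp, RadiobiologicalParams.from_mu(10.0, mu))
            for mu in mus
        ]
        assert np.all(np.diff(gs) < 0.0)


class TestMono:
    def test_symmetry_point(self):
        p = RadiobiologicalParams.from_mu(10.0, 0.1)
        assert g_mono(0.1, p) == 0.5

    def test_no_repair_limit(self, params_no_repair):
        assert g_mono(0.3, params_no_repair) == 1.0

    def test_direct_arithmetic_and_oracle(self, params):
        mu = math.log(2.0) / 1.5
        assert g_mono(0.1, params) == pytest.approx(0.1 / (0.1 + mu), rel=1e-15)
        m = MonoexponentialDoseRate(d0=1.0, lambda_e=0.1)
        go = g_oracle(m.ddot, params, horizon=800.0)
        assert g_mono(0.1, params) == pytest.approx(go, rel=1e-6)


class TestNumerical:
    def test_converges_to_mono_closed_form(self, params):
        m = MonoexponentialDoseRate(d0=1.0, lambda_e=0.1)
        bd = g_numerical(m.ddot, params, IntegrationConfig(dt=0.01, stop_time=1000.0))
        assert bd.G == pytest.approx(g_mono(0.1, params), rel=1e-3)
        assert not bd.overflowed

    def test_converges_to_biexp_closed_form(self, biexp, params):
        bd = g_numerical(
            biexp.ddot, params, IntegrationConfig(dt=0.01, stop_time=1000.0)
        )
        assert bd.G == pytest.approx(g_analytic_biexp(biexp, params), rel=1e-3)

    def test_breakdown_invariants(self, biexp, params):
        bd = g_numerical(biexp.ddot, params, IntegrationConfig(dt=0.02, stop_time=500.0))
        assert 0.0 < bd.G <= 1.0
        assert bd.R <= bd.R0
        assert bd.N >= 0.0 and bd.D > 0.0
        assert bd.R0 == pytest.approx(bd.D**2 / 2.0)

    def test_monotone_in_stop_time_and_bounded(self, biexp, params):
        stops = [100.0, 200.0, 400.0, 800.0]
        eqd_like = []
        for s in stops:
            bd = g_numerical(biexp.ddot, params, IntegrationConfig(dt=0.02, stop_time=s))
            eqd_like.append(bd.D + 2.0 * bd.N / 10.0)  # BED at alpha/beta=10
        ref_bed = 96.0 * (1.0 + g_analytic_biexp(biexp, params) * 96.0 / 10.0)
        assert np.all(np.diff(eqd_like) > 0.0)
        assert eqd_like[-1] <= ref_bed * (1.0 + 1e-4)

    def test_overflow_guard_fires(self):
        # mu = ln2/0.5: exp(mu t) crosses float64 range just past ~505 h
        p = RadiobiologicalParams(alpha_beta=10.0, trep=0.5)
        m = MonoexponentialDoseRate(d0=0.5, lambda_e=0.004345)
        bd = g_numerical(m.ddot, p, IntegrationConfig(dt=0.01, stop_time=511.0))
        assert bd.overflowed
        assert bd.stop_time_used <= OVERFLOW_EXPONENT / p.mu
        assert np.isfinite(bd.G)

    def test_overflow_can_raise_with_partial_result(self):
        p = RadiobiologicalParams(alpha_beta=10.0, trep=0.5)
        m = MonoexponentialDoseRate(d0=0.5, lambda_e=0.004345)
        with pytest.raises(NumericalOverflowError) as exc:
            g_numerical(
                m.ddot, p, IntegrationConfig(dt=0.01, stop_time=600.0),
                raise_on_overflow=True,
            )
        assert isinstance(exc.value.breakdown, GFactorBreakdown)
        assert exc.value.breakdown.overflowed

    def test_auto_stop_terminates_and_is_accurate(self, biexp):
        p = RadiobiologicalParams(alpha_beta=10.0, trep=3.0)
        bd = g_numerical(
            biexp.ddot, p,
            IntegrationConfig(dt=0.01, stop_time=72.0, auto_stop=True),
        )
        assert not bd.overflowed
        assert bd.stop_time_used > 72.0
        ref = g_analytic_biexp(biexp, p)
        assert bd.G == pytest.approx(ref, rel=0.02)

    def test_dt_halving_stability(self, biexp, params):
        g1 = g_numerical(biexp.ddot, params, IntegrationConfig(dt=0.01, stop_time=300.0)).G
        g2 = g_numerical(biexp.ddot, params, IntegrationConfig(dt=0.005, stop_time=300.0)).G
        assert abs(g1 - g2) / g2 < 1e-4


class TestHybrid:
    def test_reduces_to_mono_formula_at_tx_zero(self, params):
        m = PiecewiseLinExpDoseRate(
            [DoseRateSample(0.0, 1.0)], tx=0.0, lambda_e=0.05
        )
        assert g_hybrid(m, params).G == pytest.approx(
            g_mono(0.05, params), rel=1e-14
        )

    def test_regression_value_against_oracle(self, piecewise_example, params):
        bd = g_hybrid(piecewise_example, params)
        go = g_oracle(
            piecewise_example.ddot, params,
            horizon=max(2000.0, 40.0 / piecewise_example.lambda_e),
            points=[1.0, 4.0, 24.0, 72.0],
        )
        assert bd.G == pytest.approx(go, rel=1e-4)
        # frozen regression value (double-quadrature oracle, this model)
        assert bd.G == pytest.approx(0.0352163, abs=5e-6)

    def test_no_repair_gives_unity(self, piecewise_example, params_no_repair):
        assert g_hybrid(piecewise_example, params_no_repair).G == pytest.approx(
            1.0, rel=1e-6
        )

    def test_breakdown_decomposition(self, piecewise_example, params):
        bd = g_hybrid(piecewise_example, params)
        mu, le = params.mu, piecewise_example.lambda_e
        dtx = piecewise_example.ddot_tx
        cross = bd.M * dtx * math.exp(-mu * piecewise_example.tx) / (le + mu)
        tail = dtx**2 / (2.0 * le * (le + mu))
        assert bd.R == pytest.approx(bd.N + cross + tail, rel=1e-12)
        assert 0.0 < bd.G <= 1.0 and bd.R <= bd.R0

    def test_strictly_decreasing_in_repair_rate(self, piecewise_example):
        mus = np.linspace(0.0, 3.0, 16)
        gs = [
            g_hybrid(
                piecewise_example, RadiobiologicalParams.from_mu(10.0, mu)
            ).G
            for mu in mus
        ]
        assert np.all(np.diff(gs) < 0.0)

    def test_dt_halving_stability(self, piecewise_example, params):
        g1 = g_hybrid(piecewise_example, params, IntegrationConfig(dt=0.01)).G
        g2 = g_hybrid(piecewise_example, params, IntegrationConfig(dt=0.005)).G
        assert abs(g1 - g2) / g2 < 1e-4


class TestOracle:
    def test_no_repair_unity(self, biexp, params_no_repair):
        assert g_oracle(biexp.ddot, params_no_repair, horizon=2000.0) == pytest.approx(
            1.0, rel=1e-6
        )


class TestIntegrationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": 0.0},
            {"stop_time": -1.0},
            {"auto_stop_step": 0.0},
            {"auto_stop_rel_tol": 1.5},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IntegrationConfig(**kwargs)
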