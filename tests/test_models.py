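"""Dose-rate model evaluation, total-dose closed forms, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from eqdx.models import (
    BiexponentialDoseRate,
    DoseRateSample,
    MonoexponentialDoseRate,
    PiecewiseLinExpDoseRate,
    RadiobiologicalParams,
    ddot_biexp,
    ddot_piecewise,
    total_dose_biexp,
    total_dose_piecewise,
)


class TestRadiobiologicalParams:
    def test_derived_rate_constants(self):
        p = RadiobiologicalParams(alpha_beta=10.0, trep=1.5, phys_half_life=159.528)
        assert p.mu == math.log(2.0) / 1.5
        assert p.phys_lambda == math.log(2.0) / 159.528

    def test_no_repair_limit(self):
        assert RadiobiologicalParams.from_mu(10.0, 0.0).mu == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha_beta": 0.0, "trep": 1.5},
            {"alpha_beta": 10.0, "trep": -1.0},
            {"alpha_beta": 10.0, "trep": 1.5, "phys_half_life": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RadiobiologicalParams(**kwargs)


class TestBiexponential:
    def test_zero_at_injection_and_at_infinity(self, biexp):
        assert ddot_biexp(biexp, 0.0) == 0.0
        assert ddot_biexp(biexp, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_matches_two_phase_clearance_form(self, biexp):
        # independent evaluation via A e^{-l1 t} + B e^{-l2 t} with B = -A,
        # rates split into biological + physical parts
        lam = 0.004
        m = BiexponentialDoseRate.from_biological_rates(
            r0=2.0, lambda_1=0.02 - lam, lambda_2=0.5 - lam, phys_lambda=lam
        )
        t = 4.0
        expected = (2.0 * math.exp(-(0.02 - lam) * t)
                    - 2.0 * math.exp(-(0.5 - lam) * t)) * math.exp(-lam * t)
        assert m.ddot(t) == pytest.approx(expected, rel=1e-14)
        assert m.ddot(t) == pytest.approx(biexp.ddot(t), rel=1e-14)

    def test_negative_time_rejected(self, biexp):
        with pytest.raises(ValueError):
            biexp.ddot(-0.1)

    def test_total_dose_closed_form(self, biexp):
        assert total_dose_biexp(biexp) == pytest.approx(96.0, rel=1e-14)

    def test_total_dose_equals_quadrature(self, biexp):
        num, _ = quad(biexp.ddot, 0.0, 2000.0, limit=200)
        assert total_dose_biexp(biexp) == pytest.approx(num, rel=1e-6)

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            BiexponentialDoseRate(r0=2.0, lambda_e1=0.5, lambda_e2=0.5)
        with pytest.raises(ValueError):
            BiexponentialDoseRate(r0=2.0, lambda_e1=0.5, lambda_e2=0.02)

    @given(
        r0=st.floats(0.01, 50.0),
        l1=st.floats(0.001, 0.2),
        ratio=st.floats(1.5, 100.0),
    )
    def test_nonnegative_with_single_interior_peak(self, r0, l1, ratio):
        m = BiexponentialDoseRate(r0=r0, lambda_e1=l1, lambda_e2=l1 * ratio)
        t = np.linspace(0.0, 6.0 * m.peak_time, 4001)
        d = m.ddot(t)
        assert np.all(d >= 0.0)
        k = int(np.argmax(d))
        assert 0 < k < len(d) - 1  # single interior maximum
        assert np.all(np.diff(d[: k]) >= 0.0)
        assert np.all(np.diff(d[k + 1:]) <= 0.0)

    @given(
        r0=st.floats(0.01, 50.0),
        l1=st.floats(0.005, 0.2),
        ratio=st.floats(1.5, 50.0),
    )
    def test_total_dose_matches_quadrature_property(self, r0, l1, ratio):
        m = BiexponentialDoseRate(r0=r0, lambda_e1=l1, lambda_e2=l1 * ratio)
        horizon = 40.0 / l1  # tail beyond contributes < e^-40 relative
        num, _ = quad(m.ddot, 0.0, horizon, limit=400)
        assert m.total_dose() == pytest.approx(num, rel=1e-6)


class TestMonoexponential:
    def test_evaluation_and_total_dose(self):
        m = MonoexponentialDoseRate(d0=1.0, lambda_e=0.05)
        assert m.ddot(0.0) == 1.0
        assert m.ddot(20.0) == pytest.approx(math.exp(-1.0))
        assert m.total_dose() == pytest.approx(20.0)


class TestPiecewise:
    def test_interpolates_through_knots(self, piecewise_example):
        for t, d in [(0, 0), (1, 1), (4, 0.8), (24, 0.4)]:
            assert ddot_piecewise(piecewise_example, t) == pytest.approx(d)

    def test_tail_value(self, piecewise_example):
        # 24 h past the anchor at one tail half-life of 48 h: 0.4 * 2^-0.5
        le = math.log(2.0) / 48.0
        assert ddot_piecewise(piecewise_example, 48.0) == pytest.approx(
            0.4 * math.exp(-le * 24.0), rel=1e-14
        )

    def test_continuity_everywhere(self, piecewise_example):
        t = np.linspace(0.0, 200.0, 20001)
        d = piecewise_example.ddot(t)
        assert np.max(np.abs(np.diff(d))) < 0.02  # no jump at knots or tx

    def test_total_dose_hand_value(self, piecewise_example):
        # trapezoids 0.5 + 2.7 + 12, tail 0.4/(ln2/48)
        expected = 15.2 + 0.4 * 48.0 / math.log(2.0)
        assert total_dose_piecewise(piecewise_example) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(42.90, abs=0.005)

    def test_total_dose_equals_quadrature(self, piecewise_example):
        num, _ = quad(
            piecewise_example.ddot, 0.0, 3000.0,
            points=[1.0, 4.0, 24.0, 72.0], limit=400,
        )
        tail = piecewise_example.ddot(3000.0) / piecewise_example.lambda_e
        assert total_dose_piecewise(piecewise_example) == pytest.approx(
            num + tail, rel=1e-6
        )

    def test_single_sample_pure_exponential(self):
        m = PiecewiseLinExpDoseRate(
            [DoseRateSample(0.0, 2.0)], tx=0.0, lambda_e=0.1
        )
        assert m.total_dose() == pytest.approx(20.0)
        assert m.ddot(10.0) == pytest.approx(2.0 * math.exp(-1.0))

    def test_zero_anchor_prepended(self):
        m = PiecewiseLinExpDoseRate(
            [DoseRateSample(2.0, 1.0), DoseRateSample(4.0, 0.5)],
            tx=2.0, lambda_e=0.1,
        )
        assert m.ddot(0.0) == 0.0
        assert m.ddot(1.0) == pytest.approx(0.5)

    def test_invalid_construction_rejected(self):
        s = [DoseRateSample(1.0, 1.0), DoseRateSample(4.0, 0.5)]
        with pytest.raises(ValueError):
            PiecewiseLinExpDoseRate(s, tx=3.0, lambda_e=0.1)  # tx off-knot
        with pytest.raises(ValueError):
            PiecewiseLinExpDoseRate(s, tx=1.0, lambda_e=-0.1)
        with pytest.raises(ValueError):
            DoseRateSample(1.0, -0.5)  # negative dose rate
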