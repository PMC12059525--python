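import math

import pytest
from hypothesis import HealthCheck, settings

from eqdx import (
    BiexponentialDoseRate,
    DoseRateSample,
    PiecewiseLinExpDoseRate,
    RadiobiologicalParams,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Tumor-like radiobiology: alpha/beta = 10 Gy, T_rep = 1.5 h, 177Lu."""
    return RadiobiologicalParams(alpha_beta=10.0, trep=1.5)


@pytest.fixture
def params_no_repair():
    return RadiobiologicalParams.from_mu(alpha_beta=10.0, mu=0.0)


@pytest.fixture
def biexp():
    """Generic validation curve: peak ~6.7 h, 35 h effective tail."""
    return BiexponentialDoseRate(r0=2.0, lambda_e1=0.02, lambda_e2=0.5)


@pytest.fixture
def piecewise_example():
    """Hand-checkable five-point piecewise model: tail anchored at 24 h
    with a 48 h effective half-life (from the last two samples)."""
    samples = [
        DoseRateSample(0.0, 0.0),
        DoseRateSample(1.0, 1.0),
        DoseRateSample(4.0, 0.8),
        DoseRateSample(24.0, 0.4),
        DoseRateSample(72.0, 0.2),
    ]
    return PiecewiseLinExpDoseRate(
        samples=samples, tx=24.0, lambda_e=math.log(2.0) / 48.0
    )
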