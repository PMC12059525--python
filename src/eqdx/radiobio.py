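"""Relative effectiveness, BED and equieffective dose (EQDX) conversions.

Under the linear-quadratic model, a protracted irradiation delivering total
dose D with protraction factor G has relative effectiveness

    RE = 1 + G * D / (alpha/beta),

biologically effective dose BED = D * RE (the equieffective dose at
vanishing reference fraction size, EQD0), and equieffective dose in X-Gy
fractions

    EQDX = BED / (1 + X / (alpha/beta)).

The same alpha/beta is assumed for the reference and test radiations, so
ratios of EQDX values at any common X reduce to ratios of BEDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .models import BiexponentialDoseRate, RadiobiologicalParams

__all__ = [
    "FractionationScheme",
    "EqdxResult",
    "re_from_g",
    "re_biexp",
    "bed",
    "eqdx_from_bed",
    "eqdx_ebrt",
    "compute_eqdx",
    "multi_cycle",
]


@dataclass(frozen=True)
class FractionationScheme:
    """Reference fractionation: X Gy per fraction of the reference schedule
    (2 Gy for EQD2), optional test dose per fraction d (EBRT use), and a
    fraction/cycle count for multi-cycle reporting."""

    X: float = 2.0
    d: float = 0.0
    n_fractions: int = 1

    def __post_init__(self) -> None:
        if not self.X > 0:
            raise ValueError("X must be > 0")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


@dataclass(frozen=True)
class EqdxResult:
    """A (D, RE, BED, EQDX) bundle at a given reference fraction size X."""

    D: float
    RE: float
    BED: float
    EQDX: float
    X: float
    alpha_beta: float

    def to_dict(self) -> dict:
        return asdict(self)


def re_from_g(D: float, G: float, alpha_beta: float) -> float:
    """RE = 1 + G * D / (alpha/beta)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be > 0")
    return 1.0 + G * D / alpha_beta


def re_biexp(model: BiexponentialDoseRate, params: RadiobiologicalParams) -> float:
    """Direct closed-form RE for a biexponential dose rate, using the
    expanded total dose:

    RE = 1 + r0 (l1 + l2 + mu)(l2 - l1) /
             [(l1 + l2)(l1 + mu)(l2 + mu) (alpha/beta)]

    Algebraically identical to assembling RE from the closed-form G and D;
    kept as an independent expression for cross-checking.
    """
    l1, l2 = model.lambda_e1, model.lambda_e2
    mu = params.mu
    return 1.0 + (
        model.r0 * (l1 + l2 + mu) * (l2 - l1)
    ) / ((l1 + l2) * (l1 + mu) * (l2 + mu) * params.alpha_beta)


def bed(D: float, RE: float) -> float:
    """BED = D * RE (Gy)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if RE < 1:
        raise ValueError("RE must be >= 1")
    return D * RE


def eqdx_from_bed(BED: float, X: float, alpha_beta: float) -> float:
    """EQDX = BED / (1 + X/(alpha/beta)); X = 0 returns BED itself."""
    if BED < 0:
        raise ValueError("BED must be >= 0")
    if X < 0:
        raise ValueError("X must be >= 0")
    return BED / (1.0 + X / alpha_beta)


def eqdx_ebrt(D: float, d: float, X: float, alpha_beta: float) -> float:
    """Fractionated external-beam form: EQDX = D (1 + d/(a/b)) / (1 + X/(a/b))."""
    if D < 0 or d < 0:
        raise ValueError("doses must be >= 0")
    return D * (1.0 + d / alpha_beta) / (1.0 + X / alpha_beta)


def compute_eqdx(
    D: float, G: float, params: RadiobiologicalParams, X: float = 2.0
) -> EqdxResult:
    """Assemble the full (D, G) -> RE -> BED -> EQDX chain."""
    RE = re_from_g(D, G, params.alpha_beta)
    B = bed(D, RE)
    return EqdxResult(
        D=D, RE=RE, BED=B, EQDX=eqdx_from_bed(B, X, params.alpha_beta),
        X=X, alpha_beta=params.alpha_beta,
    )


def multi_cycle(result: EqdxResult, n_cycles: int) -> EqdxResult:
    """Per-cycle sum for n identical, well-separated treatment cycles
    (identical kinetics, full inter-cycle repair): D, BED and EQDX scale
    linearly, RE is unchanged."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    return EqdxResult(
        D=result.D * n_cycles,
        RE=result.RE,
        BED=result.BED * n_cycles,
        EQDX=result.EQDX * n_cycles,
        X=result.X,
        alpha_beta=result.alpha_beta,
    )
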