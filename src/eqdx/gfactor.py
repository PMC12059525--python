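"""Engines for the Lea-Catcheside dose-protraction factor G.

The G factor quantifies how sublethal-damage repair during protracted
irradiation reduces the quadratic kill term of the linear-quadratic model.
With a single-phase exponential repair kernel ``psi(t) = exp(-mu t)`` and
complete decay of the source,

    G = R / R0,
    R  = int_0^inf dt Ddot(t) int_0^t dt' Ddot(t') exp(-mu (t - t')),
    R0 = D^2 / 2,

so G in (0, 1]: R counts interacting sublesion pairs that survive repair,
R0 the same count with repair switched off.

Four interchangeable routes are provided:

* :func:`g_analytic_biexp` — closed form for a biexponential dose rate.
* :func:`g_mono` — the classic single-exponential limit lambda_e /
  (lambda_e + mu).
* :func:`g_numerical` — the trapezoid dynamic-programming recursion of
  Hobbs & Sgouros on a uniform grid, run to a finite stopping time.  Its
  inner integral carries an exp(+mu t) factor, so it overflows float64 once
  mu*t exceeds ~709; a guard detects this and reports a partial result
  instead of crashing.  The recursion itself is kept faithful to the
  published algorithm (no log-domain rescaling).
* :func:`g_hybrid` — the recursion on [0, tx] only, with the exponential
  tail beyond the last interpolated sample folded in analytically, which
  removes both the stopping-time choice and the overflow risk.

:func:`g_oracle` is an independent brute-force double quadrature of the
defining integral, used in validation only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad

from .models import (
    BiexponentialDoseRate,
    MonoexponentialDoseRate,
    PiecewiseLinExpDoseRate,
    RadiobiologicalParams,
)

__all__ = [
    "IntegrationConfig",
    "GFactorBreakdown",
    "NumericalOverflowError",
    "OVERFLOW_EXPONENT",
    "g_analytic_biexp",
    "g_mono",
    "g_numerical",
    "g_hybrid",
    "g_oracle",
]

#: Largest exponent mu*t allowed in the numerical recursion before the
#: overflow guard fires (float64 overflows at exp(709.78); margin ~10).
OVERFLOW_EXPONENT = 700.0


@dataclass(frozen=True)
class IntegrationConfig:
    """Settings for the grid-based engines.

    dt : time bin width in hours (default 0.01 h).
    stop_time : termination time tau in hours for the numerical engine;
        with ``auto_stop`` it is the starting stop time.
    auto_stop : extend the stopping time in steps of ``auto_stop_step``
        until successive dose/pair-integral outputs change by less than
        ``auto_stop_rel_tol`` (defaults: start 72 h, 10 h steps, 0.1%).
    """

    dt: float = 0.01
    stop_time: float = 2000.0
    auto_stop: bool = False
    auto_stop_step: float = 10.0
    auto_stop_rel_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.stop_time > 0:
            raise ValueError("stop_time must be > 0")
        if not self.auto_stop_step > 0:
            raise ValueError("auto_stop_step must be > 0")
        if not 0 < self.auto_stop_rel_tol < 1:
            raise ValueError("auto_stop_rel_tol must be in (0, 1)")


@dataclass
class GFactorBreakdown:
    """Interim and derived quantities of a G-factor computation.

    N is the double integral over the numerical window, M the inner
    integral at its end (hybrid engine; 0 for tx = 0), R the total
    sublethal-pair integral, R0 = D^2/2 its no-repair normaliser, D the
    total absorbed dose on the window used, and G = R/R0.
    """

    N: float
    M: float
    R: float
    R0: float
    D: float
    G: float
    stop_time_used: float
    overflowed: bool = False

    def to_dict(self) -> dict:
        """JSON-serialisable representation."""
        d = asdict(self)
        d["overflowed"] = bool(d["overflowed"])
        return d


class NumericalOverflowError(FloatingPointError):
    """The numerical recursion hit the exp(mu*t) overflow guard.

    Carries the partial result (computed up to the last safe stop time) in
    ``breakdown``.
    """

    def __init__(self, breakdown: GFactorBreakdown):
        self.breakdown = breakdown
        super().__init__(
            "exp(mu*t) exceeds float64 range beyond "
            f"t = {breakdown.stop_time_used:.2f} h; partial result attached"
        )


# ---------------------------------------------------------------------------
# Closed forms


def g_analytic_biexp(
    model: BiexponentialDoseRate, params: RadiobiologicalParams
) -> float:
    """Closed-form G for a biexponential dose rate:

    G = l1 l2 (l1 + l2 + mu) / [(l1 + l2)(l1 + mu)(l2 + mu)]

    with l1 = lambda_e1, l2 = lambda_e2.  Independent of the amplitude r0;
    equals 1 when mu = 0.
    """
    l1, l2, mu = model.lambda_e1, model.lambda_e2, params.mu
    return (l1 * l2 * (l1 + l2 + mu)) / ((l1 + l2) * (l1 + mu) * (l2 + mu))


def g_mono(lambda_e: float, params: RadiobiologicalParams) -> float:
    """G for single-phase exponential decay: lambda_e / (lambda_e + mu)."""
    if not lambda_e > 0:
        raise ValueError("lambda_e must be > 0")
    return lambda_e / (lambda_e + params.mu)


# ---------------------------------------------------------------------------
# Grid recursion core


def _eval_ddot(ddot: Callable, t: np.ndarray) -> np.ndarray:
    """Evaluate a dose-rate callable on a grid, tolerating scalar-only
    callables."""
    try:
        out = np.asarray(ddot(t), dtype=float)
        if out.shape == t.shape:
            return out
    except Exception:
        pass
    return np.asarray([float(ddot(x)) for x in t], dtype=float)


def _grid(stop_time: float, dt: float) -> np.ndarray:
    n = max(1, int(math.ceil(stop_time / dt - 1e-9)))
    return np.linspace(0.0, stop_time, n + 1)


def _recursion(
    ddot: Callable, mu: float, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative trapezoid recursions on grid ``t``.

    Returns (D_m, M_m, N_m) where
      M_m = M_{m-1} + (Ddot_m e^{mu t_m} + Ddot_{m-1} e^{mu t_{m-1}}) dt/2
      N_m = N_{m-1} + (Ddot_m M_m e^{-mu t_m}
                       + Ddot_{m-1} M_{m-1} e^{-mu t_{m-1}}) dt/2
    and D_m is the running trapezoid dose.  Caller must ensure
    mu * t <= OVERFLOW_EXPONENT.
    """
    d = _eval_ddot(ddot, t)
    M = cumulative_trapezoid(d * np.exp(mu * t), t, initial=0.0)
    N = cumulative_trapezoid(d * M * np.exp(-mu * t), t, initial=0.0)
    D = cumulative_trapezoid(d, t, initial=0.0)
    return D, M, N


def recursion_profile(
    ddot: Callable, params: RadiobiologicalParams, cfg: IntegrationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Run the numerical recursion once to ``cfg.stop_time`` (truncated at
    the overflow guard) and return the full running arrays
    ``(t, D_m, N_m, overflowed)``.  Used by the convergence study driver so
    a whole profile costs one pass."""
    mu = params.mu
    t = _grid(cfg.stop_time, cfg.dt)
    overflowed = False
    if mu > 0 and mu * t[-1] > OVERFLOW_EXPONENT:
        t = t[mu * t <= OVERFLOW_EXPONENT]
        overflowed = True
    D, _, N = _recursion(ddot, mu, t)
    return t, D, N, overflowed


def g_numerical(
    ddot: Callable,
    params: RadiobiologicalParams,
    cfg: IntegrationConfig | None = None,
    raise_on_overflow: bool = False,
) -> GFactorBreakdown:
    """Fully numerical G on a uniform grid (Hobbs-Sgouros recursion).

    ``ddot`` is any nonnegative dose-rate callable defined on
    [0, stop_time].  G = N(stop)/ (D(stop)^2 / 2) with both integrals taken
    on the same grid.  With ``cfg.auto_stop`` the stop time is extended in
    ``auto_stop_step`` increments until both D and N change by less than
    ``auto_stop_rel_tol`` between consecutive stops.

    If mu * stop_time exceeds the float64 overflow guard the computation is
    truncated at the last safe grid time and flagged ``overflowed=True``
    (or raised as :class:`NumericalOverflowError` carrying the same partial
    breakdown when ``raise_on_overflow``).
    """
    cfg = cfg or IntegrationConfig()
    mu = params.mu
    t_safe = math.inf if mu == 0 else OVERFLOW_EXPONENT / mu

    def compute(stop: float) -> tuple[float, float, float]:
        t = _grid(stop, cfg.dt)
        D, _, N = _recursion(ddot, mu, t)
        return float(D[-1]), float(N[-1]), float(t[-1])

    stop = cfg.stop_time
    overflowed = stop > t_safe
    stop = min(stop, t_safe)
    D, N, used = compute(stop)

    if cfg.auto_stop:
        converged = False
        while not converged:
            nxt = stop + cfg.auto_stop_step
            if nxt > t_safe:
                overflowed = True
                break
            D2, N2, used = compute(nxt)
            dD = abs(D2 - D) / D2 if D2 > 0 else 0.0
            dN = abs(N2 - N) / N2 if N2 > 0 else 0.0
            D, N, stop = D2, N2, nxt
            converged = max(dD, dN) < cfg.auto_stop_rel_tol

    G = 2.0 * N / D**2 if D > 0 else 0.0
    bd = GFactorBreakdown(
        N=N, M=0.0, R=N, R0=D**2 / 2.0, D=D, G=G,
        stop_time_used=used, overflowed=overflowed,
    )
    if overflowed and raise_on_overflow:
        raise NumericalOverflowError(bd)
    return bd


def g_hybrid(
    model: PiecewiseLinExpDoseRate,
    params: RadiobiologicalParams,
    cfg: IntegrationConfig | None = None,
) -> GFactorBreakdown:
    """Hybrid numerical-analytical G for a piecewise linear + exponential
    dose rate.

    The recursion supplies N (pair integral on [0, tx]) and
    M = int_0^tx Ddot(t') e^{mu t'} dt'; the exponential tail contributes a
    cross term and a tail term in closed form:

        R = N + M Ddot(tx) e^{-mu tx} / (lambda_e + mu)
              + Ddot(tx)^2 / (2 lambda_e (lambda_e + mu))

    and G = R / (D^2/2) with D the piecewise total dose.  No extrapolation
    beyond tx is needed; mu*tx stays small for clinical scan schedules, so
    overflow cannot occur in practice.  For tx = 0 this reduces exactly to
    the monoexponential formula lambda_e / (lambda_e + mu).
    """
    cfg = cfg or IntegrationConfig()
    mu = params.mu
    le = model.lambda_e
    tx = model.tx
    dtx = model.ddot_tx
    if tx > 0:
        # uniform grid augmented with the sample knots, so trapezoid
        # segments never straddle an interpolation kink
        t = np.union1d(_grid(tx, cfg.dt), model._kt)
        _, Marr, Narr = _recursion(model.ddot, mu, t)
        M = float(Marr[-1])
        N = float(Narr[-1])
    else:
        M = N = 0.0
    D = model.total_dose()
    cross = M * dtx * math.exp(-mu * tx) / (le + mu)
    tail = dtx**2 / (2.0 * le * (le + mu))
    R = N + cross + tail
    return GFactorBreakdown(
        N=N, M=M, R=R, R0=D**2 / 2.0, D=D, G=2.0 * R / D**2,
        stop_time_used=tx, overflowed=False,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle


def g_oracle(
    ddot: Callable,
    params: RadiobiologicalParams,
    horizon: float,
    points: Sequence[float] = (),
) -> float:
    """Independent evaluation of the defining double integral by nested
    adaptive quadrature.  Validation only — never the fast path.

    ``horizon`` truncates the outer integral; choose it so the tail beyond
    contributes < 1e-8 relative (≈ 40 / slowest effective rate).
    ``points`` lists breakpoints (e.g. interpolation knots) passed to the
    quadrature for accuracy on piecewise integrands.
    """
    mu = params.mu
    epsabs, epsrel = 1e-12, 1e-9
    pts = sorted(p for p in points if 0.0 < p < horizon)
    # repair kernel support: below t - 60/mu the kernel is < e^-60
    kernel_span = math.inf if mu == 0 else 60.0 / mu

    def inner(t: float) -> float:
        if t == 0.0:
            return 0.0
        lo_split = max(0.0, t - kernel_span) if mu > 0 else 0.0

        def f(tp: float) -> float:
            return ddot(tp) * math.exp(-mu * (t - tp))

        total = 0.0
        if lo_split > 0.0:
            p0 = [p for p in pts if p < lo_split]
            total += quad(
                f, 0.0, lo_split, points=p0 or None,
                epsabs=epsabs, epsrel=epsrel, limit=200,
            )[0]
        p1 = [p for p in pts if lo_split < p < t]
        total += quad(
            f, lo_split, t, points=p1 or None,
            epsabs=epsabs, epsrel=epsrel, limit=200,
        )[0]
        return total

    def outer(t: float) -> float:
        return ddot(t) * inner(t)

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            num, num_err = quad(
                outer, 0.0, horizon, points=pts or None,
                epsabs=epsabs, epsrel=1e-8, limit=500,
            )
            D, _ = quad(
                ddot, 0.0, horizon, points=pts or None,
                epsabs=epsabs, epsrel=epsrel, limit=500,
            )
        except UserWarning as w:  # IntegrationWarning from quad
            raise RuntimeError(f"oracle quadrature did not converge: {w}")
    if num > 0 and num_err / num > 1e-6:
        raise RuntimeError(
            f"oracle quadrature error estimate too large: {num_err / num:.2e}"
        )
    return num / (D**2 / 2.0)
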