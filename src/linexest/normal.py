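"""Shrinkage estimators for the normal mean mu, mu^2 and sigma^2.

With a known coefficient of variation ``v = sigma/mu`` the sample mean can be
improved by shrinking: the estimator ``s * abar`` with ``s = n/(n + v^2)``
has MSE strictly below ``sigma^2/n``.  Under the invariant LINEX loss the
optimal shrinkage coefficient moves away from the MSE-optimal one; this
module provides exact invariant-LINEX risks (via the normal and noncentral
chi-square MGFs), their numeric minimisers, and the cubic-Taylor
approximations that admit closed-form optima.

All invariant-form results assume mu > 0 (v finite and positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import optimize

from .core import LinexParams

__all__ = [
    "NormalSummary",
    "optimal_shrink_mean_mse",
    "invariant_risk_mean",
    "optimal_shrink_mean_linex",
    "mvue_mu2",
    "optimal_shrink_mu2_mse",
    "invariant_risk_mu2",
    "truncated_risk_mu2",
    "optimal_shrink_mu2_linex",
    "sigma2_divisor_mse",
]


@dataclass(frozen=True)
class NormalSummary:
    """Sufficient summary of a normal sample.

    ``d2`` is the sample variance with divisor n-1 (so ``E[d2] = sigma^2``,
    which the MVUE of mu^2 requires); ``v = sigma/mu`` is the coefficient of
    variation, assumed known where a method needs it.
    """

    n: int
    xbar: float
    d2: float = 0.0
    v: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.d2 < 0:
            raise ValueError("sample variance d2 must be nonnegative")
        if self.v is not None and not self.v > 0:
            raise ValueError("coefficient of variation v must be positive")


def optimal_shrink_mean_mse(n: int, v: float) -> Tuple[float, float]:
    """MSE-optimal shrinkage of the sample mean: s = n/(n + v^2).

    Returns ``(s, relative_mse)`` where ``relative_mse = MSE(s*abar)/sigma^2
    = (1/n) / (1 + v^2/n) < 1/n``.
    """
    if n < 1 or not v > 0:
        raise ValueError("need n >= 1 and v > 0")
    s = n / (n + v * v)
    rel = (1.0 / n) / (1.0 + v * v / n)
    return s, rel


def invariant_risk_mean(z: float, n: int, v: float,
                        params: LinexParams) -> float:
    """Exact invariant-LINEX risk of the estimator z*abar for mu.

    With W = abar/mu ~ N(1, v^2/n) the normal MGF gives
    E e^{a z W} = exp(a z + a^2 z^2 v^2 / (2n)), hence

        risk = b * [exp(a(z-1) + a^2 z^2 v^2/(2n)) - a(z-1) - 1].
    """
    a, b = params.a, params.b
    g = a * (z - 1.0) + a * a * z * z * v * v / (2.0 * n)
    return b * (math.expm1(g) - a * (z - 1.0))


def _scaled_risk_mean(z: float, n: int, v: float, a: float) -> float:
    # (2/a^2) * risk -- same minimiser, O(1) values so the minimiser stays
    # resolvable in floating point even for tiny a
    g = a * (z - 1.0) + a * a * z * z * v * v / (2.0 * n)
    return 2.0 * (math.expm1(g) - a * (z - 1.0)) / (a * a)


def _cubic_root_shrink(m1: float, m2: float, m3: float, a: float) -> float:
    """Positive root of the cubic-truncation stationarity quadratic.

    Truncating the loss to u^2/2 + u^3/6 with u = a*(z*W - 1) and taking
    moments m_j = E W^j gives risk ∝ E u^2/2 + E u^3/6; d/dz = 0 yields

        a*m3*z^2 + 2(1-a)*m2*z + (a-2)*m1 = 0,

    whose larger root tends to the MSE optimum m1/m2 as a -> 0.
    """
    disc = (1.0 - a) ** 2 * m2 * m2 + a * (2.0 - a) * m1 * m3
    if disc < 0:
        raise FloatingPointError("truncated stationarity has no real root")
    return ((a - 1.0) * m2 + math.sqrt(disc)) / (a * m3)


def optimal_shrink_mean_linex(n: int, v: float,
                              params: LinexParams) -> Tuple[float, float]:
    """LINEX-optimal shrinkage of the sample mean.

    Returns ``(z_min, z_approx)``: the numeric minimiser of the exact
    invariant risk, and the closed-form root of the cubic-truncated
    stationarity condition (accurate for small a; the approximation regime
    is roughly 0 < a <= 0.6).
    """
    if n < 1 or not v > 0:
        raise ValueError("need n >= 1 and v > 0")
    a = params.a
    res = optimize.minimize_scalar(
        _scaled_risk_mean, args=(n, v, a), bounds=(0.0, 2.0),
        method="bounded", options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError(f"risk minimisation failed: {res.message}")
    t = v * v / n
    z_approx = _cubic_root_shrink(1.0, 1.0 + t, 1.0 + 3.0 * t, a)
    return float(res.x), z_approx


def mvue_mu2(summary: NormalSummary) -> float:
    """MVUE of mu^2 when v is unknown: abar^2 - d2/n.

    Unbiased (E abar^2 = mu^2 + sigma^2/n and E d2 = sigma^2) but can be
    negative in small samples.
    """
    if summary.n < 2:
        raise ValueError("MVUE of mu^2 needs n >= 2 (uses the sample variance)")
    return summary.xbar**2 - summary.d2 / summary.n


def _mu2_moments(n: int, v: float) -> Tuple[float, float, float]:
    # moments of W = abar^2/mu^2 from exact normal moments of abar ~ N(mu, s2/n)
    t = v * v / n
    m1 = 1.0 + t
    m2 = 1.0 + 6.0 * t + 3.0 * t * t
    m3 = 1.0 + 15.0 * t + 45.0 * t * t + 15.0 * t**3
    return m1, m2, m3


def optimal_shrink_mu2_mse(n: int, v: float) -> float:
    """MSE-optimal coefficient t2 in the estimator t2*abar^2 of mu^2.

    t2 = E[abar^2] mu^2 / E[abar^4] = (1 + v^2/n) / (1 + 6v^2/n + 3v^4/n^2),
    always < 1 (shrinkage) and -> 1 as v -> 0.
    """
    if n < 1 or not v > 0:
        raise ValueError("need n >= 1 and v > 0")
    m1, m2, _ = _mu2_moments(n, v)
    return m1 / m2


def invariant_risk_mu2(t: float, n: int, v: float,
                       params: LinexParams) -> float:
    """Exact invariant-LINEX risk of t*abar^2 as an estimator of mu^2.

    abar^2 is a scaled noncentral chi-square, so with s = a*t/mu^2

        E e^{s abar^2} = (1 - 2 s sigma^2/n)^{-1/2} exp(s mu^2/(1 - 2 s sigma^2/n))

    finite only for s < n/(2 sigma^2), i.e. a*t < n/(2 v^2) in invariant
    units; beyond that the MGF diverges and a ValueError is raised.
    """
    a, b = params.a, params.b
    m1, _, _ = _mu2_moments(n, v)
    c = a * t * v * v / n  # s * sigma^2 / n in invariant units
    if 2.0 * c >= 1.0:
        raise ValueError(
            f"MGF diverges: need a*t < n/(2 v^2) = {n / (2 * v * v):.6g}, "
            f"got a*t = {a * t:.6g}")
    log_mgf = -0.5 * math.log1p(-2.0 * c) + a * t / (1.0 - 2.0 * c)
    # expm1 keeps the O(a^2) risk resolvable for small a
    return b * (math.expm1(-a + log_mgf) - a * (t * m1 - 1.0))


def truncated_risk_mu2(t: float, n: int, v: float,
                       params: LinexParams) -> float:
    """Cubic-Taylor ('truncated') invariant-LINEX risk of t*abar^2.

    b * (a^2/2 * E D*^2 + a^3/6 * E D*^3) with D* = t*W - 1 and exact normal
    moments of W = abar^2/mu^2.  This is the paper-style truncation that the
    closed-form optimum is derived from; agrees with the exact risk to O(a)
    for small a.
    """
    a, b = params.a, params.b
    m1, m2, m3 = _mu2_moments(n, v)
    e2 = t * t * m2 - 2.0 * t * m1 + 1.0
    e3 = t**3 * m3 - 3.0 * t * t * m2 + 3.0 * t * m1 - 1.0
    return b * (a * a * e2 / 2.0 + a**3 * e3 / 6.0)


def optimal_shrink_mu2_linex(n: int, v: float,
                             params: LinexParams) -> Tuple[float, float]:
    """LINEX-optimal coefficient for t*abar^2 estimating mu^2.

    Returns ``(t4_min, t4_approx)``: numeric argmin of the exact risk
    (within the MGF domain) and the closed-form root of the truncated
    stationarity quadratic.  Both tend to `optimal_shrink_mu2_mse` as a -> 0.
    """
    if n < 1 or not v > 0:
        raise ValueError("need n >= 1 and v > 0")
    a = params.a
    m1, m2, m3 = _mu2_moments(n, v)
    hi = 2.0
    if a > 0:
        hi = min(hi, 0.999 * n / (2.0 * a * v * v))

    def scaled(t: float) -> float:
        return invariant_risk_mu2(t, n, v, LinexParams(a)) * 2.0 / (a * a)

    res = optimize.minimize_scalar(scaled, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError(f"risk minimisation failed: {res.message}")
    t4_approx = _cubic_root_shrink(m1, m2, m3, a)
    return float(res.x), t4_approx


def sigma2_divisor_mse(n: int, d: float) -> float:
    """Relative MSE of the sigma^2 estimator SS/d, SS = sum (x_i - abar)^2.

    MSE(SS/d)/sigma^4 = 2(n-1)/d^2 + ((n-1)/d - 1)^2: equals 2/(n-1) at the
    unbiased divisor d = n-1, and is minimised at d = n+1 with value 2/(n+1).
    """
    if n < 2 or not d > 0:
        raise ValueError("need n >= 2 and d > 0")
    m = n - 1
    return 2.0 * m / d**2 + (m / d - 1.0) ** 2
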