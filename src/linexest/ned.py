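"""Minimum-risk estimators of the negative-exponential scale theta and theta^2.

For a sample of size n from the negative exponential distribution (NED) with
mean theta, the sample mean abar is Gamma(n, scale theta/n) (equivalently
2 n abar / theta is chi-square with 2n df).  Shrinking abar improves it:
``n/(n+1) * abar`` has MSE theta^2/(n+1) < theta^2/n.  Under the invariant
LINEX loss the risk of ``z * abar`` is available exactly through the gamma
MGF and has the closed-form optimum

    z_min = (n/a) * (1 - exp(-a/(n+1))).

For theta^2 the estimator ``z5 * abar^2`` is handled through the cubic-Taylor
truncated risk only: the exact invariant risk involves E exp(s*abar^2) for a
gamma variable, which is infinite for any s > 0, so a truncation is the only
finite risk available — the API flags those results as truncated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

from .core import LinexParams

__all__ = [
    "NedSummary",
    "shrink_scale_mse",
    "invariant_risk_scale",
    "optimal_shrink_scale_linex",
    "shrink_scale2_mse",
    "truncated_risk_scale2",
    "optimal_shrink_scale2_linex",
]


@dataclass(frozen=True)
class NedSummary:
    """Size and sample mean of a negative-exponential sample (mean theta)."""

    n: int
    xbar: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.xbar > 0:
            raise ValueError("sample mean must be positive")


def shrink_scale_mse(n: int) -> Tuple[float, float]:
    """MSE-optimal shrinkage of abar for theta: s = n/(n+1).

    Returns (s, relative_mse) with relative_mse = MSE(s*abar)/theta^2
    = 1/(n+1), strictly below the 1/n of the unbiased abar.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return n / (n + 1), 1.0 / (n + 1)


def invariant_risk_scale(z: float, n: int, params: LinexParams) -> float:
    """Exact invariant-LINEX risk of z*abar for theta.

    With W = abar/theta ~ Gamma(n, scale 1/n), E e^{azW} = (1 - az/n)^{-n}
    for a*z < n, giving

        risk = b * [e^{-a} (1 - az/n)^{-n} - a*z + a - 1].
    """
    a, b = params.a, params.b
    if a * z >= n:
        raise ValueError(f"MGF diverges: need a*z < n, got a*z = {a * z}")
    # log-space + expm1 for precision at small a
    g = -a - n * math.log1p(-a * z / n)
    return b * (math.expm1(g) - a * (z - 1.0))


def optimal_shrink_scale_linex(n: int, params: LinexParams) -> float:
    """Exact LINEX-optimal shrinkage z_min = (n/a)(1 - e^{-a/(n+1)}).

    Stationary point of the exact invariant risk; tends to n/(n+1) as
    a -> 0 and stays in (0, 1) for a > 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a = params.a
    return -(n / a) * math.expm1(-a / (n + 1))


def _scale2_moments(n: int) -> Tuple[float, float, float]:
    # exact gamma moments of W = abar^2/theta^2:
    # E abar^{2k} = theta^{2k} * prod_{j=1..2k-1}(n+j) / n^{2k-1}
    m1 = (n + 1) / n
    m2 = (n + 1) * (n + 2) * (n + 3) / n**3
    m3 = (n + 1) * (n + 2) * (n + 3) * (n + 4) * (n + 5) / n**5
    return m1, m2, m3


def shrink_scale2_mse(n: int) -> float:
    """MSE-optimal coefficient for z*abar^2 estimating theta^2.

    E[abar^2] theta^2 / E[abar^4] = n^2 / ((n+2)(n+3)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * n / ((n + 2) * (n + 3))


def truncated_risk_scale2(z5: float, n: int, params: LinexParams) -> float:
    """Cubic-Taylor truncated invariant-LINEX risk of z5*abar^2 for theta^2.

    b * (a^2/2 E D*^2 + a^3/6 E D*^3), D* = z5*W - 1, with the exact gamma
    moments of W = abar^2/theta^2 (sixth moment factor
    (n+1)...(n+5)/n^5).  Only the truncated risk is finite here: the exact
    risk requires E exp(s*abar^2), which diverges for any s > 0.
    """
    if not 0.0 <= z5 <= 1.0:
        warnings.warn(f"z5 = {z5} outside [0, 1], the range the truncated "
                      "optimum is derived for", stacklevel=2)
    a, b = params.a, params.b
    m1, m2, m3 = _scale2_moments(n)
    e2 = z5 * z5 * m2 - 2.0 * z5 * m1 + 1.0
    e3 = z5**3 * m3 - 3.0 * z5 * z5 * m2 + 3.0 * z5 * m1 - 1.0
    return b * (a * a * e2 / 2.0 + a**3 * e3 / 6.0)


def bracket_scale2(n: int, params: LinexParams) -> Tuple[float, float]:
    """Admissible bracket for the truncated optimum.

    Lower end (a-1) n^2 / (a (n+5)(n+4)) is where the truncated risk stops
    being convex; the optimum is sought in [max(lower, 0), 1].
    """
    a = params.a
    return (a - 1.0) * n * n / (a * (n + 5) * (n + 4)), 1.0


def optimal_shrink_scale2_linex(
    n: int, params: LinexParams
) -> Tuple[float, Tuple[float, float]]:
    """Optimal z5 from the truncated-risk stationarity quadratic.

    a*m3*z^2 + 2(1-a)*m2*z + (a-2)*m1 = 0 with gamma moments m_j; the root
    inside the convexity bracket is returned together with the bracket.
    Tends to the MSE optimum n^2/((n+2)(n+3)) as a -> 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a = params.a
    m1, m2, m3 = _scale2_moments(n)
    lo, hi = bracket_scale2(n, params)
    disc = (1.0 - a) ** 2 * m2 * m2 + a * (2.0 - a) * m1 * m3
    if disc < 0:
        raise RuntimeError("stationarity quadratic has no real root")
    roots = [((a - 1.0) * m2 + s * math.sqrt(disc)) / (a * m3)
             for s in (+1.0, -1.0)]
    tol = 1e-12
    inside = [z for z in roots if lo - tol <= z <= hi + tol]
    if not inside:
        raise RuntimeError(
            f"no stationary point inside bracket [{lo:.6g}, {hi:.6g}]; "
            f"roots were {roots}")
    if len(inside) == 2 and not math.isclose(inside[0], inside[1]):
        inside.sort(key=lambda z: truncated_risk_scale2(z, n, params))
    return inside[0], (lo, hi)
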