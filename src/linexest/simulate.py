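"""Synthetic-data generators used by the benchmark harness and tests.

The generators emulate the study conditions the methods assume: exponential
lifetimes with independent exponential right-censoring, normal samples with
known coefficient of variation, and homogeneous Poisson event streams
(the latter lives in :mod:`linexest.poisson` as `simulate_path`).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .survival import CensoredSample
from .normal import NormalSummary

__all__ = ["gen_censored_exponential", "gen_normal", "censor_rate_for_fraction"]


def censor_rate_for_fraction(lam: float, fraction: float) -> float:
    """Exponential censoring rate hitting an expected censored fraction.

    With lifetime rate lam and independent Exp(rate_c) censoring, the
    probability a unit is censored is rate_c/(lam + rate_c); solving for a
    target fraction q gives rate_c = lam*q/(1-q).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("censored fraction must be in [0, 1)")
    return lam * fraction / (1.0 - fraction)


def gen_censored_exponential(n: int, lam: float, censor_fraction: float,
                             seed) -> CensoredSample:
    """One right-censored sample: Exp(lam) lifetimes, independent censoring.

    `censor_fraction` is the expected fraction of censored units (0 gives a
    fully observed sample).  `seed` may be an int, SeedSequence or Generator.
    """
    if not lam > 0:
        raise ValueError("rate lam must be positive")
    rng = np.random.default_rng(seed)
    lifetimes = rng.exponential(1.0 / lam, size=n)
    if censor_fraction == 0:
        return CensoredSample(times=lifetimes, status=np.ones(n, dtype=int))
    rate_c = censor_rate_for_fraction(lam, censor_fraction)
    cens = rng.exponential(1.0 / rate_c, size=n)
    return CensoredSample(times=np.minimum(lifetimes, cens),
                          status=(lifetimes <= cens).astype(int))


def gen_normal(n: int, mu: float, sigma: float, seed
               ) -> Tuple[np.ndarray, NormalSummary]:
    """Normal sample plus its summary (xbar, d2, v = sigma/mu).

    v is only defined for mu != 0; for mu = 0 the summary carries v = None.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if n < 2:
        raise ValueError("need n >= 2 for the sample variance")
    rng = np.random.default_rng(seed)
    x = rng.normal(mu, sigma, size=n)
    v = sigma / mu if mu != 0 else None
    if mu != 0 and v is not None and v < 0:
        v = None  # invariant-form machinery assumes mu > 0
    summary = NormalSummary(n=n, xbar=float(x.mean()),
                            d2=float(x.var(ddof=1)), v=v)
    return x, summary
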