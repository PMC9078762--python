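"""Sequential Bayes estimation of a Poisson intensity under LINEX loss.

A homogeneous Poisson process with unknown intensity theta is observed
continuously; sampling costs c per unit time.  With a Gamma(alpha, scale
beta) prior, the posterior after watching up to time t is
Gamma(alpha + R(t), scale beta/(t*beta + 1)) where R(t) counts events in
[0, t].  The Bayes estimate under LINEX shape a and its posterior risk are

    theta_tilde(t) = ((alpha + R(t))/a) * ln(1 + a*beta/(t*beta + 1)),
    U_t            = (alpha + R(t)) * [x - ln(1 + x)],  x = a*beta/(t*beta+1).

U_t decreases continuously between events and jumps up at each event; the
asymptotically pointwise optimal (APO) rule stops as soon as the posterior
risk no longer exceeds the cost already paid per unit of scaled time:

    tau* = inf{ t >= 0 : U_t <= c * t }.

The scaled risk C_t = t * U_t converges to a^2 * theta / 2 along a path with
true intensity theta, which yields the small-cost approximation
tau* ~ a * sqrt(theta/(2c)).

Beta here is a SCALE (prior mean alpha*beta), the opposite convention from
the survival module; ``GammaDist.from_shape_scale`` converts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .core import GammaDist, LinexParams

__all__ = [
    "PoissonPath",
    "ApoDecision",
    "simulate_path",
    "posterior_at",
    "theta_tilde",
    "posterior_risk_u",
    "scaled_risk_c",
    "apo_stop",
    "sequential_bayes_risk",
]


@dataclass(frozen=True)
class PoissonPath:
    """Ordered event times of one realisation, with the observation horizon."""

    event_times: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", ev)
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")
        if ev.size:
            if ev[0] < 0 or np.any(np.diff(ev) <= 0):
                raise ValueError("event times must be strictly increasing "
                                 "and nonnegative")
            if ev[-1] > self.horizon:
                raise ValueError("event times must not exceed the horizon")

    def count_at(self, t: float) -> int:
        """R(t): number of events in [0, t]."""
        return int(np.searchsorted(self.event_times, t, side="right"))


@dataclass(frozen=True)
class ApoDecision:
    """Outcome of the APO rule on one path."""

    tau: float
    r_at_tau: int
    theta_tilde: float
    posterior_risk: float
    sampling_cost: float
    truncated: bool = False


def simulate_path(theta: float, horizon: float, seed) -> PoissonPath:
    """Homogeneous Poisson path of intensity theta on [0, horizon].

    `seed` may be an int, SeedSequence or Generator.
    """
    if not theta > 0 or not horizon > 0:
        raise ValueError("theta and horizon must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(theta * horizon)
    times = np.sort(rng.uniform(0.0, horizon, size=n))
    return PoissonPath(event_times=times, horizon=horizon)


def _validate_prior(prior_shape: float, prior_scale: float,
                    params: Optional[LinexParams] = None) -> None:
    if not prior_shape > 0 or not prior_scale > 0:
        raise ValueError("prior shape and scale must be positive")
    if params is not None and params.a < 0:
        # regime where the asymptotic-optimality theory is stated for a < 0
        if not (prior_shape > 1 and prior_scale < -1.0 / params.a):
            warnings.warn(
                "for a < 0 the asymptotic theory assumes alpha > 1 and "
                "0 < beta < -1/a; proceeding outside that regime",
                stacklevel=3)


def posterior_at(prior_shape: float, prior_scale: float, path: PoissonPath,
                 t: float) -> GammaDist:
    """Posterior Gamma(alpha + R(t), rate t + 1/beta) at observation time t."""
    _validate_prior(prior_shape, prior_scale)
    if not 0.0 <= t <= path.horizon:
        raise ValueError(f"t = {t} outside [0, horizon = {path.horizon}]")
    return GammaDist(k=prior_shape + path.count_at(t), r=t + 1.0 / prior_scale)


def _xt(prior_scale: float, t, a: float):
    """x = a*beta/(t*beta + 1), the posterior's a/rate."""
    return a * prior_scale / (t * prior_scale + 1.0)


def theta_tilde(prior_shape: float, prior_scale: float, path: PoissonPath,
                t: float, params: LinexParams) -> float:
    """Bayes-LINEX intensity estimate ((alpha + R(t))/a) ln(1 + x)."""
    _validate_prior(prior_shape, prior_scale, params)
    if not 0.0 <= t <= path.horizon:
        raise ValueError(f"t = {t} outside [0, horizon = {path.horizon}]")
    x = _xt(prior_scale, t, params.a)
    if x <= -1.0:
        raise ValueError("posterior MGF diverges: need a*beta/(t*beta+1) > -1")
    k = prior_shape + path.count_at(t)
    return k / params.a * math.log1p(x)


def _u_of(k: float, x: float, b: float = 1.0) -> float:
    return b * k * (x - math.log1p(x))


def posterior_risk_u(prior_shape: float, prior_scale: float, path: PoissonPath,
                     t: float, params: LinexParams) -> float:
    """Posterior LINEX risk U_t = (alpha + R(t)) [x - ln(1 + x)] (times b).

    Continuous and strictly decreasing in t between events, jumping up by
    one posterior-shape unit of risk at each event.
    """
    _validate_prior(prior_shape, prior_scale, params)
    if not 0.0 <= t <= path.horizon:
        raise ValueError(f"t = {t} outside [0, horizon = {path.horizon}]")
    x = _xt(prior_scale, t, params.a)
    if x <= -1.0:
        raise ValueError("posterior MGF diverges: need a*beta/(t*beta+1) > -1")
    return _u_of(prior_shape + path.count_at(t), x, params.b)


def scaled_risk_c(prior_shape: float, prior_scale: float, path: PoissonPath,
                  t: float, params: LinexParams) -> float:
    """C_t = t * U_t; converges to a^2*theta/2 along a long path."""
    if not t > 0:
        raise ValueError("t must be positive")
    return t * posterior_risk_u(prior_shape, prior_scale, path, t, params)


def apo_stop(path: PoissonPath, prior_shape: float, prior_scale: float,
             params: LinexParams, c: float,
             xtol: float = 1e-12) -> ApoDecision:
    """Run the APO rule tau* = inf{t : U_t <= c*t} on one path.

    Within each inter-event interval U_t - c*t is continuous and strictly
    decreasing (U falls, the cost line rises), so there is at most one
    crossing per interval, found by Brent root-finding; U jumps up at each
    event, which is why the scan restarts per interval.  If no crossing
    occurs before the horizon a truncated decision at the horizon is
    returned (flagged).
    """
    if not c > 0:
        raise ValueError("cost rate c must be positive")
    _validate_prior(prior_shape, prior_scale, params)
    a, b, beta = params.a, params.b, prior_scale
    ev = path.event_times
    # interval starts: 0, T_1, ..., T_m ; interval i has R = i events so far
    starts = np.concatenate(([0.0], ev))
    ends = np.concatenate((ev, [path.horizon]))
    ks = prior_shape + np.arange(starts.size)

    def g(t: float, k: float) -> float:
        x = _xt(beta, t, a)
        return _u_of(k, x, b) - c * t

    # vectorised pre-scan: g at interval starts and at left limits of ends
    xs = _xt(beta, starts, a)
    xe = _xt(beta, ends, a)
    g_start = b * ks * (xs - np.log1p(xs)) - c * starts
    g_end = b * ks * (xe - np.log1p(xe)) - c * ends  # left limit at ends

    def decision(tau: float, k_idx: int) -> ApoDecision:
        x = _xt(beta, tau, a)
        k = float(ks[k_idx])
        return ApoDecision(
            tau=float(tau),
            r_at_tau=int(k_idx),
            theta_tilde=k / a * math.log1p(x),
            posterior_risk=_u_of(k, x, b),
            sampling_cost=c * float(tau),
            truncated=False,
        )

    hit_start = np.flatnonzero(g_start <= 0)
    hit_cross = np.flatnonzero(g_end < 0)
    i_start = hit_start[0] if hit_start.size else np.inf
    i_cross = hit_cross[0] if hit_cross.size else np.inf
    if i_start <= i_cross and np.isfinite(i_start):
        i = int(i_start)
        return decision(starts[i], i)
    if np.isfinite(i_cross):
        i = int(i_cross)
        tau = optimize.brentq(g, starts[i], ends[i], args=(ks[i],),
                              xtol=xtol, rtol=4 * np.finfo(float).eps)
        return decision(tau, i)

    # no stop before the horizon
    i = starts.size - 1
    x = _xt(beta, path.horizon, a)
    return ApoDecision(
        tau=float(path.horizon), r_at_tau=i,
        theta_tilde=float(ks[i]) / a * math.log1p(x),
        posterior_risk=_u_of(float(ks[i]), x, b),
        sampling_cost=c * path.horizon, truncated=True,
    )


def sequential_bayes_risk(
    prior_shape: float,
    prior_scale: float,
    params: LinexParams,
    c: float,
    reps: int,
    seed: int,
    horizon: Optional[float] = None,
) -> Tuple[float, float, float]:
    """Monte-Carlo Bayes risk E[b*U_tau* + c*tau*] of the APO rule.

    theta is drawn from the prior for each replicate and a fresh path is
    simulated given theta.  Returns (risk, mean_tau, se_of_risk).  The
    default horizon is five times the small-cost approximation
    a*sqrt(prior_mean/(2c)); replicates still unstopped at the horizon are
    truncated there, with a warning if they exceed 1% of reps.
    """
    if reps < 100:
        raise ValueError("need reps >= 100")
    _validate_prior(prior_shape, prior_scale, params)
    prior_mean = prior_shape * prior_scale
    if horizon is None:
        horizon = 5.0 * max(1.0, abs(params.a) * math.sqrt(prior_mean / (2 * c)))
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    thetas = rng.gamma(shape=prior_shape, scale=prior_scale, size=reps)
    losses = np.empty(reps)
    taus = np.empty(reps)
    n_trunc = 0
    for i, theta in enumerate(thetas):
        path = simulate_path(float(theta), horizon, rng)
        dec = apo_stop(path, prior_shape, prior_scale, params, c)
        losses[i] = dec.posterior_risk + dec.sampling_cost
        taus[i] = dec.tau
        n_trunc += dec.truncated
    if n_trunc > 0.01 * reps:
        warnings.warn(f"{n_trunc}/{reps} replicates hit the horizon before "
                      "stopping; the risk estimate is biased low", stacklevel=2)
    risk = float(losses.mean())
    se = float(losses.std(ddof=1) / math.sqrt(reps))
    return risk, float(taus.mean()), se
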