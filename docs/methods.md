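# Methods

## The loss and the Bayes machinery

The LINEX loss is `L(Δ) = b(e^{aΔ} − aΔ − 1)` with shape `a ≠ 0` and scale
`b > 0`. It is convex, zero only at `Δ = 0`, and asymmetric: for `a > 0`,
`L(+Δ) > L(−Δ)`. As `|a| → 0`, `2L/(b a²) → Δ²`, the squared-error limit.
The invariant form replaces `Δ` by the relative error `Δ* = θ̂/θ − 1`,
making risks scale-free; it requires `θ > 0` and every invariant-form result
in this package assumes a positive parameter (for the normal mean, a known
positive coefficient of variation `v = σ/μ`).

The Bayes estimator under LINEX loss is `−(1/a)·ln E[e^{−aθ} | data]`. For a
gamma posterior with shape `k` and rate `r` this is `(k/a)·ln(1 + a/r)`,
finite iff `a > −r` (the posterior MGF at `−a` must exist); its posterior
risk is `b·k·(a/r − ln(1 + a/r))`. Both formulas route through a
second-order series for `|a| < 10⁻⁶` to avoid catastrophic cancellation in
the `1/a` factor near the symmetric limit.

A quadrature oracle (`numeric_bayes_oracle`) independently minimises
`∫ L(d, θ) π(θ) dθ` by adaptive quadrature (absolute/relative tolerance
10⁻¹² for risk evaluation) plus bounded scalar minimisation (xatol 10⁻¹⁰),
bracketing the minimiser at the posterior mean ± 12 posterior sds (widened
for negative shapes, whose minimisers sit above the mean). Every closed form
in the package is tested against this oracle; for normal posteriors the
oracle itself is checked against the known minimiser `μ − aσ²/2`.

### Notation

The literature on this loss uses several symbols for the shape (x, z, a) and
scale (y, b). This package fixes `(a, b)` in `LinexParams` throughout, with
`b = 1` by default: the scale multiplies every risk but never moves a
minimiser.

## Shrinkage estimators

**Normal mean, known v.** `ā ~ N(μ, σ²/n)`, so `W = ā/μ ~ N(1, v²/n)` and
the invariant LINEX risk of `z·ā` is exact via the normal MGF:
`exp(a(z−1) + a²z²v²/(2n)) − a(z−1) − 1`. The MSE-optimal coefficient is
`n/(n+v²)`; the LINEX-optimal one is found two ways: (i) numerically, by
minimising the exact risk *scaled by 2/a²* (keeping the objective O(1) so
the minimiser remains resolvable in floating point down to `a = 10⁻⁶`), and
(ii) in closed form from the cubic Taylor truncation of the loss,
`E u²/2 + E u³/6` with `u = a(zW − 1)`, whose stationarity condition is the
quadratic

```
a·m₃·z² + 2(1−a)·m₂·z + (a−2)·m₁ = 0,    m_j = E W^j,
```

solved by the larger root (the one tending to the MSE optimum `m₁/m₂` as
`a → 0`). The truncation is accurate for roughly `0 < a ≤ 0.6`; both routes
are always returned so the user can see the gap.

**μ².** `ā²` is a scaled noncentral chi-square, so
`E e^{sā²} = (1−2sσ²/n)^{−1/2} exp(sμ²/(1−2sσ²/n))` for `s < n/(2σ²)`;
the exact invariant risk of `t·ā²` therefore exists only for
`a·t < n/(2v²)` and the module raises beyond that bound. The same cubic
truncation (with the exact normal moments of `ā²/μ²`, i.e.
`1 + 6v²/n + 3v⁴/n²` and `1 + 15v²/n + 45v⁴/n² + 15v⁶/n³`) gives the
closed-form coefficient. When `v` is unknown the MVUE `ā² − d²/n` is
provided (`d²` = sample variance with divisor n−1); it can be negative in
small samples, which is documented rather than truncated away.

**σ².** For the estimator `Σ(x−ā)²/d` the relative MSE is
`2(n−1)/d² + ((n−1)/d − 1)²`: `2/(n−1)` at the unbiased divisor and minimal
`2/(n+1)` at `d = n+1`.

**NED scale.** `ā ~ Gamma(n, θ/n)`, `E e^{azā/θ} = (1−az/n)^{−n}` for
`az < n`, so the invariant risk of `z·ā` is exact and its stationary point
is the closed form `z_min = (n/a)(1−e^{−a/(n+1)})` — an *exact* optimum, not
a truncation, verified to 10⁻¹⁰ by the analytic derivative over a grid of
(n, a). For `θ²` no exact LINEX risk exists: `E e^{sā²}` diverges for every
`s > 0` when `ā` is gamma (the tests demonstrate the quadrature blow-up), so
the cubic-truncated risk with exact gamma moments
(`E ā^{2k} = θ^{2k}·Π_{j<2k}(n+j)/n^{2k−1}`) is the honest object; its
optimum is the quadratic root inside the convexity bracket
`[(a−1)n²/(a(n+5)(n+4)), 1]` (when both roots qualify, the one with smaller
truncated risk). The API labels these results as truncated. Negative `a` is
accepted wherever the MGF exists.

## Censored exponential survival

Lifetimes with right censoring, `(t_i, δ_i)`, constant hazard λ. The
likelihood is `λ^d e^{−λT}` with `d = Σδ`, `T = Σt`; MLE `d/T`; conjugate
gamma prior with shape k and **rate** β (the kernel is `e^{−λ(T+β)}`, so β
adds to the time at risk — the Poisson module uses the scale convention
instead, and `GammaDist` exposes both plus a converter, because the two
problems are conventionally parametrised differently). Survival is
`e^{−λ̂t}` and the hazard is the rate itself.

Degenerate samples: with every lifetime censored the MLE sits on the
boundary (returned as λ̂ = 0 with a warning), while the Bayes-LINEX estimate
remains proper through the prior — one of the practical arguments for the
Bayesian route.

The MSE study draws, per replicate, exponential lifetimes and independent
exponential censoring with rate `λq/(1−q)` — the closed form that makes the
expected censored fraction equal the target `q`. All replicates are filled
from a single seeded generator in replicate-major order, so enlarging the
replication count leaves earlier replicates unchanged. Rates can be held
fixed or drawn from the prior; the latter is the setting in which Bayes
optimality guarantees the Bayes-LINEX estimator's prior-averaged LINEX risk
cannot exceed the MLE's. The default survival reporting grid is the deciles
of the generating distribution.

## Sequential Poisson estimation and the APO rule

With prior `Gamma(α, scale β)` and `R(t)` events by time `t`, the posterior
is `Gamma(α + R(t), scale β/(tβ+1))`; the Bayes estimate and its posterior
risk `U_t = (α+R(t))(x − ln(1+x))`, `x = aβ/(tβ+1)`, follow from the gamma
closed forms (the identity with the generic gamma risk is asserted to
10⁻¹² in tests). `U_t` decreases continuously between events and jumps up
at events, while the cost line `c·t` increases, so `U_t − c·t` has at most
one zero per inter-event interval: the stopping time
`τ* = inf{t : U_t ≤ c·t}` is located by a vectorised scan over intervals
followed by Brent root-finding (xtol 10⁻¹²; interior stops satisfy
`|U_τ − cτ| ≤ 10⁻⁹`). Crossings are sought in half-open intervals
`[T_i, T_{i+1})` — the posterior filtration is right-continuous, so if
`U_{T_i} ≤ c·T_i` already holds at an event, the rule stops there. Paths
that never cross before the horizon return a flagged truncated decision.

Asymptotics: `C_t = tU_t → a²θ/2`, giving the small-cost approximations
`τ* ≈ a·sqrt(θ/(2c))` and, prior-averaged, `τ̄ ≈ a·sqrt(θ̄/(2c))`. The
Bayes-risk simulator draws θ from the prior, simulates each path to a
horizon of five times that approximation (so <1% of replicates truncate in
practice; more triggers a warning), and reports `E[b·U_{τ*} + c·τ*]` with
its standard error. For `a < 0` the asymptotic-optimality theory assumes
`α > 1` and `β < −1/a`; the module warns (not errors) outside that regime,
since the stopping rule itself stays well defined wherever the MGF exists.

## Synthetic data and what the tests show

The generators produce exactly the conditions the theory assumes:
i.i.d. exponential lifetimes with independent exponential censoring, normal
samples with known coefficient of variation, homogeneous Poisson streams
with gamma intensity. They do not emulate covariates, non-constant hazards,
informative censoring, or overdispersed event streams — so passing tests
validate the estimators *under their stated model*, not robustness to
misspecification.

Default study sizes (all adjustable): censored-survival comparisons use
n = 30, 20% censoring, 10⁴ replicates; shrinkage MSE recoveries use 10⁵
draws; the scaled-risk asymptote uses 200 paths observed to t = 10⁴ and the
stopping-time approximation 200–300 replicates at c = 10⁻⁴ with prior
Gamma(4, scale 0.5) — a prior concentrated enough that
`E√θ ≈ √θ̄` holds to a few percent, which is what the approximation quality
depends on. Monte-Carlo assertions use 3-standard-error bands throughout.

## Numerical choices

- Series switch at `|a| = 10⁻⁶` for the gamma closed forms; `expm1`/`log1p`
  everywhere a `−1` or `1+` would cancel.
- Risk minimisations operate on the `2/a²`-scaled objective so that optima
  remain well conditioned as `a → 0`.
- Quadrature oracle: tolerance 10⁻¹⁰–10⁻¹²; loss×density integrands return
  0 where the density has underflowed, since the analytic product vanishes
  in the far tail even where the loss alone overflows.
- Root selection for truncated-risk quadratics: the root inside the
  convexity bracket; ties broken by the smaller truncated risk.
- Seeds: every stochastic routine takes an explicit seed (or Generator);
  benchmark tables are bit-reproducible under (config, seed).

## Known limitations

- The exact invariant-LINEX risk of `z₅·ā²` (NED) does not exist; only the
  truncated risk is offered, clearly labelled.
- Invariant-form results require a positive parameter (μ > 0, θ > 0).
- The censored-data module covers the constant-hazard exponential model
  only; no covariates, no Weibull/flexible hazards.
- The sequential module handles homogeneous processes; no second-order
  (non-deficiency) risk expansions are computed — the harness reports
  simulated Bayes risk with standard errors instead.
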