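# linexest

Estimation under the asymmetric **LINEX loss** for survival and event-count
models: Bayes estimators for censored exponential lifetime data,
minimum-risk shrinkage estimators for normal and negative-exponential scale
parameters, and the asymptotically pointwise optimal (APO) sequential
stopping rule for a Poisson intensity — together with a seeded Monte-Carlo
harness that compares everything against maximum likelihood.

## Who this is for

Biostatisticians and reliability analysts who care that over- and
under-estimation are *not* equally costly. Overestimating a patient's
survival probability, or underestimating a hazard rate, can be far more
damaging than the opposite error; squared-error procedures ignore this. The
LINEX (linear-exponential) loss

```
L(Δ) = b (e^{aΔ} − aΔ − 1),   Δ = θ̂ − θ,
```

rises exponentially on one side of zero and almost linearly on the other:
`a > 0` penalises overestimation more, `a < 0` underestimation, and
`|a| → 0` recovers squared error. For scale parameters the *invariant* form
applies the same loss to the relative error `Δ* = θ̂/θ − 1`.

## What's inside

| module | contents |
|---|---|
| `linexest.core` | `LinexParams`, `GammaDist`, plain/invariant LINEX loss, the gamma closed form `θ̂ = (k/a)·ln(1 + a/r)` for the Bayes estimator `−(1/a)·ln E[e^{−aθ}|data]`, its posterior risk `k(a/r − ln(1+a/r))`, and a quadrature oracle for arbitrary posteriors |
| `linexest.normal` | shrinkage of the sample mean (`s = n/(n+v²)`, known coefficient of variation `v = σ/μ`), of `μ²` and of `σ²`, under MSE and invariant LINEX; exact risks via normal / noncentral-χ² MGFs |
| `linexest.ned` | negative-exponential scale: exact invariant-LINEX risk, the closed optimum `z_min = (n/a)(1 − e^{−a/(n+1)})`, and the truncated-risk optimum for `θ²` |
| `linexest.survival` | censored exponential data: sufficient statistics, MLE `Σδ/Σt`, conjugate gamma posterior, Bayes-LINEX rate, survival/hazard curves, MSE study |
| `linexest.poisson` | Poisson intensity: conjugate updating, posterior risk `U_t`, the APO rule `τ* = inf{t : U_t ≤ c·t}`, Bayes-risk simulation |
| `linexest.simulate`, `linexest.bench`, `linexest.cli` | synthetic-data generators, the risk-table benchmark, a thin `linexest` command-line front end |

## Worked example

```python
import numpy as np
from linexest import GammaDist, LinexParams, CensoredSample, fit_mle, fit_bayes_linex

sample = CensoredSample(times=np.array([2., 3., 5.]), status=np.array([1, 1, 0]))
prior  = GammaDist(k=1, r=1)          # beta is a RATE here: it adds to Σt
params = LinexParams(a=1.0)           # overestimation costs more

fit_mle(sample).lambda_hat            # 0.2            (= Σδ/Σt = 2/10)
fit_bayes_linex(sample, prior, params).lambda_hat
                                      # 0.26103        (= 3·ln(12/11); below the
                                      #  posterior mean 3/11 ≈ 0.27273, as a > 0 demands)
```

The `examples/` directory has one narrative script per capability
(`fit_censored_lifetimes.py`, `shrinkage_estimators.py`, `apo_stopping.py`,
`risk_benchmark.py`); each prints its numbers with a line on what they mean.
For instance `examples/apo_stopping.py` reports, for one simulated stream
with true intensity 2:

```
c=0.1    tau*=   1.681  ...  U_tau=0.16805 (= c*tau up to 1e-9)
c=0.01   tau*=  10.580  ...  theta~=2.4848
c=0.001  tau*=  34.016  ...  theta~=2.3934
```

— smaller sampling cost delays the stop and sharpens the Bayes estimate,
and at every interior stop the posterior risk exactly meets the cost line.

A thin CLI mirrors the library:

```bash
linexest fit-exp data.csv --prior-shape 1 --prior-rate 1 --linex-a 1
linexest shrinkage --family ned --n 10 --linex-a 0.5
linexest apo-run --path events.csv --horizon 100 --cost 0.01
```

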