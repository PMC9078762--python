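"""Monte-Carlo risk table: Bayes-LINEX vs MLE on censored survival data.

Reproduces the structure of an estimator-comparison study: rates drawn from
the generating prior, 20% censoring, bias/MSE/LINEX risk per estimator.
"""

from linexest.core import GammaDist, LinexParams
from linexest.bench import BenchConfig, run_benchmark

cfg = BenchConfig(
    scenario="exp_survival",
    prior=GammaDist(k=2.0, r=4.0),   # prior mean rate 0.5
    linex=LinexParams(a=0.5),
    n=30, censor_fraction=0.2,
    reps=5000, seed=1,
    lambda_from_prior=True,          # score under the generating prior
)
table = run_benchmark(cfg)
rates = table[table["quantity"] == "rate"]
print(rates[["estimator", "bias", "mse", "linex_risk"]].to_string(index=False))
print("\nunder the generating prior the Bayes-LINEX rate has the lower "
      "prior-averaged LINEX risk (Bayes optimality); its bias toward the "
      "prior buys a large variance reduction")

surv = table[table["quantity"].str.startswith("survival")]
print("\nsurvival-probability MSE (first rows):")
print(surv[["estimator", "quantity", "mse"]].head(6).to_string(index=False))
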