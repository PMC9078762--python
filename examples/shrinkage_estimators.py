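"""Shrinkage coefficients for normal and negative-exponential parameters.

Prints MSE-optimal and LINEX-optimal scaling coefficients for the sample
mean (known coefficient of variation v) and for the NED scale, and shows
that the LINEX optimum dominates under LINEX risk.
"""

from linexest.core import LinexParams
from linexest import ned, normal

n, v = 10, 2.0
p = LinexParams(a=0.4)

s, rel = normal.optimal_shrink_mean_mse(n, v)
z_min, z_approx = normal.optimal_shrink_mean_linex(n, v, p)
print(f"normal mean, n={n}, v={v}:")
print(f"  MSE-optimal coefficient  s = {s:.5f} "
      f"(relative MSE {rel:.5f} < 1/n = {1/n})")
print(f"  LINEX-optimal (a={p.a})  z = {z_min:.5f} "
      f"(cubic-truncation closed form {z_approx:.5f})")
r_lin = normal.invariant_risk_mean(z_min, n, v, p)
r_mse = normal.invariant_risk_mean(s, n, v, p)
print(f"  invariant LINEX risk: {r_lin:.6f} (LINEX-opt) vs {r_mse:.6f} "
      "(MSE-opt) -> LINEX-opt never loses under its own risk")

n = 10
s, rel = ned.shrink_scale_mse(n)
z = ned.optimal_shrink_scale_linex(n, LinexParams(a=0.5))
print(f"\nNED scale, n={n}:")
print(f"  MSE-optimal  n/(n+1) = {s:.5f}  (relative MSE 1/(n+1) = {rel:.5f})")
print(f"  LINEX-optimal (a=0.5) = {z:.5f}  (exact stationary point)")

z5, (lo, hi) = ned.optimal_shrink_scale2_linex(n, LinexParams(a=0.2))
print(f"  theta^2 estimator coefficient z5 = {z5:.5f} "
      f"(truncated-risk optimum, bracket [{max(lo,0):.3f}, {hi:.0f}]; "
      f"MSE-optimal would be {ned.shrink_scale2_mse(n):.5f})")
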