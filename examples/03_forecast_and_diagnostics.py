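"""Residual diagnostics and multi-step forecasting on a fitted model.

Uses a seeded synthetic series at the scale of monthly incident counts
(mean ~1.6, dispersion ~1.5), checks overdispersion and residual
whiteness, and prints six-step-ahead forecasts.
"""

from blinar import (
    fit_cml,
    forecast,
    ljung_box,
    overdispersion_test,
    pearson_residuals,
    rmse_holdout,
)
from blinar.diagnostics import BELL
from blinar.simstudy import make_fixture

series, meta = make_fixture("blinar", T=132, seed=7)
print(f"synthetic monthly series, T={len(series)}, "
      f"truth alpha={meta['alpha']:.4f} theta={meta['theta']:.4f}")

idx, crit, reject = overdispersion_test(series, B=499, level=0.05, seed=1)
print(f"\ndispersion index {idx:.4f}, bootstrap critical value {crit:.4f} "
      f"-> overdispersed: {reject}")
print("(index above the critical value says a Poisson-innovation model is too rigid)")

fit = fit_cml(series)
print(f"\nCML fit: alpha_hat={fit.alpha_hat:.4f}, theta_hat={fit.theta_hat:.4f}")

resid = pearson_residuals(series, fit.params)
stat, pval = ljung_box(resid, lags=10, model_df=2)
print(f"Pearson residuals: mean {resid.mean():.3f}, variance {resid.var(ddof=1):.3f}")
print(f"Ljung-Box on residuals: Q={stat:.2f}, p={pval:.4f} "
      f"(large p = no leftover autocorrelation)")

print("\nforecasts from the last observation "
      f"(x_T = {int(series.values[-1])}):")
print("k\tmean\tvariance")
for k, (m, v) in enumerate(forecast(series, fit.params, 6), start=1):
    print(f"{k}\t{m:.3f}\t{v:.3f}")

rmse = rmse_holdout(series, BELL, h=6)
print(f"\nholdout RMSE over the last 6 observations: {rmse:.4f}")
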