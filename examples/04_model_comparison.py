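"""Compare innovation families on an overdispersed count series.

Fits Bell-, Poisson- and geometric-innovation INAR(1) models to the same
series by conditional maximum likelihood and tabulates information
criteria, fitted stationary moments, and holdout forecast RMSE.
"""

from blinar import compare_models
from blinar.diagnostics import BELL, GEOMETRIC, POISSON
from blinar.simstudy import make_fixture

series, meta = make_fixture("overdispersed_demo", T=108, seed=3)
print(f"synthetic strikes-scale series, T={len(series)}: "
      f"sample mean {series.values.mean():.3f}, "
      f"sample variance {series.values.var(ddof=1):.3f}")

rows = compare_models(series, (BELL, POISSON, GEOMETRIC), h=6)
header = f"{'model':<20}{'AIC':>9}{'BIC':>9}{'CAIC':>9}{'HQIC':>9}" \
         f"{'mean':>8}{'var':>8}{'RMSE':>8}"
print("\n" + header)
for r in rows:
    print(f"{r.model:<20}{r.aic:>9.2f}{r.bic:>9.2f}{r.caic:>9.2f}"
          f"{r.hqic:>9.2f}{r.fitted_mean:>8.3f}{r.fitted_variance:>8.3f}"
          f"{r.rmse:>8.3f}")
    est = ", ".join(f"{k}={v:.4f}" for k, v in r.estimates.items())
    print(f"    estimates: {est}")

print("\nrows are sorted by AIC; on Bell-generated data the Bell family "
      "should head the table,\nand its fitted variance should sit closest "
      "to the sample variance.")
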