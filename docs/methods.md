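# Methods

This note records the model, the numerical choices, and the design
decisions behind `blinar`, in enough detail that a maintainer can judge
what the tests do and do not establish.

## Model and assumptions

The BL-INAR(1) process is `X_t = α∘X_{t−1} + ε_t` with binomial thinning
(`α∘X | X ~ Binomial(X, α)`, 0 < α < 1) and i.i.d. Bell(θ) innovations,
θ > 0, independent of the thinning and of the past. Because the Bell law
has finite mean and variance, the chain is an ergodic stationary Markov
chain; all stationary quantities used in the package follow from the
standard INAR(1) moment identities with μ_ε = θe^θ and
σ_ε² = θ(1+θ)e^θ:

- mean μ = θe^θ/(1−α); variance σ² = θe^θ(1+α+θ)/(1−α²);
- autocorrelation ρ_k = α^k; autocovariance γ_k = α^k σ²;
- dispersion index I_x = σ²/μ = (1+α+θ)/(1+α) = 1 + θ/(1+α) > 1.

The dispersion index deserves a remark: it is the ratio of the two
closed forms above, `1 + θ/(1+α)`, and long-path simulation confirms it
(e.g. α = 0.13, θ = 0.695 gives sampled I_x ≈ 1.615). The superficially
similar reading `(1+θ)/(1+α)` is *not* σ²/μ and is not used anywhere.

The model is suitable only for overdispersed series: I_x > 1 for every
admissible (α, θ). For equidispersed data the Poisson-innovation INAR(1)
(available through the `diagnostics` family interface) is the right null.

## Bell numbers and the Bell distribution

Bell numbers are computed exactly with Python big integers via the Bell
triangle (the O(n²) form of the binomial recurrence
B_{n+1} = Σ_k C(n,k) B_k) and cached incrementally; the log values are
taken directly from the exact integers (`math.log` accepts arbitrary
precision ints), so `log_bell_number` carries only one floating rounding
at any n. This matters because B_z overflows double precision near
z ≈ 180 while observed counts can exceed that. Dobinski's series is kept
only as a cross-check oracle: it converges slowly and cancels badly in
floating point.

The pmf is always evaluated in log space
(`z·lnθ − (e^θ−1) + ln B_z − ln z!`); the cdf truncates adaptively using
the geometric tail majorant with ratio r = θ·B_{z+1}/((z+1)B_z), stopping
once the bound drops below 1e−14. The default sampler uses the
compound-Poisson representation (N ~ Poisson(e^θ−1) zero-truncated
Poisson(θ) summands); a cdf-inversion sampler provides an independent
route, and the two are checked against each other distributionally.
`theta_from_mean` inverts θe^θ = m by the principal Lambert W branch plus
one Newton polish step, achieving round-trip error ≤ 1e−10·max(1, m).

## Likelihood and estimation

The one-step transition probability is

    P(i | j) = Σ_{m=0}^{min(i,j)} C(j,m) α^m (1−α)^{j−m} P(ε = i−m),

accumulated by log-sum-exp with a log-probability floor at
log(realmin)+50 so that impossible transitions degrade to a very small
likelihood rather than −∞. The conditional log-likelihood
L(α,θ) = Σ_t log P(X_{t+1}|X_t) collapses repeated (previous, next)
pairs to unique rows with multiplicities before evaluation, which makes
a T = 1000 evaluation cost a few hundred log-sum-exp rows.

- **CLS**: the closed forms for (α̂, μ̂) with sums over t = 2..T; θ̂ then
  solves θe^θ = μ̂(1−α̂). When μ̂(1−α̂) ≤ 0 (possible on short series)
  θ̂ is undefined and the fit is flagged rather than raised. α̂ outside
  (0,1) is reported raw and flagged.
- **YW**: α̂ = lag-1 sample autocorrelation (cross-products over
  t = 1..T−1, centered squared sum over t = 1..T in the denominator),
  μ̂ = X̄.
- **CML**: BFGS on (logit α, ln θ) with numerical gradients, gradient
  tolerance 1e−6, at most 200 iterations; initial values are the YW
  estimates with α clipped into [0.001, 0.999]. Non-convergence sets a
  flag; it never raises. The observed-information covariance (inverse
  numerical Hessian on the natural scale) is available on request.

### Asymptotic covariance of CLS

The asymptotic covariance Σ of √T(α̂_CLS−α, μ̂_CLS−μ) is assembled from
the conditional-least-squares sandwich: with regressor z = (X_{t−1}, 1)
and conditional variance v(x) = α(1−α)x + σ_ε²,

    A = V⁻¹ W V⁻¹,   V = E[zz'],   W = E[v(X) zz'],

gives the covariance of (α̂, μ̂_ε); the Jacobian of
(α, μ_ε) ↦ (α, μ_ε/(1−α)) maps it to the reported (α, μ) scale. W needs
the stationary third raw moment μ₃ = E[X³], obtained by taking third
moments in X = α∘Y + ε at stationarity (binomial third moment inside,
Bell raw moments for ε, third cumulant θe^θ(1+3θ+θ²)) and solving the
resulting linear equation. Published renderings of Σ and μ₃ for this
model conflate the third raw moment with the cube of the mean and drop
fraction bars; rather than guess among readings, the implementation was
required to match the Monte Carlo sampling covariance of the CLS
estimates — it does, entrywise within a few percent at T = 2000 over
2000 replicates (the acceptance suite re-runs this check at a 15%
tolerance), which simultaneously fixes the μ₃-vs-μ³ ambiguity in favor
of the construction above.

Delta-method standard errors for θ̂ propagate Σ/T through
θ = W(μ(1−α)) with dW/dx = W/(x(1+W)); simulation puts the empirical
coverage of the nominal 95% intervals at T = 2000 inside 93–97%.

## Diagnostics

The innovation family is pluggable: a family supplies a normalized pmf,
mean/variance, a sampler, moment-based initial values, and an
unconstrained reparameterization. Bell, Poisson, and geometric
(pmf π(1−π)^k on {0,1,…}) are built in; the generalized CML maximizes
the same thinning likelihood with the family's pmf substituted.

Information criteria use the standard definitions AIC = −2L+2k,
BIC = −2L+k ln n, CAIC = −2L+k(ln n+1), HQIC = −2L+2k ln ln n with
n = T−1, the number of conditional terms in L (the likelihood is defined
over T−1 transitions; using T instead would shift every model's
criterion equally and rarely change a ranking). Sample variances use the
T−1 denominator throughout; both conventions are isolated behind single
functions.

The overdispersion screen is a parametric bootstrap: fit the
equidispersed Poisson-INAR(1) null by CML, simulate B null paths of the
observed length, take the empirical (1−level) quantile of their
dispersion indices as the critical value. An asymptotic closed-form
critical value could later replace the bootstrap behind the same
interface. Bootstrap null paths use a shorter burn-in (100) than study
simulations; the null chain mixes fast at the fitted α.

Point forecasts are the k-step conditional means
α^k X_T + μ_ε(1−α^k)/(1−α) — real-valued, not integer-coherent — with
the matching k-step conditional variances; holdout RMSE fits on the
first T−h observations and forecasts the last h anchored at observation
T−h (default h = 6).

## Monte Carlo harness and seeding

Every replicate's seed derives from
SeedSequence([master, round(α·10⁶), round(θ·10⁶), T, replicate]), so any
cell of the study can be recomputed alone and bit-reproduces. Study
paths are initialized from a Bell(θ) draw followed by a 500-step burn-in
(the chain's mixing time at α ≤ 0.75 is far shorter). Failed fits
(optimizer non-convergence or undefined θ̂) are excluded from a cell's
mean/MSE and counted; at the study design points failures are rare
(zero in most cells).

The default replicate count is 200 per cell for desk-scale runs; the
full-scale design uses 1000 (a flag/argument away). The acceptance
script runs 1000 replicates for the three cheap cells it reports and
300 for the two expensive ones; replicate counts are recorded next to
each reported value.

## What the synthetic data does and does not show

The fixture generator produces seeded BL-INAR(1) (or Poisson-INAR(1))
paths whose stationary mean and dispersion index are matched, by exact
inversion of the closed forms, to the scale of two classic monthly count
datasets (mean ≈ 1.6 with I_x ≈ 1.5; mean ≈ 4.94 with I_x ≈ 1.59). They
emulate the marginal scale and first-order dependence of such data, but
not seasonality, trend, covariate effects, regime changes, or any
departure from the INAR(1) dependence structure — so passing tests
demonstrate correct model arithmetic and estimator behavior *under the
model*, not adequacy of the model for any particular real dataset.

## Numerical edge cases

- Constant series make every estimator degenerate (zero denominator) and
  raise a data error.
- α̂ outside (0,1) is reported raw with a flag; it is clipped only when
  used as a CML starting value.
- Transition-row truncation for matrix builds is by state-space size
  chosen from mean + 12 sd; row sums over the states of interest are
  verified to 1e−10 in the tests.
- The stationary marginal (needed only for the optional
  stationary-initialization joint probability) has no closed form and is
  computed by power iteration of the truncated transition operator to a
  1e−12 fixed point.

## Known limitations

Higher-order INAR(p), alternative thinning operators, Bell–Touchard or
zero-inflated Bell innovations, Bayesian estimation, and bootstrap
standard errors are out of scope. The additional innovation families
reported in applied comparisons (Poisson–Lindley, negative binomial,
zero-inflated Poisson, double/generalized Poisson) are not built in, but
the `InnovationFamily` interface accepts user-supplied implementations.
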