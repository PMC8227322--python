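"""The Bell distribution: pmf, moments, sampling, mean inversion.

Builds the distribution for a couple of parameter values and prints its
head probabilities, closed-form moments, and a sampling check.
"""

import numpy as np

from blinar import BellParam, bell_logpmf, bell_moments, bell_number, bell_sample, theta_from_mean

print("First Bell numbers B_0..B_8:", [bell_number(n) for n in range(9)])

for theta in (0.5, 1.5):
    p = BellParam(theta)
    mean, var = bell_moments(p)
    pmf = np.exp(bell_logpmf(np.arange(6), p))
    print(f"\nBell(theta={theta}):")
    print("  P(Z=0..5) =", np.round(pmf, 4))
    print(f"  mean = {mean:.4f}, variance = {var:.4f}, "
          f"variance/mean = {var / mean:.4f}  (= 1 + theta: always overdispersed)")
    x = bell_sample(p, 100_000, seed=1)
    print(f"  sample mean over 1e5 draws = {x.mean():.4f}")

# the mean map theta -> theta e^theta inverts uniquely via Lambert W
m = 2.5
theta = theta_from_mean(m).theta
print(f"\ntheta with mean {m}: theta = {theta:.6f} "
      f"(check: theta e^theta = {theta * np.exp(theta):.6f})")
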