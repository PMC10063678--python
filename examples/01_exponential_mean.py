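"""The exponential mean: what an exponentially growing population sees.

A stochastic duration t (a replisome pause, a cell-cycle period) is
experienced by an exponentially growing culture as its exponential mean
tau = -(1/k_G) ln E[exp(-k_G t)], which is always <= the arithmetic
mean and stays finite even when a subfraction of lineages arrests
forever.
"""

import numpy as np

import lagtime as lt

T = 30 * 60.0  # mass-doubling time, s
k_G = lt.growth_rate(T)

# an exponentially distributed pause with mean 600 s
tau = lt.exponential_mean(("exponential", 600.0), k_G)
print(f"exponential pause, mean 600 s, T = 30 min -> seen as {tau:.1f} s")

# the same from a Monte-Carlo sample of single-cell lifetimes
rng = np.random.default_rng(0)
sample = rng.exponential(600.0, size=1_000_000)
print(f"Monte-Carlo sample of 10^6 lifetimes          -> {lt.exponential_mean(sample, k_G):.1f} s")

# 10% of lineages arrest forever at the pause site: the pause looks
# longer by -T log2(0.9), but stays finite
tau_arrest = lt.exponential_mean(("mixture_arrest", 0.0, 0.1), k_G)
print(f"10% arrest alone (no finite pause)            -> {tau_arrest / 60:.2f} min")

# removing that arrest contribution from an observed pause
est = lt.arrest_corrected_pause(9.7 * 60, eps=0.1, T=54.6 * 60, se=0.9 * 60)
print(
    f"observed 9.7 min pause, 10% arrest, T=54.6 min -> "
    f"corrected {est.corrected / 60:.1f} +- {est.corrected_se / 60:.1f} min"
)
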