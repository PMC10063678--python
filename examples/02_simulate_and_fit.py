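"""Stochastic cell-cycle simulation -> marker frequency -> fork velocity.

Grows a population from a single progenitor with exponential B periods
and exponential per-bin replication steps, censuses the marker
frequency at 10^5 cells, samples sequencing reads, and runs the full
analysis: the fitted log-slope should satisfy alpha = k_G / v.
"""

import lagtime as lt

config = lt.SimConfig(
    n_bins={"left": 150, "right": 150},
    bin_length=10_000.0,  # 1.5 Mb arms
    step_time_mean=4.0,  # 4 s per 10 kb bin -> v = 2.5 kb/s
    step_dist="exponential",
    b_dist="exponential",
    b_mean=600.0,
    pop_cap=100_000,
    seed=1,
)
result = lt.simulate_population(config)
print(f"population doubling time: {result.doubling_time / 60:.2f} min")
print(f"active fork pairs per cell at census: {result.fork_pairs_per_unit:.2f}")

coverage = result.sample(2_000_000, seed=2)
profile = lt.build_profile(coverage, result.layout(), T=result.doubling_time)
model = lt.fit_piecewise(profile, lt.PiecewiseSpec.constant(profile.arm_spans))
vp = lt.velocity_profile(model, profile.k_G)
vbar, sigma = lt.mean_velocity(vp)
print(f"fitted fork velocity: {vbar:.3f} +- {sigma:.3f} kb/s (true 2.5)")

null = lt.fit_piecewise(
    profile, lt.PiecewiseSpec.constant(profile.arm_spans, slope_sharing="shared")
)
lrt = lt.likelihood_ratio_test(null, model)
print(f"equal-arm-velocity test: {lrt}")
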