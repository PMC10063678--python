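"""Measuring a replisome pause from a step in the marker frequency.

A pause at a locus delays every downstream locus, printing a step of
height k_G * dtau in ln N. For a stochastic pause the measured dtau is
the exponential mean of its lifetime distribution — shorter than the
single-cell average.
"""

import math

import lagtime as lt

config = lt.SimConfig(
    n_bins={"left": 120, "right": 120},
    bin_length=10_000.0,
    step_time_mean=6.0,
    step_dist="exponential",
    b_dist="exponential",
    b_mean=600.0,
    pause_sites=[lt.PauseSite("right", 60, "exponential", 600.0)],
    pop_cap=50_000,
    seed=3,
)
result = lt.simulate_population(config)
k = result.k_hat
print(f"doubling time: {result.doubling_time / 60:.1f} min")

coverage = result.sample(400_000, seed=4)
profile = lt.build_profile(coverage, result.layout(), T=result.doubling_time)
spec = lt.PiecewiseSpec.constant(
    profile.arm_spans,
    pauses=[lt.PauseLocus("sim", "right", 600_000.0, group="conflict")],
)
model = lt.fit_piecewise(profile, spec)
est = model.pause_estimates(k)
print(
    f"measured pause: {est.dtau.iloc[0]:.0f} +- {est.dtau_se.iloc[0]:.0f} s"
)
print(f"single-cell mean lifetime: 600 s")
print(f"exponential-mean prediction: {math.log1p(k * 600) / k:.0f} s")
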