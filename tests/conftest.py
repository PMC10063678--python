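import math

import numpy as np
import pytest

import lagtime as lt


@pytest.fixture
def two_arm_profile():
    """Factory: analytic profile -> Poisson reads -> MarkerFrequencyProfile.

    Returns (profile, expected, layout) for a given velocity spec.
    """

    def make(
        v_spec,
        T_s: float = 1800.0,
        n_bins: int = 200,
        bin_length: float = 10_000.0,
        reads: int = 6_000_000,
        seed: int = 0,
        pauses=(),
    ):
        k_G = math.log(2.0) / T_s
        expected = lt.analytic_marker_frequency(
            v_spec, {"left": n_bins, "right": n_bins}, bin_length, k_G, pauses=pauses
        )
        cov = lt.sample_reads(expected, reads, seed=seed)
        layout = expected.layout()
        profile = lt.build_profile(cov, layout, T=T_s)
        return profile, expected, layout

    return make


@pytest.fixture
def simple_layout():
    return lt.GenomeLayout(
        chromosomes=[lt.Chromosome("chr1", 4_000_000)],
        origins={"chr1": 1_000_000},
        terminus={"chr1": (3_000_000, 100_000)},
    )
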