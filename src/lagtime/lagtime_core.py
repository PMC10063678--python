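"""Lag-time calculus.

The abundance of a locus in a steady-state exponentially growing
population lags the origin's abundance by the time the fork takes to
reach it. The central identities are

    tau(l)      = (1/k_G) ln(N_0 / N(l))            lag time of a locus
    dtau_ij     = (1/k_G) ln(N_i / N_j)             lag-time difference
    tau_exp     = -(1/k_G) ln E[exp(-k_G t)]        exponential mean

with k_G = ln 2 / T the population growth rate. The exponential mean is
the effective deterministic duration that an exponentially growing
population assigns to a stochastic duration t; an arrested subfraction
eps (infinite lifetime) extends it by -T log2(1 - eps) while leaving it
finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import BinnedCoverage, GenomeLayout

__all__ = [
    "signed_distance",
    "MarkerFrequencyProfile",
    "build_profile",
    "lag_time",
    "lag_time_difference",
    "exponential_mean",
    "PauseEstimate",
    "arrest_corrected_pause",
    "growth_rate",
]

LN2 = math.log(2.0)


def growth_rate(T: float) -> float:
    """Growth rate k_G = ln 2 / T for mass-doubling time T (same units)."""
    if T <= 0:
        raise ValueError("doubling time must be > 0")
    return LN2 / T


def _circular_delta(a: float, b: float, length: float) -> float:
    """Distance travelled going forward (increasing coordinate) from b to a."""
    return (a - b) % length


def _base_arm(
    layout: GenomeLayout, chromosome: str, position: float
) -> tuple[str, float]:
    """Physical arm (left/right) and signed origin distance."""
    chrom = layout.chromosome(chromosome)
    L = chrom.length
    if not 0 <= position < L:
        raise ValueError(f"position {position} outside [0, {L}) on {chromosome}")
    ori = layout.origins[chromosome]
    if chromosome in layout.terminus:
        ter = layout.terminus[chromosome][0]
        right_span = _circular_delta(ter, ori, L)
    else:
        right_span = L / 2.0
    d_right = _circular_delta(position, ori, L)
    if d_right <= right_span:
        return "right", d_right
    return "left", -(L - d_right)


def _region_label(layout: GenomeLayout, chromosome: str, position: float,
                  default: str) -> str:
    for c, start, end, label in layout.direction_map:
        if c == chromosome and start <= position < end:
            return label
    return default


def signed_distance(
    layout: GenomeLayout, chromosome: str, position: float
) -> tuple[str, float]:
    """Arm label and signed origin distance of a position.

    Returns ``(arm, l)`` where ``l`` is the along-chromosome distance
    from the controlling origin measured in the direction the fork
    travels to reach the locus: positive on the right arm (increasing
    coordinates from the origin), negative on the left. The two arms
    meet at the terminus when one is declared, else at the antipode.
    Positions inside a ``direction_map`` interval get that interval's
    label (e.g. ``retrograde``) instead of left/right; the distance is
    unchanged.
    """
    arm, ell = _base_arm(layout, chromosome, position)
    return _region_label(layout, chromosome, position, arm), ell


@dataclass
class MarkerFrequencyProfile:
    """ln relative marker frequency vs signed origin distance.

    ``data`` has one row per retained bin with columns: chrom, arm
    (physical arm, left/right — the fitting coordinate), region (the
    direction-map label, e.g. ``retrograde``, defaulting to the arm),
    ell (signed bp), abs_ell (bp along the fork path), y
    (= ln(count / total_reads)), w (= count, the inverse delta-method
    variance of y up to the total-read constant).
    """

    data: pd.DataFrame
    T: float  # mass-doubling time, seconds
    total_reads: float
    arm_spans: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def k_G(self) -> float:
        return LN2 / self.T

    def arm(self, chrom: str, arm: str) -> pd.DataFrame:
        return self.data[(self.data.chrom == chrom) & (self.data.arm == arm)]

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data.chrom))


def build_profile(
    cov: BinnedCoverage,
    layout: GenomeLayout,
    T: float,
    min_count: float = 10.0,
    min_bins: int = 20,
    divisor: BinnedCoverage | None = None,
) -> MarkerFrequencyProfile:
    """Convert masked binned coverage to a marker-frequency profile.

    Retained bins are unmasked, outside any terminus exclusion window and
    have count >= ``min_count`` (the Poisson delta-method variance of a
    log-count, 1/count, is only trustworthy for non-tiny counts). Each
    carries its arm, signed origin distance (evaluated at the bin
    midpoint), ln relative frequency and weight.

    ``divisor`` is an optional per-bin normalization track with the
    same binning (e.g. a stationary-phase control): each bin's count is
    divided by the matching divisor count before the log; bins where
    the divisor is masked or zero are dropped. Weights remain the raw
    counts (the divisor is treated as noise-free).
    """
    total = cov.total_reads
    if total <= 0:
        raise ValueError("coverage has no reads")
    rows = []
    arm_spans: dict[tuple[str, str], float] = {}
    for name, cb in cov.chroms.items():
        chrom = layout.chromosome(name)
        mids = cov.midpoints(name)
        ter = layout.terminus.get(name)
        keep = ~cb.mask & (cb.counts >= min_count)
        div = None
        if divisor is not None:
            div = divisor.chroms[name]
            if len(div.counts) != len(cb.counts):
                raise ValueError(f"divisor binning mismatch on {name!r}")
            keep &= ~div.mask & (div.counts > 0)
        n_kept = 0
        for i in np.flatnonzero(keep):
            pos = mids[i]
            if ter is not None:
                ter_pos, half = ter
                d = min(
                    _circular_delta(pos, ter_pos, chrom.length),
                    _circular_delta(ter_pos, pos, chrom.length),
                )
                if d <= half:
                    continue
            arm, ell = _base_arm(layout, name, pos)
            region = _region_label(layout, name, pos, arm)
            key = (name, arm)
            arm_spans[key] = max(arm_spans.get(key, 0.0), abs(ell))
            value = cb.counts[i] if div is None else cb.counts[i] / div.counts[i]
            rows.append(
                (name, arm, region, ell, abs(ell),
                 math.log(value / total), cb.counts[i])
            )
            n_kept += 1
        if n_kept < min_bins:
            raise ValueError(
                f"chromosome {name!r}: only {n_kept} retained bins (< {min_bins}); unfittable"
            )
    data = pd.DataFrame(
        rows, columns=["chrom", "arm", "region", "ell", "abs_ell", "y", "w"]
    )
    return MarkerFrequencyProfile(data=data, T=T, total_reads=total, arm_spans=arm_spans)


def lag_time(n_locus: float, n_origin: float, k_G: float) -> float:
    """Lag time tau = (1/k_G) ln(N_origin / N_locus).

    Negative values (locus apparently more abundant than the origin) are
    returned with a warning, not clamped — they diagnose normalization
    or layout errors.
    """
    if n_locus <= 0 or n_origin <= 0:
        raise ValueError("counts must be > 0")
    if k_G <= 0:
        raise ValueError("k_G must be > 0")
    tau = math.log(n_origin / n_locus) / k_G
    if tau < 0:
        warnings.warn(
            f"negative lag time ({tau:.3g}): locus more abundant than origin"
        )
    return tau


def lag_time_difference(n_i: float, n_j: float, k_G: float) -> float:
    """Lag-time difference dtau = (1/k_G) ln(N_i / N_j).

    Positive when locus j is replicated after locus i (less abundant).
    Antisymmetric under argument swap.
    """
    if n_i <= 0 or n_j <= 0:
        raise ValueError("counts must be > 0")
    return math.log(n_i / n_j) / k_G


def exponential_mean(lifetime_spec, k_G: float) -> float:
    """Exponential mean tau = -(1/k_G) ln E[exp(-k_G t)] of a duration.

    ``lifetime_spec`` is either an array of sampled durations (infinities
    are legal and encode arrested lineages, contributing 0 to the
    expectation) or a named distribution:

    - ``('delta', t0)``                      -> t0
    - ``('exponential', mu)``                -> ln(1 + k_G mu) / k_G
    - ``('uniform', a, b)``                  -> closed form on [a, b]
    - ``('mixture_arrest', tau0, eps)``      -> tau0 - T log2(1 - eps)

    The exponential mean is <= the arithmetic mean (Jensen), with
    equality only for a deterministic duration; as k_G -> 0 it tends to
    the arithmetic mean.
    """
    if k_G <= 0:
        raise ValueError("k_G must be > 0")
    if isinstance(lifetime_spec, tuple):
        kind = lifetime_spec[0]
        if kind == "delta":
            return float(lifetime_spec[1])
        if kind == "exponential":
            mu = float(lifetime_spec[1])
            return math.log1p(k_G * mu) / k_G
        if kind == "uniform":
            a, b = float(lifetime_spec[1]), float(lifetime_spec[2])
            if b <= a:
                raise ValueError("uniform spec needs b > a")
            mean_exp = (math.exp(-k_G * a) - math.exp(-k_G * b)) / (k_G * (b - a))
            return -math.log(mean_exp) / k_G
        if kind == "mixture_arrest":
            tau0, eps = float(lifetime_spec[1]), float(lifetime_spec[2])
            if not 0 <= eps < 1:
                raise ValueError("arrest fraction must be in [0, 1)")
            return tau0 - math.log1p(-eps) / k_G
        raise ValueError(f"unknown lifetime distribution {kind!r}")
    sample = np.asarray(lifetime_spec, dtype=float)
    if sample.size == 0:
        raise ValueError("empty lifetime sample")
    with np.errstate(over="ignore"):
        weights = np.where(np.isinf(sample), 0.0, np.exp(-k_G * sample))
    mean_w = weights.mean()
    if mean_w == 0.0:
        warnings.warn("all lifetimes arrested; exponential mean is infinite")
        return math.inf
    return -math.log(mean_w) / k_G


@dataclass
class LagTimeProfile:
    """Per-knot lag times in seconds with standard errors.

    ``data`` columns: chrom, arm, position (bp from origin), tau_s,
    se_s. The lag time at the origin is 0 by construction.
    """

    data: pd.DataFrame
    k_G: float

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class PauseEstimate:
    """An observed pause and its arrest-corrected value (seconds)."""

    locus: str
    observed: float
    se: float
    arrest_fraction: float = 0.0
    corrected: float | None = None
    corrected_se: float | None = None


def arrest_corrected_pause(
    observed: float,
    eps: float,
    T: float,
    se: float = 0.0,
    eps_se: float | None = None,
    locus: str = "",
) -> PauseEstimate:
    """Remove the arrested-subfraction contribution from an observed pause.

    A fraction eps of lineages arresting at the pause site inflates the
    exponential-mean pause by -T log2(1 - eps); the corrected value
    ``observed + T log2(1 - eps)`` estimates the pause experienced by
    non-arrested cells. If ``eps_se`` is given the correction's
    uncertainty is propagated by the delta method.
    """
    if not 0 <= eps < 1:
        raise ValueError("arrest fraction must be in [0, 1)")
    if T <= 0:
        raise ValueError("doubling time must be > 0")
    corrected = observed + T * math.log2(1.0 - eps)
    var = se ** 2
    if eps_se is not None:
        var += (T / ((1.0 - eps) * LN2)) ** 2 * eps_se ** 2
    if corrected < 0:
        warnings.warn(
            f"arrest correction exceeds observed pause ({corrected:.3g} s): "
            "possible model misfit"
        )
    return PauseEstimate(
        locus=locus,
        observed=observed,
        se=se,
        arrest_fraction=eps,
        corrected=corrected,
        corrected_se=math.sqrt(var),
    )
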