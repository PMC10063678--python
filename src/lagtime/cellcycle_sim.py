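"""Synthetic marker-frequency data: analytic generator and Gillespie engine.

Two independent routes to synthetic data for an exponentially growing
population replicating a two-armed circular chromosome:

* :func:`analytic_marker_frequency` evaluates the steady-state
  expectation N(l) = N0 exp(-k_G tau(l)) with
  tau(l) = integral_0^l dl'/v(l') plus exponential-mean pause offsets,
  and :func:`sample_reads` adds multinomial (Poisson) read noise.

* :func:`simulate_population` runs an event-driven stochastic
  population simulation from a single progenitor: birth -> stochastic
  B period -> bidirectional per-bin fork stepping with stochastic step
  lifetimes -> optional pause sites with stochastic lifetimes and a
  permanent-arrest probability -> D period -> division. A multifork
  mode re-initiates origins at a fixed inter-initiation interval
  irrespective of fork completion. The census over all cells at the
  population cap yields the simulated marker frequency, and the
  realized growth rate is estimated from the log population trajectory.

The simulator steps one event per genomic bin rather than per
nucleotide: the exponential-mean correction from sub-bin stochasticity
is of order k_G * var/mean of a step, negligible for sub-second bins,
so per-bin granularity preserves the population statistics while
keeping the simulation desk-scale.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import BinnedCoverage, ChromBins, GenomeLayout, Chromosome
from .lagtime_core import exponential_mean

__all__ = [
    "PauseSite",
    "SimConfig",
    "SimResult",
    "ExpectedProfile",
    "two_arm_layout",
    "analytic_marker_frequency",
    "sample_reads",
    "simulate_population",
    "estimate_growth_rate",
]

ARMS = ("left", "right")


def two_arm_layout(
    n_left: int, n_right: int, bin_length: float, name: str = "sim"
) -> GenomeLayout:
    """Circular single-chromosome layout for a simulated two-armed genome.

    The origin sits at coordinate ``n_left * bin_length``; the two arms
    meet at coordinate 0 (the terminus). Right-arm bin i occupies
    ``[ori + i*b, ori + (i+1)*b)``; left-arm bin i occupies
    ``[ori - (i+1)*b, ori - i*b)``.
    """
    length = int(round((n_left + n_right) * bin_length))
    return GenomeLayout(
        chromosomes=[Chromosome(name, length, circular=True)],
        origins={name: int(round(n_left * bin_length))},
        terminus={name: (0, 0)},
    )


def _arms_to_coverage(
    left: np.ndarray, right: np.ndarray, bin_length: float, name: str = "sim"
) -> BinnedCoverage:
    """Lay per-arm bin values onto the circular coordinate system."""
    n_left, n_right = len(left), len(right)
    b = int(round(bin_length))
    counts = np.concatenate([left[::-1], right]).astype(float)
    starts = np.arange(n_left + n_right, dtype=np.int64) * b
    widths = np.full(n_left + n_right, b, dtype=np.int64)
    mask = counts == 0
    return BinnedCoverage(b, {name: ChromBins(starts, widths, counts, mask)})


# ---------------------------------------------------------------------------
# analytic generator
# ---------------------------------------------------------------------------


@dataclass
class ExpectedProfile:
    """Noise-free expected marker frequency on a two-armed genome."""

    bin_length: float
    midpoints: dict[str, np.ndarray]  # arm -> bp from origin (bin midpoints)
    tau: dict[str, np.ndarray]  # arm -> lag time (s)
    expected: dict[str, np.ndarray]  # arm -> expected relative copy number
    k_G: float

    def layout(self, name: str = "sim") -> GenomeLayout:
        return two_arm_layout(
            len(self.expected["left"]), len(self.expected["right"]),
            self.bin_length, name,
        )

    def coverage(self, name: str = "sim") -> BinnedCoverage:
        """Expected values laid onto the circular coordinates (no noise)."""
        return _arms_to_coverage(
            self.expected["left"], self.expected["right"], self.bin_length, name
        )


def _piecewise_velocity(arm_spec, n_bins: int, bin_length: float) -> np.ndarray:
    """Per-bin velocity (bp/s) from a scalar, array, or (edges, values) pair."""
    mids = (np.arange(n_bins) + 0.5) * bin_length
    if np.isscalar(arm_spec):
        v = np.full(n_bins, float(arm_spec))
    elif isinstance(arm_spec, tuple) and len(arm_spec) == 2:
        edges, values = (np.asarray(a, dtype=float) for a in arm_spec)
        idx = np.clip(np.searchsorted(edges, mids, side="right") - 1, 0, len(values) - 1)
        v = values[idx]
    elif callable(arm_spec):
        v = np.asarray([float(arm_spec(m)) for m in mids])
    else:
        v = np.asarray(arm_spec, dtype=float)
        if len(v) != n_bins:
            raise ValueError("per-bin velocity array has wrong length")
    if np.any(v <= 0):
        raise ValueError("fork velocity must be > 0 everywhere")
    return v


def analytic_marker_frequency(
    v_spec: dict,
    n_bins: dict,
    bin_length: float,
    k_G: float,
    pauses=(),
    N0: float = 1.0,
) -> ExpectedProfile:
    """Expected marker frequency for a locus-dependent fork velocity.

    Parameters
    ----------
    v_spec
        Map arm -> velocity specification in bp/s: a scalar, a per-bin
        array, an ``(edges_bp, values)`` piecewise-constant pair, or a
        callable of distance.
    n_bins
        Map arm -> number of bins.
    bin_length
        Bin width in bp.
    pauses
        Iterable of ``(arm, ell_bp, dtau)`` where ``dtau`` is the pause's
        exponential-mean duration in seconds, or a lifetime spec tuple
        accepted by :func:`lagtime_core.exponential_mean` (e.g.
        ``('exponential', mu)`` or ``('mixture_arrest', tau0, eps)``).
        Loci at distance > ell_bp inherit the extra lag.

    tau(l) accumulates bin_length / v per bin plus pause offsets;
    N(l) = N0 * exp(-k_G * tau(l)).
    """
    mids, taus, expected = {}, {}, {}
    for arm in ARMS:
        n = n_bins[arm]
        v = _piecewise_velocity(v_spec[arm], n, bin_length)
        step_tau = bin_length / v
        # tau at bin midpoint: full bins before it plus half its own bin
        tau = np.cumsum(step_tau) - 0.5 * step_tau
        m = (np.arange(n) + 0.5) * bin_length
        for entry in pauses:
            p_arm, ell_p, dur = entry
            if p_arm != arm:
                continue
            dtau = exponential_mean(dur, k_G) if isinstance(dur, tuple) else float(dur)
            tau = tau + dtau * (m > ell_p)
        mids[arm] = m
        taus[arm] = tau
        expected[arm] = N0 * np.exp(-k_G * tau)
    return ExpectedProfile(
        bin_length=bin_length, midpoints=mids, tau=taus, expected=expected, k_G=k_G
    )


def sample_reads(profile, total_reads: int, seed=None) -> BinnedCoverage:
    """Multinomial read sampling over bins, proportional to copy number.

    ``profile`` is an :class:`ExpectedProfile` or :class:`SimResult`.
    Equivalent to independent Poisson counts conditioned on the total;
    reproducible under ``seed`` (an int or a Generator).
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(profile, SimResult):
        left, right = profile.counts["left"], profile.counts["right"]
        bin_length = profile.config.bin_length
    else:
        left, right = profile.expected["left"], profile.expected["right"]
        bin_length = profile.bin_length
    p = np.concatenate([left, right]).astype(float)
    p /= p.sum()
    draw = rng.multinomial(int(total_reads), p)
    nl = len(left)
    return _arms_to_coverage(draw[:nl], draw[nl:], bin_length)


# ---------------------------------------------------------------------------
# stochastic population simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PauseSite:
    """A pause site at the boundary into ``bin_index`` on one arm.

    The fork dwells for a lifetime drawn from ``dist`` with the given
    mean before replicating that bin; with probability ``eps`` the
    lineage's fork arrests permanently instead.
    """

    arm: str
    bin_index: int
    dist: str = "exponential"  # delta | exponential | uniform
    mean: float = 0.0
    eps: float = 0.0


@dataclass
class SimConfig:
    """Stochastic cell-cycle population simulation parameters.

    ``step_time_mean`` sets the mean seconds a fork spends per bin
    (scalar or per-arm array), defining the locus-dependent velocity
    v = bin_length / step_time_mean. Distributions for step and
    B-period lifetimes are ``delta`` (deterministic), ``exponential``,
    or ``uniform`` (on [0, 2*mean]). ``mode='cell'`` couples initiation
    to division through the B period; ``mode='multifork'`` re-initiates
    each origin copy after a stochastic interval of mean
    ``interinit_interval`` seconds irrespective of fork completion
    (overlapping rounds). The inter-initiation interval is stochastic
    (``interinit_dist``, default exponential) because a strictly
    periodic interval started from a single progenitor never relaxes to
    the asynchronous steady state the analysis assumes — the population
    stays in synchronized bursts and the marker frequency is a
    staircase; ``delta`` remains available for studying that regime.
    """

    n_bins: dict = field(default_factory=lambda: {"left": 200, "right": 200})
    bin_length: float = 10_000.0
    step_time_mean: dict | float = 4.0
    step_dist: str = "exponential"
    pause_sites: list[PauseSite] = field(default_factory=list)
    b_dist: str = "exponential"
    b_mean: float = 300.0
    d_period: float = 0.0
    mode: str = "cell"  # cell | multifork
    interinit_interval: float = 0.0
    interinit_dist: str = "exponential"
    pop_cap: int = 100_000
    seed: int | None = None

    def step_means(self, arm: str) -> np.ndarray:
        n = self.n_bins[arm]
        m = self.step_time_mean
        if isinstance(m, dict):
            m = m[arm]
        if np.isscalar(m):
            return np.full(n, float(m))
        m = np.asarray(m, dtype=float)
        if len(m) != n:
            raise ValueError(f"step_time_mean for {arm} has wrong length")
        return m

    def velocity(self, arm: str) -> np.ndarray:
        """Configured per-bin fork velocity in bp/s."""
        return self.bin_length / self.step_means(arm)

    def __post_init__(self) -> None:
        for arm in ARMS:
            if self.n_bins[arm] < 10:
                raise ValueError("need >= 10 bins per arm")
            if np.any(self.step_means(arm) <= 0):
                raise ValueError("step times must be > 0")
        for p in self.pause_sites:
            if not 0 <= p.eps <= 1:
                raise ValueError("arrest probability must be in [0, 1]")
            if not 0 <= p.bin_index < self.n_bins[p.arm]:
                raise ValueError("pause bin index outside arm")
        if self.b_mean < 0 or self.d_period < 0:
            raise ValueError("durations must be >= 0")
        if self.mode not in ("cell", "multifork"):
            raise ValueError("mode must be 'cell' or 'multifork'")
        if self.mode == "multifork" and self.interinit_interval <= 0:
            raise ValueError("multifork mode needs interinit_interval > 0")
        if self.pop_cap < 1000:
            raise ValueError("population cap must be >= 10^3")


@dataclass
class SimResult:
    """Census of a simulated population.

    ``counts`` holds the per-bin chromosome copy number summed over all
    cells at the census time; ``k_hat`` is the realized growth rate
    from the terminal slope of the log population trajectory.
    """

    config: SimConfig
    counts: dict[str, np.ndarray]
    census_time: float
    population: int
    k_hat: float
    trajectory_t: np.ndarray
    trajectory_n: np.ndarray
    fork_pairs: int = 0  # replication rounds in progress at census

    @property
    def fork_pairs_per_unit(self) -> float:
        """Active fork pairs per cell (cell mode) or per origin (multifork)."""
        return self.fork_pairs / self.population

    @property
    def doubling_time(self) -> float:
        return math.log(2.0) / self.k_hat

    def layout(self, name: str = "sim") -> GenomeLayout:
        return two_arm_layout(
            self.config.n_bins["left"], self.config.n_bins["right"],
            self.config.bin_length, name,
        )

    def coverage(self, name: str = "sim") -> BinnedCoverage:
        """Census copy counts laid onto circular coordinates."""
        return _arms_to_coverage(
            self.counts["left"], self.counts["right"], self.config.bin_length, name
        )

    def sample(self, total_reads: int, seed=None) -> BinnedCoverage:
        return sample_reads(self, total_reads, seed)


def _draw(rng, dist: str, means):
    means = np.asarray(means, dtype=float)
    if dist == "delta":
        return means.copy()
    if dist == "exponential":
        return rng.exponential(means)
    if dist == "uniform":
        return rng.uniform(0.0, 2.0 * means)
    raise ValueError(f"unknown lifetime distribution {dist!r}")


class _ArmSampler:
    """Draws fork arrival-time offsets for one arm, pause sites included."""

    def __init__(self, config: SimConfig, arm: str):
        self.dist = config.step_dist
        self.means = config.step_means(arm)
        self.base_cumsum = np.cumsum(self.means)
        self.pauses = sorted(
            (p for p in config.pause_sites if p.arm == arm),
            key=lambda p: p.bin_index,
        )

    def draw(self, rng) -> tuple[np.ndarray, bool]:
        """Arrival offsets from initiation (per bin); arrested flag."""
        if self.dist == "delta":
            arr = self.base_cumsum.copy()
        else:
            arr = np.cumsum(_draw(rng, self.dist, self.means))
        arrested = False
        for p in self.pauses:
            if p.eps > 0 and rng.random() < p.eps:
                arr[p.bin_index:] = np.inf
                arrested = True
                break
            if p.mean > 0:
                arr[p.bin_index:] += _draw(rng, p.dist, np.array([p.mean]))[0]
        return arr, arrested


def simulate_population(config: SimConfig) -> SimResult:
    """Run the stochastic population simulation to the population cap.

    In ``cell`` mode each cell runs birth -> B period -> bidirectional
    fork launch -> per-bin stepping (pauses and permanent arrest
    possible) -> termination -> D period -> division into two newborns;
    arrested lineages never divide but remain in the census. In
    ``multifork`` mode origin copies re-initiate every
    ``interinit_interval`` seconds and the census counts chromosome
    copies per bin over all replication rounds.
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "multifork":
        return _simulate_multifork(config, rng)
    samplers = {arm: _ArmSampler(config, arm) for arm in ARMS}
    heap: list[tuple[float, int]] = []
    alive: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    next_id = 0
    traj_t, traj_n = [], []

    def spawn(birth: float) -> None:
        nonlocal next_id
        b = _draw(rng, config.b_dist, np.array([config.b_mean]))[0]
        t0 = birth + b
        arr_l, arrested_l = samplers["left"].draw(rng)
        arr_r, arrested_r = samplers["right"].draw(rng)
        arr_l = (t0 + arr_l).astype(np.float32)
        arr_r = (t0 + arr_r).astype(np.float32)
        term = max(arr_l[-1], arr_r[-1])
        alive[next_id] = (arr_l, arr_r, t0, float(term))
        if not (arrested_l or arrested_r):
            heapq.heappush(heap, (float(term) + config.d_period, next_id))
        next_id += 1

    spawn(0.0)
    t = 0.0
    while len(alive) < config.pop_cap:
        if not heap:
            raise RuntimeError("entire population arrested; no divisions possible")
        t, cid = heapq.heappop(heap)
        if cid not in alive:
            continue
        del alive[cid]
        spawn(t)
        spawn(t)
        traj_t.append(t)
        traj_n.append(len(alive))

    counts = {arm: np.zeros(config.n_bins[arm]) for arm in ARMS}
    ids = list(alive)
    t32 = np.float32(t)
    for start in range(0, len(ids), 10_000):
        chunk = ids[start : start + 10_000]
        for arm, j in (("left", 0), ("right", 1)):
            block = np.stack([alive[i][j] for i in chunk])
            counts[arm] += len(chunk) + (block <= t32).sum(axis=0)
    pairs = sum(1 for arr in alive.values() if arr[2] <= t < arr[3])

    traj_t_arr = np.asarray(traj_t)
    traj_n_arr = np.asarray(traj_n, dtype=float)
    k_hat = estimate_growth_rate(traj_t_arr, traj_n_arr)
    _check_stability(traj_t_arr, traj_n_arr)
    return SimResult(
        config=config,
        counts=counts,
        census_time=t,
        population=len(alive),
        k_hat=k_hat,
        trajectory_t=traj_t_arr,
        trajectory_n=traj_n_arr,
        fork_pairs=pairs,
    )


def _simulate_multifork(config: SimConfig, rng) -> SimResult:
    samplers = {arm: _ArmSampler(config, arm) for arm in ARMS}
    b = _draw(rng, config.b_dist, np.array([config.b_mean]))[0]
    heap: list[float] = [float(b)]
    rounds: list[tuple[np.ndarray, np.ndarray]] = []
    origins = 1
    traj_t, traj_n = [], []
    t = 0.0
    while origins < config.pop_cap:
        t = heapq.heappop(heap)
        arr_l, _ = samplers["left"].draw(rng)
        arr_r, _ = samplers["right"].draw(rng)
        rounds.append(((t + arr_l).astype(np.float32), (t + arr_r).astype(np.float32)))
        origins += 1
        gaps = _draw(rng, config.interinit_dist,
                     np.full(2, config.interinit_interval))
        heapq.heappush(heap, t + gaps[0])
        heapq.heappush(heap, t + gaps[1])
        traj_t.append(t)
        traj_n.append(origins)
    counts = {arm: np.ones(config.n_bins[arm]) for arm in ARMS}
    t32 = np.float32(t)
    for arm, j in (("left", 0), ("right", 1)):
        block = np.stack([r[j] for r in rounds])
        counts[arm] += (block <= t32).sum(axis=0)
    pairs = sum(1 for arr_l, arr_r in rounds if max(arr_l[-1], arr_r[-1]) > t32)
    traj_t_arr = np.asarray(traj_t)
    traj_n_arr = np.asarray(traj_n, dtype=float)
    k_hat = estimate_growth_rate(traj_t_arr, traj_n_arr)
    _check_stability(traj_t_arr, traj_n_arr)
    return SimResult(
        config=config,
        counts=counts,
        census_time=t,
        population=origins,
        k_hat=k_hat,
        trajectory_t=traj_t_arr,
        trajectory_n=traj_n_arr,
        fork_pairs=pairs,
    )


def estimate_growth_rate(times, sizes) -> float:
    """Terminal-slope growth rate of a population trajectory.

    Least-squares slope of ln(size) versus time over the final half of
    the trajectory's time span; requires at least 3 doublings overall.
    """
    times = np.asarray(times, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(times) < 4 or sizes[-1] / sizes[0] < 8.0:
        raise ValueError("trajectory must span at least 3 doublings")
    # events sharing the final timestamp belong to a division burst cut
    # off by the population cap (synchronized populations); drop them
    complete = times < times[-1]
    if complete.sum() >= 4:
        times, sizes = times[complete], sizes[complete]
    mid = 0.5 * (times[0] + times[-1])
    sel = times >= mid
    return float(np.polyfit(times[sel], np.log(sizes[sel]), 1)[0])


def _check_stability(times: np.ndarray, sizes: np.ndarray) -> None:
    """Warn if the growth rate shifted > 5% between the last two doublings."""
    top = sizes[-1]
    sel2 = sizes >= top / 2
    sel1 = (sizes >= top / 4) & ~sel2
    if sel1.sum() < 3 or sel2.sum() < 3:
        return
    k1 = np.polyfit(times[sel1], np.log(sizes[sel1]), 1)[0]
    k2 = np.polyfit(times[sel2], np.log(sizes[sel2]), 1)[0]
    if abs(k2 - k1) / abs(k2) > 0.05:
        warnings.warn(
            "growth rate unstable between the last two doublings; "
            "population cap may be too small for steady state"
        )
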