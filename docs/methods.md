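# Methods

This note records the model implemented by `lagtime`, the numerical and
design choices behind it, what the synthetic-data generators do and do
not emulate, and the package's known limitations.

## Model

### Lag time and the log-slope law

In steady-state exponential growth at rate `k_G = ln2/T`, every locus's
copy-number trajectory is the origin's trajectory delayed by the
replication lag, so relative abundance encodes time:
`τ(ℓ) = (1/k_G)·ln(N₀/N(ℓ))`. Differentiating
`N(ℓ) = N₀·e^(−k_G τ(ℓ))` with `τ(ℓ) = ∫₀^ℓ dℓ′/v(ℓ′)` gives the local
log-slope law `α(ℓ) = −d ln N/dℓ = k_G/v(ℓ)`. A replisome pause of
duration `Δτ` at a locus appears as a step of height `k_G·Δτ` in
`ln N`, downward in the direction of fork travel.

Critically, the law survives cell-cycle stochasticity: a stochastic
duration `t` enters all population-level quantities only through its
exponential mean `τ = −(1/k_G)·ln E[e^(−k_G t)]`. Two consequences:

- For fast steps (single-nucleotide incorporation, or one genomic bin),
  `τ ≈ μ − k_G σ²/2`, a negligible correction, so the log-slope law
  holds with the ordinary velocity. For the simulator's coarse bins the
  correction is `ln(1+k_G μ_step)/(k_G μ_step) − 1 ≈ −k_G μ_step/2`;
  the validation battery keeps `k_G·μ_step ≲ 10⁻³` so it stays well
  below statistical resolution.
- For slow or heavy-tailed processes the bias matters: an exponential
  pause with single-cell mean `μ` is measured as `ln(1+k_G μ)/k_G`, and
  a fraction `ε` of permanently arrested lineages contributes a finite
  `−T·log₂(1−ε)` — arrest is indistinguishable from a longer pause.
  `arrest_corrected_pause` removes this term when `ε` is known
  independently, with delta-method error propagation if `ε` carries an
  uncertainty.

### Assumptions

- The culture is in steady-state exponential growth and `T` is measured
  independently (growth rate is never inferred from the sequencing
  data).
- Fork motion is unidirectional at every analyzed locus. This fails
  near the terminus where forks meet, so bins inside a configurable
  terminus exclusion window (default half-width 100 kb) are dropped.
- Read depth is proportional to locus copy number with Poisson counting
  noise; no GC or mappability correction is applied (an optional
  per-bin divisor hook exists, but no correction method is prescribed).

## Estimation

### Binning and masking

Alignments are counted by leftmost mapped coordinate into 0-based
half-open bins (default 1 kb); fragment-midpoint assignment would shift
profiles by far less than a bin. Secondary, supplementary and duplicate
alignments are excluded; default mapping-quality threshold 20. Bins
with zero counts are masked (never log-transformed or imputed), as are
bins in declared masked intervals, and bins whose ln-count deviates
from a 21-bin running median by more than 5 robust standard deviations
(1.4826·MAD). The outlier pass iterates to a fixpoint so masking is
idempotent; the threshold is deliberately conservative so genuine
pause steps — at most tens of percent in copy number — are never
masked. Masking flags bins; it never alters counts.

### Weighted least squares and AIC

The response is `y = ln(count/total)` with weights `w = count`, the
inverse delta-method variance of a Poisson log-count. Bins with fewer
than 10 counts are excluded to keep that approximation valid. The model
is continuous piecewise-linear per arm (hinge basis on distance from
the origin), with one free intercept `ln N₀` per chromosome, optional
step columns at declared pause loci (indicator on "replicated after the
locus", so the sign convention is structural), and optional slope
sharing across arms. Parameter covariance comes from the weighted
normal equations; `χ² = Σ w·r²`.

With per-bin variance treated as known, `AIC = χ² + 2k` up to an
additive constant, so only AIC differences are meaningful; ΔAIC values
from conventions that re-estimate a residual scale can differ at O(1).
Knot layouts are uniform grids from the origin outward, with anchor
loci (pause sites, region boundaries) inserted as extra knots; grids of
candidate spacings are compared by AIC (`select_knot_spacing`). Each
segment must contain at least 10 retained bins. Rank deficiency is
reported with the offending parameters named, never silently
regularized.

The constant-velocity null is tested against the selected model by a
likelihood-ratio test (`χ²_null − χ²_full` on `k_full − k_null`
degrees of freedom). Underflowing p-values are reported through an
exact log-tail bound rather than 0. Calibration (uniform null p-values
at 500 replicates) is part of the validation battery.

### Resolution

Finite read number limits time resolution as `σ_τ = 1/(k_G√N)`; the
velocity from lag-time differences of adjacent knot windows of width
`Δℓ` at depth `n` reads/bp has
`σ_v/v = √(2/(n·Δℓ³))·(v/k_G)` — about 10% at 1.5 reads/bp and 100-kb
knots for typical fast growth. Both formulas are validated by
Monte-Carlo in the battery; note the full piecewise fit couples
neighboring segments, so its segment-slope errors carry a modestly
larger constant than the two-window formula.

### Derived dynamics

Velocities are `v = k_G/α` per segment with delta-method errors;
segments with non-positive fitted slope are flagged as
layout/normalization faults and excluded from statistics, never
silently accepted. The lag-time coordinate of a segment midpoint is
read off the fitted curve, `τ = (ln N₀ − ln N̂)/k_G`, which telescopes
`∫dℓ/v` plus pause steps exactly.

**Bilateral symmetry.** Matched left/right segment pairs (nearest
`|ℓ|`, tolerance half the median segment length) are decomposed about
the common mean into symmetric `s = (d_R+d_L)/2` and antisymmetric
`a = (d_R−d_L)/2` parts; `f_S = Σs²/(Σs²+Σa²)`. This operational
definition reproduces the limiting behaviours that motivate it: a
purely time-dependent velocity gives `f_S = 1`, independent arm noise
gives `f_S ≈ 1/2` (exactly `(n−1)/(2n−1)` in expectation at `n` pairs,
because the common mean is estimated). Segments labelled by a
direction map (retrograde regions of ectopic-origin strains) are
excluded.

**Oscillations.** The relative velocity `u(τ) = v(τ)/v̄ − 1` (arms
pooled, or one arm when the other is confounded, e.g. by rDNA pauses)
is fit by a single un-damped sinusoid `A·cos(2πτ/P + φ)` with a free
intercept absorbing the error in `v̄`. `(A, φ)` solve a linear problem
at each period of a grid (default 2–40 min, 0.5-min step); the optimum
is refined by parabolic interpolation and kept only if it lowers the
residual. Positive `φ` advances the cosine, so an early velocity peak
gives negative phase; `A` is the cosine amplitude (half peak-to-peak).
Perfectly uniform lag-time sampling can alias the period grid; real
segment grids are irregular, and the fitter accepts a precomputed
`(τ, u)` series for controlled analyses.

**Mean fork number.** Origin firings occur at rate `k_G` per origin in
steady state and each firing's fork pair lives for the chromosome's
replication span `C_c`, beginning `τ_c` after the primary origin fires.
Counting pairs per cell under the steady-state demography gives

    N̄_F = Σ_c 2^((C_end+D)/T) · (2^(−τ_c/T) − 2^(−(τ_c+C_c)/T)),

with `C_end = max_c(τ_c + C_c)` and a user-supplied D period. For one
chromosome this is `2^((C+D)/T) − 2^(D/T)`: exactly one continuous pair
for back-to-back rounds (`C = T, D = 0`) and `ln2·C/T·2^(D/T)` in slow
growth. This computation is a reconstruction (the quantity admits
several reasonable averages — the lineage time-average, for instance,
gives `C/T` in slow growth); the population average implemented here is
the one the simulator's census measures, and the two agree within 10%
in the test battery.

## Synthetic data

### Analytic generator

`analytic_marker_frequency` evaluates
`N(ℓ) = N₀·e^(−k_G τ(ℓ))` exactly for piecewise-constant, per-bin or
callable velocity fields plus exponential-mean pause offsets, and
`sample_reads` draws multinomial reads (Poisson conditioned on the
total). This is the exact expectation of the stochastic model below and
serves as the fast oracle for fitting.

### Stochastic population engine

`simulate_population` grows a population from a single progenitor.
Per cell: birth → B period (delta/exponential/uniform) → bidirectional
fork launch → one stepping event per genomic bin with lifetime drawn
per bin (delta/exponential/uniform; mean = bin length / local velocity)
→ optional pause sites with stochastic lifetimes and permanent-arrest
probability `ε` → termination → D period → division into two newborns.
Arrested lineages never divide but remain in the census — precisely
what produces the arrest limit. The census sums per-bin copy numbers
over all cells when the population reaches the cap (default 10⁵), and
the realized growth rate comes from the terminal slope of the log
population-size trajectory (final half; division bursts truncated by
the cap are dropped, which matters only for near-deterministic
configurations).

Design notes:

- **Per-bin granularity.** One event per bin, not per nucleotide: the
  exponential-mean error this introduces is `~k_G·σ²_step/2` per step,
  well under a second for the defaults, while making the engine
  desk-scale (a 10⁵-cell census in ~10 s).
- **Multifork mode** re-initiates each origin copy after a stochastic
  interval (default exponential) of configured mean, irrespective of
  fork completion. The interval is stochastic by design: a strictly
  periodic interval started from a single progenitor never relaxes to
  an asynchronous steady state — the population stays in synchronized
  bursts, the age distribution sits on a lattice, and the marker
  frequency is a staircase rather than an exponential decay. A `delta`
  option remains for studying exactly that regime. For the same reason
  the validation battery keeps the B period stochastic whenever
  stepping is deterministic.
- **Census noise.** All cells share one progenitor, so census bin
  counts carry correlated demographic fluctuations of relative size
  `~1/√cap` beyond read-sampling noise. Validation therefore samples
  reads at depths where Poisson counting noise dominates (per-bin
  ~10³ reads at cap 10⁵) — also the realistic regime, since real
  cultures contain orders of magnitude more cells than reads.

### What the generators do not emulate

Initiation-mass control (DnaA-type regulation), chromosome segregation
and cell-size dynamics, GC/mappability bias, library-preparation
artifacts, and stationary-phase contamination. Passing the validation
battery therefore demonstrates the estimator's correctness under the
stated stochastic cell-cycle model, not robustness to real-data
systematics — for real data the masking and model-comparison machinery
exist precisely because those systematics are present.

## Validation battery sizes

The battery (tests and `scripts/acceptance.py`) uses: six stochastic
configurations at 200 bins/arm and 10⁵-cell caps for the log-slope law;
5·10⁴-cell populations for the exponential-mean pause (μ = 600 s,
T ≈ 30 min) and arrest (ε = 0.1) checks; 200 Poisson replicates for
the resolution formulas; a 16-segment (500-kb blocks, ±30% velocity
scatter) genome at 6×10⁶ reads with 50 seeds for AIC resolution; 1000
replicates for the symmetry null; 100 seeds for oscillation recovery at
the Poisson noise level of ~6×10⁶ reads; and 500 replicates for LRT
calibration. These sizes give each check a comfortable statistical
margin while the whole battery runs in a few minutes on one CPU.

## Limitations

- Doubling time `T` must be supplied; errors in `T` scale all lag times
  and velocities proportionally (they covary between loci, so ratios
  and pause durations are less affected).
- Negative lag times (a locus more abundant than the origin) are
  reported with a warning rather than clamped — they diagnose a wrong
  origin position or normalization, not a physical velocity.
- Knots live on fixed grids plus anchors; there is no changepoint
  discovery, and features smaller than the AIC-selected spacing are
  averaged over.
- The velocity is undefined inside the terminus exclusion window
  (bidirectional fork motion), although replication timing there is
  still well measured.
- The Chr2-style secondary chromosome couples into the fit only through
  a free intercept (its origin's lag time); pause measurements across
  the trigger locus → secondary origin use the fitted values at those
  loci.
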