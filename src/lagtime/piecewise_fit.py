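"""Continuous piecewise-linear fits to ln marker frequency.

The log marker frequency on each arm is fit as a continuous piecewise
linear function of the distance from the origin, with per-segment
log-slopes alpha (units 1/bp, alpha = k_G / v), optional downward step
discontinuities at declared pause loci (step height s = k_G * dtau),
and one free intercept ln N0 per chromosome. Fits are weighted least
squares with weights w = bin count — the delta-method inverse variance
of a Poisson log-count — so the weighted residual sum is a chi^2 with
known unit variance and AIC = chi^2 + 2k (additive constant dropped;
only AIC differences are meaningful). Model resolution (knot spacing)
is selected by AIC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lagtime_core import MarkerFrequencyProfile

__all__ = [
    "PauseLocus",
    "PiecewiseSpec",
    "PiecewiseModel",
    "fit_piecewise",
    "aic",
    "select_knot_spacing",
    "compare_pause_models",
    "LRTResult",
    "likelihood_ratio_test",
    "sigma_tau",
    "sigma_v_relative",
]


@dataclass(frozen=True)
class PauseLocus:
    """A locus where a step discontinuity in ln N is allowed.

    Pauses sharing a ``group`` share a single step parameter
    (the all-equal scheme); distinct groups are fit freely.
    """

    chrom: str
    arm: str
    abs_ell: float
    group: str = ""
    name: str = ""

    @property
    def key(self) -> str:
        return self.group or f"{self.name or 'pause'}@{self.chrom}:{self.arm}:{self.abs_ell:.0f}"


@dataclass
class PiecewiseSpec:
    """Knot layout and parameter-sharing scheme for a piecewise fit.

    ``knots`` maps (chrom, arm) to a strictly increasing array of
    distances from the origin, anchored at 0 and at the arm end.
    ``slope_sharing='shared'`` ties the slope of segment j on every arm
    of a chromosome to a single parameter (segments are paired by
    index; unpaired segments of a longer arm stay free).
    """

    knots: dict[tuple[str, str], np.ndarray]
    pauses: list[PauseLocus] = field(default_factory=list)
    slope_sharing: str = "independent"

    def __post_init__(self) -> None:
        if self.slope_sharing not in ("independent", "shared"):
            raise ValueError("slope_sharing must be 'independent' or 'shared'")
        for key, kn in self.knots.items():
            kn = np.asarray(kn, dtype=float)
            if len(kn) < 2 or np.any(np.diff(kn) <= 0) or kn[0] != 0:
                raise ValueError(
                    f"knots for {key} must be strictly increasing and start at 0"
                )
            self.knots[key] = kn
        for p in self.pauses:
            kn = self.knots.get((p.chrom, p.arm))
            if kn is None:
                raise ValueError(f"pause {p} lies on an arm without knots")
            if not (0 < p.abs_ell < kn[-1]):
                raise ValueError(f"pause at {p.abs_ell} not strictly inside its arm")

    # ---- constructors --------------------------------------------------
    @classmethod
    def constant(
        cls,
        arm_spans: dict[tuple[str, str], float],
        pauses: list[PauseLocus] | None = None,
        slope_sharing: str = "independent",
    ) -> "PiecewiseSpec":
        """One segment per arm: constant velocity."""
        knots = {key: np.array([0.0, span]) for key, span in arm_spans.items()}
        return cls(knots=knots, pauses=list(pauses or []), slope_sharing=slope_sharing)

    @classmethod
    def uniform(
        cls,
        arm_spans: dict[tuple[str, str], float],
        spacing: float,
        anchors: dict[tuple[str, str], list[float]] | None = None,
        pauses: list[PauseLocus] | None = None,
        slope_sharing: str = "independent",
    ) -> "PiecewiseSpec":
        """Knots laid out from the origin outward at ``spacing``.

        Anchor loci (e.g. crtS, pause sites, region boundaries) are
        inserted as extra knots; knots closer than 10% of the spacing to
        an anchor are merged into it.
        """
        pauses = list(pauses or [])
        anchors = dict(anchors or {})
        for p in pauses:
            anchors.setdefault((p.chrom, p.arm), []).append(p.abs_ell)
        knots = {}
        for key, span in arm_spans.items():
            grid = list(np.arange(0.0, span, spacing)) + [float(span)]
            if grid[-1] - grid[-2] < 0.1 * spacing and len(grid) > 2:
                del grid[-2]
            for a in anchors.get(key, []):
                grid = [g for g in grid if g in (0.0, float(span)) or abs(g - a) >= 0.1 * spacing]
                if 0 < a < span:
                    grid.append(float(a))
            knots[key] = np.unique(np.asarray(grid, dtype=float))
        return cls(knots=knots, pauses=pauses, slope_sharing=slope_sharing)

    def is_nested_in(self, other: "PiecewiseSpec") -> bool:
        """True if every model this spec can express, ``other`` can too."""
        for key, kn in self.knots.items():
            if key not in other.knots:
                return False
            okn = other.knots[key]
            # the final knot is an arm-end anchor, not a breakpoint; only
            # interior knots constrain nesting
            if not np.all(np.isin(np.round(kn[1:-1], 6), np.round(okn, 6))):
                return False
        mine = {(p.chrom, p.arm, round(p.abs_ell, 6)) for p in self.pauses}
        theirs = {(p.chrom, p.arm, round(p.abs_ell, 6)) for p in other.pauses}
        if not mine <= theirs:
            return False
        if self.slope_sharing == "independent" and other.slope_sharing == "shared":
            # free arm slopes cannot be expressed by a shared-slope model
            # unless the shared model has at least as many segments (it
            # does not, pairing by index), so reject
            return False
        return True


@dataclass
class PiecewiseModel:
    """A fitted piecewise-linear marker-frequency model."""

    spec: PiecewiseSpec
    intercepts: dict[str, float]
    segments: pd.DataFrame  # chrom, arm, lo, hi, alpha, alpha_se, n_bins
    steps: pd.DataFrame  # group, s, s_se, n_loci
    beta: np.ndarray
    cov: np.ndarray
    param_names: list[str]
    chi2: float
    dof: int
    n_bins: int
    k: int

    @property
    def aic(self) -> float:
        return self.chi2 + 2 * self.k

    def predict(self, chrom: str, arm: str, abs_ell) -> np.ndarray:
        """Predicted ln(count / total) at distance(s) from the origin."""
        abs_ell = np.atleast_1d(np.asarray(abs_ell, dtype=float))
        y = np.full(len(abs_ell), self.intercepts[chrom])
        segs = self.segments[
            (self.segments.chrom == chrom) & (self.segments.arm == arm)
        ]
        for seg in segs.itertuples(index=False):
            y -= seg.alpha * np.clip(abs_ell - seg.lo, 0.0, seg.hi - seg.lo)
        for p in self.spec.pauses:
            if p.chrom == chrom and p.arm == arm:
                s = float(self.steps.loc[self.steps.group == p.key, "s"].iloc[0])
                y -= s * (abs_ell > p.abs_ell)
        return y

    def _design_row(self, chrom: str, arm: str, abs_ell: float) -> np.ndarray:
        row = np.zeros(self.k)
        row[self.param_names.index(f"lnN0[{chrom}]")] = 1.0
        for seg in self.segments.itertuples(index=False):
            if seg.chrom != chrom or seg.arm != arm:
                continue
            for name in (
                f"alpha[{chrom}:{arm}:seg{seg.seg}]",
                f"alpha[{chrom}:seg{seg.seg}]",
            ):
                if name in self.param_names:
                    row[self.param_names.index(name)] -= float(
                        np.clip(abs_ell - seg.lo, 0.0, seg.hi - seg.lo)
                    )
                    break
        for p in self.spec.pauses:
            if p.chrom == chrom and p.arm == arm and abs_ell > p.abs_ell:
                row[self.param_names.index(f"step[{p.key}]")] -= 1.0
        return row

    def lag_times(self, k_G: float) -> pd.DataFrame:
        """Per-knot lag times tau = (lnN0 - y_hat)/k_G with standard errors.

        tau at the origin is 0 by construction; errors come from the
        fitted parameter covariance by the delta method.
        """
        rows = []
        for (chrom, arm), kn in sorted(self.spec.knots.items()):
            e_int = np.zeros(self.k)
            e_int[self.param_names.index(f"lnN0[{chrom}]")] = 1.0
            for pos in kn:
                g = (e_int - self._design_row(chrom, arm, float(pos))) / k_G
                tau = float(g @ self.beta)
                se = float(math.sqrt(max(g @ self.cov @ g, 0.0)))
                rows.append(
                    {"chrom": chrom, "arm": arm, "position": float(pos),
                     "tau_s": tau, "se_s": se}
                )
        return pd.DataFrame(rows)

    def diagnostics(self, profile) -> pd.DataFrame:
        """Observed vs fitted ln marker frequency per retained bin."""
        out = profile.data[["chrom", "arm", "ell", "abs_ell", "y", "w"]].copy()
        fitted = np.empty(len(out))
        for (chrom, arm), g in out.groupby(["chrom", "arm"], sort=False):
            fitted[g.index] = self.predict(chrom, arm, g["abs_ell"].to_numpy())
        out["y_fit"] = fitted
        out["residual"] = out["y"] - out["y_fit"]
        return out

    def pause_estimates(self, k_G: float) -> pd.DataFrame:
        """Pause durations dtau = s / k_G (seconds) with standard errors."""
        out = self.steps.copy()
        out["dtau"] = out["s"] / k_G
        out["dtau_se"] = out["s_se"] / k_G
        return out

    def monotonicity_violations(self) -> pd.DataFrame:
        """Segments where predicted ln N increases away from the origin."""
        return self.segments[self.segments.alpha < 0]

    def to_dict(self) -> dict:
        return {
            "intercepts": self.intercepts,
            "segments": self.segments.to_dict(orient="records"),
            "steps": self.steps.to_dict(orient="records"),
            "chi2": self.chi2,
            "dof": self.dof,
            "k": self.k,
            "aic": self.aic,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _build_design(profile: MarkerFrequencyProfile, spec: PiecewiseSpec,
                  min_bins_per_segment: int):
    data = profile.data
    chroms = profile.chromosomes
    names: list[str] = [f"lnN0[{c}]" for c in chroms]
    slope_param: dict[tuple[str, str, int], int] = {}
    seg_meta = []  # (chrom, arm, seg_idx, lo, hi, param_idx)
    shared_idx: dict[tuple[str, int], int] = {}
    for (chrom, arm), kn in sorted(spec.knots.items()):
        for j in range(len(kn) - 1):
            if spec.slope_sharing == "shared":
                skey = (chrom, j)
                if skey in shared_idx:
                    idx = shared_idx[skey]
                else:
                    idx = len(names)
                    names.append(f"alpha[{chrom}:seg{j}]")
                    shared_idx[skey] = idx
            else:
                idx = len(names)
                names.append(f"alpha[{chrom}:{arm}:seg{j}]")
            slope_param[(chrom, arm, j)] = idx
            seg_meta.append((chrom, arm, j, kn[j], kn[j + 1], idx))
    step_idx: dict[str, int] = {}
    for p in spec.pauses:
        if p.key not in step_idx:
            step_idx[p.key] = len(names)
            names.append(f"step[{p.key}]")
    k = len(names)
    n = len(data)
    X = np.zeros((n, k))
    x = data["abs_ell"].to_numpy()
    for ci, chrom in enumerate(chroms):
        X[(data.chrom == chrom).to_numpy(), ci] = 1.0
    seg_counts = {}
    for chrom, arm, j, lo, hi, idx in seg_meta:
        sel = ((data.chrom == chrom) & (data.arm == arm)).to_numpy()
        X[sel, idx] -= np.clip(x[sel] - lo, 0.0, hi - lo)
        nb = int(np.sum(sel & (x >= lo) & (x < hi)))
        seg_counts[(chrom, arm, j)] = nb
        if nb < min_bins_per_segment:
            raise ValueError(
                f"segment {chrom}:{arm} [{lo:.0f}, {hi:.0f}) has {nb} bins "
                f"(< {min_bins_per_segment}); refine the knot layout"
            )
    for p in spec.pauses:
        sel = ((data.chrom == p.chrom) & (data.arm == p.arm)).to_numpy()
        X[sel, step_idx[p.key]] -= (x[sel] > p.abs_ell).astype(float)
    return X, names, seg_meta, seg_counts, step_idx


def fit_piecewise(
    profile: MarkerFrequencyProfile,
    spec: PiecewiseSpec,
    min_bins_per_segment: int = 10,
) -> PiecewiseModel:
    """Weighted least-squares fit of the piecewise-linear model.

    The response is y = ln(count/total) with weights w = count; the
    parameter covariance comes from the weighted normal equations
    (known per-bin variance 1/count), chi^2 = sum w * residual^2.
    """
    X, names, seg_meta, seg_counts, step_idx = _build_design(
        profile, spec, min_bins_per_segment
    )
    y = profile.data["y"].to_numpy()
    w = profile.data["w"].to_numpy()
    sw = np.sqrt(w)
    A = X * sw[:, None]
    b = y * sw
    G = A.T @ A
    # scaled condition check to catch unidentifiable segments
    d = np.sqrt(np.diag(G))
    if np.any(d == 0):
        bad = [names[i] for i in np.flatnonzero(d == 0)]
        raise ValueError(f"unidentifiable parameters (no data support): {bad}")
    Gs = G / np.outer(d, d)
    if np.linalg.cond(Gs) > 1e10:
        u, s, vt = np.linalg.svd(Gs)
        bad_dir = np.abs(vt[-1])
        bad = [names[i] for i in np.flatnonzero(bad_dir > 0.3)]
        raise ValueError(f"rank-deficient design; degenerate parameters: {bad}")
    beta = np.linalg.solve(G, A.T @ b)
    cov = np.linalg.inv(G)
    resid = y - X @ beta
    chi2 = float(np.sum(w * resid ** 2))
    n, k = X.shape
    chroms = profile.chromosomes
    intercepts = {c: float(beta[i]) for i, c in enumerate(chroms)}
    seg_rows = [
        {
            "chrom": chrom,
            "arm": arm,
            "seg": j,
            "lo": lo,
            "hi": hi,
            "alpha": float(beta[idx]),
            "alpha_se": float(math.sqrt(cov[idx, idx])),
            "n_bins": seg_counts[(chrom, arm, j)],
        }
        for chrom, arm, j, lo, hi, idx in seg_meta
    ]
    step_rows = [
        {
            "group": key,
            "s": float(beta[idx]),
            "s_se": float(math.sqrt(cov[idx, idx])),
            "n_loci": sum(1 for p in spec.pauses if p.key == key),
        }
        for key, idx in step_idx.items()
    ]
    return PiecewiseModel(
        spec=spec,
        intercepts=intercepts,
        segments=pd.DataFrame(seg_rows),
        steps=pd.DataFrame(step_rows, columns=["group", "s", "s_se", "n_loci"]),
        beta=beta,
        cov=cov,
        param_names=names,
        chi2=chi2,
        dof=n - k,
        n_bins=n,
        k=k,
    )


def aic(model: PiecewiseModel) -> float:
    """AIC = chi^2 + 2k under known per-bin variance; differences only."""
    return model.aic


def select_knot_spacing(
    profile: MarkerFrequencyProfile,
    candidate_spacings,
    pauses: list[PauseLocus] | None = None,
    anchors: dict[tuple[str, str], list[float]] | None = None,
    slope_sharing: str = "independent",
    min_bins_per_segment: int = 10,
) -> PiecewiseModel:
    """Fit one model per candidate knot spacing and return the AIC-minimal one.

    The full AIC table is attached to the returned model as
    ``model.aic_table`` for reporting.
    """
    candidate_spacings = list(candidate_spacings)
    if len(candidate_spacings) < 2:
        raise ValueError("need at least 2 candidate spacings")
    rows, fits = [], {}
    for spacing in candidate_spacings:
        try:
            spec = PiecewiseSpec.uniform(
                profile.arm_spans, spacing, anchors=anchors, pauses=pauses,
                slope_sharing=slope_sharing,
            )
            m = fit_piecewise(profile, spec, min_bins_per_segment)
            fits[spacing] = m
            rows.append(
                {"spacing": spacing, "k": m.k, "n_knots": sum(len(v) for v in spec.knots.values()),
                 "chi2": m.chi2, "aic": m.aic}
            )
        except ValueError as exc:
            rows.append({"spacing": spacing, "k": np.nan, "n_knots": np.nan,
                         "chi2": np.nan, "aic": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    if not fits:
        raise ValueError("no candidate spacing produced a fittable model")
    best_spacing = min(fits, key=lambda s: fits[s].aic)
    best = fits[best_spacing]
    best.aic_table = table  # type: ignore[attr-defined]
    best.selected_spacing = best_spacing  # type: ignore[attr-defined]
    return best


def compare_pause_models(
    profile: MarkerFrequencyProfile,
    rdna_loci: list[PauseLocus],
    min_bins_per_segment: int = 10,
) -> pd.DataFrame:
    """Fit the four constant-velocity pause hypotheses and rank by AIC.

    Model 1: equal arm velocities, no pauses. Model 2: unequal arm
    velocities, no pauses. Model 3: equal arm velocities with
    equal-duration pauses at every listed locus. Model 4: unequal arm
    velocities with the pauses. All pause steps share one duration
    parameter. Returns a table sorted by AIC with dAIC vs the best, the
    shared step height where fitted, and the fitted models in a
    ``model`` column.
    """
    if not rdna_loci:
        raise ValueError("rdna_loci must be non-empty")
    shared = [
        PauseLocus(p.chrom, p.arm, p.abs_ell, group="rdna", name=p.name)
        for p in rdna_loci
    ]
    spans = profile.arm_spans
    configs = [
        (1, "equal velocities, no pauses", "shared", None),
        (2, "unequal velocities, no pauses", "independent", None),
        (3, "equal velocities, rDNA pauses", "shared", shared),
        (4, "unequal velocities, rDNA pauses", "independent", shared),
    ]
    rows = []
    for num, label, sharing, pauses in configs:
        spec = PiecewiseSpec.constant(spans, pauses=pauses, slope_sharing=sharing)
        m = fit_piecewise(profile, spec, min_bins_per_segment)
        row = {"model": num, "description": label, "k": m.k, "chi2": m.chi2,
               "aic": m.aic, "s": np.nan, "s_se": np.nan, "fit": m}
        if pauses is not None:
            row["s"] = float(m.steps["s"].iloc[0])
            row["s_se"] = float(m.steps["s_se"].iloc[0])
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["daic"] = table["aic"] - table["aic"].iloc[0]
    return table


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float
    log10_p: float  # exact log10 tail probability; use when p underflows

    def __str__(self) -> str:
        if self.p > 0:
            return f"LRT chi2={self.statistic:.2f}, df={self.df}, p={self.p:.3g}"
        return (
            f"LRT chi2={self.statistic:.2f}, df={self.df}, "
            f"p < 10^{math.ceil(self.log10_p)}"
        )


def likelihood_ratio_test(
    null_model: PiecewiseModel, full_model: PiecewiseModel
) -> LRTResult:
    """Chi-square test of a nested (null) model against a richer one.

    Statistic = chi^2_null - chi^2_full with df = k_full - k_null.
    Underflowing p-values are reported through ``log10_p`` (an exact
    log-tail bound), never as 0 alone.
    """
    if full_model.n_bins != null_model.n_bins:
        raise ValueError("models were fit to different data")
    if not null_model.spec.is_nested_in(full_model.spec):
        raise ValueError("null model is not nested in the full model")
    df = full_model.k - null_model.k
    stat = null_model.chi2 - full_model.chi2
    if df == 0:
        return LRTResult(statistic=stat, df=0, p=1.0, log10_p=0.0)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    log10_p = float(stats.chi2.logsf(stat, df)) / math.log(10.0)
    if not math.isfinite(log10_p):
        # asymptotic upper tail: sf ~ (x/2)^(df/2-1) e^(-x/2) / Gamma(df/2)
        log10_p = (
            -stat / 2.0
            + (df / 2.0 - 1.0) * math.log(stat / 2.0)
            - math.lgamma(df / 2.0)
        ) / math.log(10.0)
    return LRTResult(statistic=stat, df=df, p=p, log10_p=log10_p)


def sigma_tau(read_count: float, k_G: float) -> float:
    """Poisson-limited lag-time uncertainty: sigma_tau = 1/(k_G sqrt(N))."""
    if read_count <= 0:
        raise ValueError("read count must be > 0")
    return 1.0 / (k_G * math.sqrt(read_count))


def sigma_v_relative(
    depth_per_base: float, knot_spacing: float, v: float, k_G: float
) -> float:
    """Relative fork-velocity error from Poisson counting noise.

    sigma_v / v = sqrt(2 / (n dl^3)) * (v / k_G), with n the read depth
    in reads per base and dl the knot spacing in bp.
    """
    if min(depth_per_base, knot_spacing, v, k_G) <= 0:
        raise ValueError("all arguments must be > 0")
    return math.sqrt(2.0 / (depth_per_base * knot_spacing ** 3)) * v / k_G
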