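"""Fork-velocity profiles, bilateral symmetry and temporal oscillations.

A fitted piecewise model gives per-segment log-slopes alpha; the fork
velocity is v = k_G / alpha (kb/s) and the lag-time coordinate of a
segment midpoint follows from the fitted curve itself,
tau = (ln N0 - ln N_hat) / k_G, which telescopes the cumulative
integral of 1/v plus any pause steps. Bilateral symmetry between the
two arms is quantified by splitting matched-pair velocity deviations
into symmetric and antisymmetric parts; temporal structure is
summarized by a single-sinusoid fit of the relative velocity versus
lag time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeLayout
from .piecewise_fit import PiecewiseModel

__all__ = [
    "VelocityProfile",
    "velocity_profile",
    "mean_velocity",
    "region_velocity_ratio",
    "origin_initiation_lag",
    "mean_fork_number",
    "SymmetryResult",
    "symmetry_fraction",
    "OscillationFit",
    "oscillation_fit",
    "relative_velocity_curves",
]


@dataclass
class VelocityProfile:
    """Per-segment fork velocities with genomic and lag-time midpoints.

    ``segments`` columns: chrom, arm, lo, hi, length, ell_mid (signed bp,
    right +, left -), abs_mid, tau_mid (s), v (kb/s), v_se (kb/s),
    flagged (alpha <= 0: excluded from statistics).
    """

    segments: pd.DataFrame
    k_G: float
    label: str = ""

    @property
    def valid(self) -> pd.DataFrame:
        return self.segments[~self.segments.flagged]

    @property
    def mean(self) -> float:
        return mean_velocity(self)[0]


def velocity_profile(
    model: PiecewiseModel, k_G: float, label: str = ""
) -> VelocityProfile:
    """Invert fitted log-slopes into a fork-velocity profile.

    v = k_G / alpha per segment, with delta-method standard error
    k_G * SE_alpha / alpha^2. Segments with alpha <= 0 (apparent copy
    number increasing away from the origin — a layout or normalization
    fault) are flagged and excluded from downstream statistics.
    Lag-time midpoints come from the fitted curve, including pause
    steps, so the tau axis telescopes the integral of 1/v.
    """
    rows = []
    for seg in model.segments.itertuples(index=False):
        mid = 0.5 * (seg.lo + seg.hi)
        yhat = float(model.predict(seg.chrom, seg.arm, mid)[0])
        tau = (model.intercepts[seg.chrom] - yhat) / k_G
        flagged = seg.alpha <= 0
        if flagged:
            v = v_se = np.nan
        else:
            v = k_G / seg.alpha / 1000.0  # kb/s
            v_se = k_G * seg.alpha_se / seg.alpha ** 2 / 1000.0
        sign = -1.0 if seg.arm == "left" else 1.0
        rows.append(
            {
                "chrom": seg.chrom,
                "arm": seg.arm,
                "lo": seg.lo,
                "hi": seg.hi,
                "length": seg.hi - seg.lo,
                "ell_mid": sign * mid,
                "abs_mid": mid,
                "tau_mid": tau,
                "v": v,
                "v_se": v_se,
                "flagged": flagged,
            }
        )
    segments = pd.DataFrame(rows)
    segments = segments.sort_values(["chrom", "arm", "lo"]).reset_index(drop=True)
    return VelocityProfile(segments=segments, k_G=k_G, label=label)


def _select(vp: VelocityProfile, region) -> pd.DataFrame:
    df = vp.valid
    if region is None:
        return df
    if callable(region):
        return df[region(df)]
    chrom, arm, lo, hi = region
    sel = (df.abs_mid >= lo) & (df.abs_mid < hi)
    if chrom is not None:
        sel &= df.chrom == chrom
    if arm is not None:
        sel &= df.arm == arm
    return df[sel]


def mean_velocity(vp: VelocityProfile, region=None) -> tuple[float, float]:
    """Segment-length-weighted mean and std of the fork velocity (kb/s).

    ``region`` is None (all unflagged segments), a ``(chrom, arm, lo,
    hi)`` tuple in distance-from-origin coordinates (None entries are
    wildcards), or a boolean predicate on the segment table.
    """
    df = _select(vp, region)
    if len(df) == 0:
        raise ValueError("no unflagged segments in region")
    w = df["length"].to_numpy(dtype=float)
    v = df["v"].to_numpy(dtype=float)
    vbar = float(np.average(v, weights=w))
    sigma = float(math.sqrt(np.average((v - vbar) ** 2, weights=w)))
    return vbar, sigma


def _region_mean_se(vp: VelocityProfile, region) -> tuple[float, float]:
    df = _select(vp, region)
    if len(df) == 0:
        raise ValueError("no unflagged segments in region")
    w = df["length"].to_numpy(dtype=float)
    v = df["v"].to_numpy(dtype=float)
    se = df["v_se"].to_numpy(dtype=float)
    vbar = float(np.average(v, weights=w))
    var = float(np.sum((w / w.sum()) ** 2 * se ** 2))
    return vbar, math.sqrt(var)


def region_velocity_ratio(
    vp: VelocityProfile, region_a, region_b
) -> tuple[float, float]:
    """Ratio of region mean velocities with propagated standard error."""
    va, sa = _region_mean_se(vp, region_a)
    vb, sb = _region_mean_se(vp, region_b)
    ratio = va / vb
    se = abs(ratio) * math.sqrt((sa / va) ** 2 + (sb / vb) ** 2)
    return ratio, se


def origin_initiation_lag(
    model: PiecewiseModel,
    k_G: float,
    trigger: tuple[str, str, float],
    target_chrom: str,
) -> float:
    """Lag between replication of a trigger locus and a second origin.

    Computed as the lag-time difference between the fitted marker
    frequency at the trigger locus (chrom, arm, distance) and the fitted
    origin intercept of ``target_chrom`` — e.g. the crtS -> oriC2 pause
    on the V. cholerae secondary chromosome.
    """
    chrom, arm, abs_ell = trigger
    y_trigger = float(model.predict(chrom, arm, abs_ell)[0])
    return (y_trigger - model.intercepts[target_chrom]) / k_G


def mean_fork_number(
    model: PiecewiseModel,
    layout: GenomeLayout,
    T: float,
    D_period: float,
) -> float:
    """Steady-state mean number of active fork pairs per cell.

    Reconstruction from the fitted lag-time spans: in an exponential
    steady state, origin firings occur at rate k_G per origin and each
    firing's fork pair lives for that chromosome's replication span
    C_c, starting tau_c after the primary origin fires. Counting pairs
    per cell under the steady-state age demography gives

        N_F = sum_c 2^((C_end + D)/T) * (2^(-tau_c/T) - 2^(-(tau_c+C_c)/T))

    with C_end = max_c (tau_c + C_c) the lag time of the last terminus.
    For a single chromosome this reduces to 2^((C+D)/T) - 2^(D/T):
    exactly one continuous pair for back-to-back rounds (C = T, D = 0)
    and ~ ln2 * C/T pairs in the slow-growth limit.
    """
    if D_period is None or D_period < 0:
        raise ValueError("D_period must be supplied and >= 0")
    k_G = math.log(2.0) / T
    ref = max(model.intercepts, key=model.intercepts.get)
    taus, spans = {}, {}
    for chrom in model.intercepts:
        segs = model.segments[model.segments.chrom == chrom]
        c_span = 0.0
        for arm in segs.arm.unique():
            end = segs[segs.arm == arm]["hi"].max()
            yhat = float(model.predict(chrom, arm, end)[0])
            c_span = max(c_span, (model.intercepts[chrom] - yhat) / k_G)
        spans[chrom] = c_span
        taus[chrom] = (model.intercepts[ref] - model.intercepts[chrom]) / k_G
    c_end = max(taus[c] + spans[c] for c in spans)
    total = 0.0
    for c in spans:
        total += 2.0 ** ((c_end + D_period) / T) * (
            2.0 ** (-taus[c] / T) - 2.0 ** (-(taus[c] + spans[c]) / T)
        )
    return total


@dataclass
class SymmetryResult:
    """Decomposition of arm velocity deviations about the origin."""

    grid: np.ndarray  # matched |ell| positions
    symmetric: np.ndarray  # s = (d_R + d_L) / 2
    antisymmetric: np.ndarray  # a = (d_R - d_L) / 2
    f_symmetric: float  # sum s^2 / (sum s^2 + sum a^2)

    @property
    def variance_fractions(self) -> tuple[float, float]:
        return self.f_symmetric, 1.0 - self.f_symmetric


def symmetry_fraction(
    vp: VelocityProfile, chrom: str | None = None, tol: float | None = None
) -> SymmetryResult:
    """Fraction of arm velocity variance that is origin-symmetric.

    Segment midpoints of the two arms are matched by nearest |ell|
    (tolerance: half the median segment length unless given). With
    deviations d_R, d_L of each arm from the common mean, the symmetric
    part is s = (d_R + d_L)/2 and the antisymmetric part
    a = (d_R - d_L)/2; f_S = sum s^2 / (sum s^2 + sum a^2). A purely
    time-dependent velocity gives f_S = 1; independent arm noise gives
    f_S ~ 0.5. Retrograde or other direction-map segments are excluded.
    """
    df = vp.valid
    if chrom is not None:
        df = df[df.chrom == chrom]
    right = df[df.arm == "right"].sort_values("abs_mid")
    left = df[df.arm == "left"].sort_values("abs_mid")
    if len(right) < 2 or len(left) < 2:
        raise ValueError("both arms need at least 2 unflagged segments")
    if tol is None:
        tol = 0.5 * float(df["length"].median())
    lo = max(right.abs_mid.min(), left.abs_mid.min()) - tol
    hi = min(right.abs_mid.max(), left.abs_mid.max()) + tol
    if hi <= lo:
        raise ValueError("arms have no overlapping |ell| range")
    grid_pts, vr, vl = [], [], []
    l_mid = left.abs_mid.to_numpy()
    l_v = left.v.to_numpy()
    for seg in right.itertuples(index=False):
        if not lo <= seg.abs_mid <= hi:
            continue
        j = int(np.argmin(np.abs(l_mid - seg.abs_mid)))
        if abs(l_mid[j] - seg.abs_mid) > tol:
            continue
        grid_pts.append(seg.abs_mid)
        vr.append(seg.v)
        vl.append(l_v[j])
    if len(grid_pts) < 2:
        raise ValueError("fewer than 2 matched segment pairs between arms")
    vr = np.asarray(vr)
    vl = np.asarray(vl)
    vbar = 0.5 * (vr.mean() + vl.mean())
    d_r = vr - vbar
    d_l = vl - vbar
    s = 0.5 * (d_r + d_l)
    a = 0.5 * (d_r - d_l)
    ss, aa = float(np.sum(s ** 2)), float(np.sum(a ** 2))
    return SymmetryResult(
        grid=np.asarray(grid_pts),
        symmetric=s,
        antisymmetric=a,
        f_symmetric=ss / (ss + aa) if ss + aa > 0 else 1.0,
    )


@dataclass
class OscillationFit:
    """Single-sinusoid description of relative velocity vs lag time.

    u(tau) = A cos(2 pi tau / P + phi): P in minutes, phi in degrees in
    (-180, 180] (an early velocity peak gives negative phi), A the
    cosine amplitude (half the peak-to-peak excursion).
    """

    period_min: float
    phase_deg: float
    amplitude: float
    residual_variance: float
    tau_window_s: tuple[float, float]
    n_points: int


def _sinusoid_rss(tau: np.ndarray, u: np.ndarray, w: np.ndarray, P_s: float):
    omega = 2.0 * math.pi / P_s
    # free intercept absorbs the error in the mean-velocity normalization
    X = np.column_stack(
        [np.cos(omega * tau), np.sin(omega * tau), np.ones_like(tau)]
    )
    A = X * np.sqrt(w)[:, None]
    b = u * np.sqrt(w)
    coef, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
    rss = float(np.sum(w * (u - X @ coef) ** 2))
    return rss, coef


def oscillation_fit(
    profiles,
    period_grid_min: np.ndarray | None = None,
    arms: tuple[str, ...] = ("left", "right"),
    weighted: bool = True,
) -> OscillationFit:
    """Fit u(tau) = A cos(2 pi tau / P + phi) over a period grid.

    ``profiles`` is a VelocityProfile or a list of them (conditions are
    pooled on the common lag-time axis after each is normalized by its
    own mean velocity), or a precomputed relative-velocity series as a
    ``(tau_s, u)`` pair of arrays or a DataFrame with ``tau_mid`` and
    ``u`` columns (as produced by :func:`relative_velocity_curves`). At
    each candidate period the amplitude and phase solve a linear
    least-squares problem (with a free intercept absorbing the
    mean-normalization error); the grid optimum is refined by local
    parabolic interpolation of the residual sum. Beware aliasing when
    segments are sampled perfectly uniformly in lag time.
    """
    if period_grid_min is None:
        period_grid_min = np.arange(2.0, 40.01, 0.5)
    if isinstance(profiles, tuple) and len(profiles) == 2:
        tau = np.asarray(profiles[0], dtype=float)
        u = np.asarray(profiles[1], dtype=float)
        return _oscillation_fit_series(tau, u, np.ones_like(tau), period_grid_min)
    if isinstance(profiles, pd.DataFrame):
        tau = profiles["tau_mid"].to_numpy(dtype=float)
        u = profiles["u"].to_numpy(dtype=float)
        return _oscillation_fit_series(tau, u, np.ones_like(tau), period_grid_min)
    if isinstance(profiles, VelocityProfile):
        profiles = [profiles]
    taus, us, ws = [], [], []
    for vp in profiles:
        df = vp.valid
        df = df[df.arm.isin(arms)]
        if len(df) == 0:
            continue
        vbar = float(
            np.average(df["v"], weights=df["length"])
        )
        taus.append(df["tau_mid"].to_numpy(dtype=float))
        us.append(df["v"].to_numpy(dtype=float) / vbar - 1.0)
        se = df["v_se"].to_numpy(dtype=float) / vbar
        if weighted and np.all(se > 0):
            ws.append(1.0 / se ** 2)
        else:
            ws.append(np.ones(len(df)))
    tau = np.concatenate(taus)
    u = np.concatenate(us)
    w = np.concatenate(ws)
    return _oscillation_fit_series(tau, u, w, period_grid_min)


def _oscillation_fit_series(
    tau: np.ndarray, u: np.ndarray, w: np.ndarray, period_grid_min
) -> OscillationFit:
    if len(tau) < 5:
        raise ValueError("fewer than 5 segments available for the oscillation fit")
    grid_s = np.asarray(period_grid_min, dtype=float) * 60.0
    rss = np.array([_sinusoid_rss(tau, u, w, P)[0] for P in grid_s])
    i = int(np.argmin(rss))
    P_best = grid_s[i]
    if 0 < i < len(grid_s) - 1:
        # parabolic refinement through the three bracketing grid points
        x0, x1, x2 = grid_s[i - 1], grid_s[i], grid_s[i + 1]
        y0, y1, y2 = rss[i - 1], rss[i], rss[i + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
        if a > 0:
            P_ref = -b / (2 * a)
            if x0 < P_ref < x2 and _sinusoid_rss(tau, u, w, P_ref)[0] <= y1:
                P_best = P_ref
    rss_best, coef = _sinusoid_rss(tau, u, w, P_best)
    amp = float(math.hypot(coef[0], coef[1]))
    phase = math.degrees(math.atan2(-coef[1], coef[0]))
    if phase <= -180.0:
        phase += 360.0
    return OscillationFit(
        period_min=P_best / 60.0,
        phase_deg=phase,
        amplitude=amp,
        residual_variance=rss_best / max(len(tau) - 3, 1),
        tau_window_s=(float(tau.min()), float(tau.max())),
        n_points=len(tau),
    )


def relative_velocity_curves(profiles, labels=None) -> pd.DataFrame:
    """Relative velocity u = v/vbar - 1 per condition on a shared tau axis.

    Returns a long-format table (label, chrom, arm, ell_mid, tau_mid, v,
    u) for cross-condition comparison; u is invariant under rescaling
    all of a condition's velocities.
    """
    if isinstance(profiles, VelocityProfile):
        profiles = [profiles]
    if labels is None:
        labels = [vp.label or f"condition{i}" for i, vp in enumerate(profiles)]
    frames = []
    for label, vp in zip(labels, profiles):
        df = vp.valid.copy()
        vbar = float(np.average(df["v"], weights=df["length"]))
        df["u"] = df["v"] / vbar - 1.0
        df["label"] = label
        frames.append(df[["label", "chrom", "arm", "ell_mid", "tau_mid", "v", "u"]])
    return pd.concat(frames, ignore_index=True)
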