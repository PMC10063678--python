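"""Piecewise-linear fitting, AIC selection, hypothesis tests, resolution."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lagtime as lt

MIN = 60.0


def profile_from_arrays(y, w, abs_ell, arm="right", T_s=1800.0, chrom="sim"):
    """Assemble a MarkerFrequencyProfile directly from arrays."""
    sign = -1.0 if arm == "left" else 1.0
    data = pd.DataFrame(
        {
            "chrom": chrom,
            "arm": arm,
            "region": arm,
            "ell": sign * np.asarray(abs_ell, dtype=float),
            "abs_ell": np.asarray(abs_ell, dtype=float),
            "y": np.asarray(y, dtype=float),
            "w": np.asarray(w, dtype=float),
        }
    )
    return lt.MarkerFrequencyProfile(
        data=data, T=T_s, total_reads=float(np.sum(w)),
        arm_spans={(chrom, arm): float(np.max(abs_ell))},
    )


class TestFitPiecewise:
    def test_noiseless_exact_interpolation(self):
        alpha = 3e-7
        x = np.linspace(5_000, 1_995_000, 200)
        y = -2.0 - alpha * x
        prof = profile_from_arrays(y, np.full_like(x, 1e4), x)
        spec = lt.PiecewiseSpec(
            knots={("sim", "right"): np.array([0.0, 0.7e6, 1.3e6, 2e6])},
            pauses=[lt.PauseLocus("sim", "right", 1e6, group="p")],
        )
        model = lt.fit_piecewise(prof, spec)
        np.testing.assert_allclose(model.segments.alpha, alpha, rtol=1e-9)
        assert model.steps.s.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert model.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_step_duration_closed_form(self):
        # a 0.10 ln-unit drop at the pause locus is dtau = 0.10 T / ln2
        T = 30 * MIN
        k = math.log(2) / T
        x = np.linspace(5_000, 1_995_000, 200)
        y = -2.0 - 3e-7 * x - 0.10 * (x > 1e6)
        prof = profile_from_arrays(y, np.full_like(x, 1e4), x, T_s=T)
        spec = lt.PiecewiseSpec(
            knots={("sim", "right"): np.array([0.0, 2e6])},
            pauses=[lt.PauseLocus("sim", "right", 1e6, group="p")],
        )
        model = lt.fit_piecewise(prof, spec)
        est = model.pause_estimates(k)
        assert est.dtau.iloc[0] / MIN == pytest.approx(0.10 * T / math.log(2) / MIN)
        assert est.dtau.iloc[0] / MIN == pytest.approx(4.33, abs=0.01)

    def test_two_segment_poisson_recovery(self, two_arm_profile):
        # alpha1 = 0.15/Mb, alpha2 = 0.30/Mb via velocities at fixed k_G
        T = 1800.0
        k = math.log(2) / T
        v1, v2 = k / 0.15e-6, k / 0.30e-6
        profile, _, _ = two_arm_profile(
            {"right": (np.array([0.0, 1e6]), np.array([v1, v2])),
             "left": (np.array([0.0, 1e6]), np.array([v1, v2]))},
            T_s=T, reads=6_000_000, seed=21,
        )
        spec = lt.PiecewiseSpec(
            knots={("sim", a): np.array([0.0, 1e6, 2e6]) for a in ("left", "right")}
        )
        model = lt.fit_piecewise(profile, spec)
        for seg in model.segments.itertuples(index=False):
            truth = 0.15e-6 if seg.lo < 1e6 else 0.30e-6
            assert abs(seg.alpha - truth) < 3 * seg.alpha_se

    def test_step_consistent_with_flanking_prediction(self, two_arm_profile):
        T = 1800.0
        k = math.log(2) / T
        profile, _, _ = two_arm_profile(
            {"left": 1000.0, "right": 1000.0}, T_s=T, reads=2_000_000,
            seed=4, pauses=[("right", 1e6, 200.0)],
        )
        spec = lt.PiecewiseSpec(
            knots={("sim", a): np.array([0.0, 2e6]) for a in ("left", "right")},
            pauses=[lt.PauseLocus("sim", "right", 1e6, group="p")],
        )
        model = lt.fit_piecewise(profile, spec)
        s = model.steps.s.iloc[0]
        eps = 1.0
        jump = (
            model.predict("sim", "right", 1e6 - eps)[0]
            - model.predict("sim", "right", 1e6 + eps)[0]
        )
        alpha = model.segments.alpha.iloc[1]
        assert jump - 2 * eps * alpha == pytest.approx(s, rel=1e-9)
        # and the fitted pause is within 3 SE of the configured 200 s
        est = model.pause_estimates(k)
        assert abs(est.dtau.iloc[0] - 200.0) < 3 * est.dtau_se.iloc[0]

    def test_empty_segment_rejected(self):
        x = np.linspace(5_000, 995_000, 100)
        prof = profile_from_arrays(-2 - 3e-7 * x, np.full_like(x, 1e3), x)
        spec = lt.PiecewiseSpec(
            knots={("sim", "right"): np.array([0.0, 1e6, 3e6])}
        )
        with pytest.raises(ValueError, match="bins"):
            lt.fit_piecewise(prof, spec)

    def test_monotonicity_violation_reported(self):
        x = np.linspace(5_000, 1_995_000, 200)
        y = -2.0 - 3e-7 * x + 6e-7 * np.clip(x - 1e6, 0, None)
        prof = profile_from_arrays(y, np.full_like(x, 1e4), x)
        spec = lt.PiecewiseSpec(
            knots={("sim", "right"): np.array([0.0, 1e6, 2e6])}
        )
        model = lt.fit_piecewise(prof, spec)
        viol = model.monotonicity_violations()
        assert len(viol) == 1 and viol.lo.iloc[0] == 1e6


class TestAIC:
    def test_inert_parameter_costs_two(self):
        x = np.linspace(5_000, 1_995_000, 200)
        y = -2.0 - 3e-7 * x
        prof = profile_from_arrays(y, np.full_like(x, 1e4), x)
        a = lt.fit_piecewise(
            prof, lt.PiecewiseSpec(knots={("sim", "right"): np.array([0.0, 2e6])})
        )
        b = lt.fit_piecewise(
            prof,
            lt.PiecewiseSpec(knots={("sim", "right"): np.array([0.0, 1e6, 2e6])}),
        )
        # noiseless: both interpolate exactly, chi2 identical
        assert lt.aic(b) - lt.aic(a) == pytest.approx(2.0, abs=1e-6)

    def test_null_delta_aic_averages_one(self):
        # an extra truly-zero parameter: E[dAIC] = 2 - E[chi2_1] = 1
        rng = np.random.default_rng(31)
        x = np.linspace(5_000, 1_995_000, 200)
        deltas = []
        for _ in range(200):
            counts = rng.poisson(2000 * np.exp(-3e-7 * x))
            keep = counts >= 10
            prof = profile_from_arrays(
                np.log(counts[keep] / counts[keep].sum()), counts[keep], x[keep]
            )
            a = lt.fit_piecewise(
                prof,
                lt.PiecewiseSpec(knots={("sim", "right"): np.array([0.0, 2e6])}),
            )
            b = lt.fit_piecewise(
                prof,
                lt.PiecewiseSpec(
                    knots={("sim", "right"): np.array([0.0, 1e6, 2e6])}
                ),
            )
            deltas.append(b.aic - a.aic)
        # Var(dAIC) = Var(chi2_1) = 2 -> SE = sqrt(2/200) = 0.1
        assert np.mean(deltas) == pytest.approx(1.0, abs=0.4)


class TestSelectKnotSpacing:
    def test_constant_velocity_prefers_coarse(self, two_arm_profile):
        wins = 0
        for seed in range(10):
            profile, _, _ = two_arm_profile(
                {"left": 1000.0, "right": 1000.0}, reads=2_000_000, seed=100 + seed,
                n_bins=400, bin_length=5000.0,
            )
            model = lt.select_knot_spacing(
                profile, [50_000.0, 100_000.0, 400_000.0]
            )
            wins += model.selected_spacing == 400_000.0
        assert wins >= 8

    def test_aic_table_attached(self, two_arm_profile):
        profile, _, _ = two_arm_profile(
            {"left": 1000.0, "right": 1000.0}, reads=1_000_000, seed=5
        )
        model = lt.select_knot_spacing(profile, [200_000.0, 500_000.0])
        assert len(model.aic_table) == 2
        assert model.aic == model.aic_table.aic.min()

    def test_needs_two_candidates(self, two_arm_profile):
        profile, _, _ = two_arm_profile(
            {"left": 1000.0, "right": 1000.0}, reads=1_000_000, seed=5
        )
        with pytest.raises(ValueError):
            lt.select_knot_spacing(profile, [200_000.0])


class TestComparePauseModels:
    RDNA = [
        lt.PauseLocus("sim", "right", x, name=f"rrn{i}")
        for i, x in enumerate([0.2e6, 0.5e6, 0.8e6, 1.1e6, 1.3e6, 1.5e6, 1.7e6])
    ] + [lt.PauseLocus("sim", "left", 0.9e6, name="rrnL")]

    def test_null_truth_ranking_matches_statistical_oracle(self, two_arm_profile):
        # under Model-1 truth the best-model frequency follows from the
        # chi-square behaviour of the two (near-orthogonal) extra
        # parameters: P(M1 best) ~ P(chi2_1 < 2)^2
        oracle = stats.chi2.cdf(2, 1) ** 2
        n_rep, best1 = 40, 0
        for seed in range(n_rep):
            profile, _, _ = two_arm_profile(
                {"left": 1000.0, "right": 1000.0}, reads=2_000_000,
                seed=300 + seed,
            )
            table = lt.compare_pause_models(profile, self.RDNA)
            best1 += table.model.iloc[0] == 1
        se = math.sqrt(oracle * (1 - oracle) / n_rep)
        assert abs(best1 / n_rep - oracle) < 3.5 * se

    def test_short_pauses_detected_at_depth(self, two_arm_profile):
        # 17 s pauses at 8 loci, T = 64 min, 1e8 reads
        T = 64 * MIN
        k = math.log(2) / T
        pauses = [(p.arm, p.abs_ell, 17.0) for p in self.RDNA]
        profile, _, _ = two_arm_profile(
            {"left": 1000.0, "right": 1000.0}, T_s=T, reads=100_000_000,
            seed=33, pauses=pauses,
        )
        table = lt.compare_pause_models(profile, self.RDNA)
        aic_by_model = table.set_index("model").aic
        assert max(aic_by_model[3], aic_by_model[4]) < min(
            aic_by_model[1], aic_by_model[2]
        )
        best = table.iloc[0]
        assert best.model in (3, 4)
        dtau = best.s / k
        dtau_se = best.s_se / k
        assert abs(dtau - 17.0) < 2 * dtau_se


class TestLikelihoodRatioTest:
    def test_identical_models(self, two_arm_profile):
        profile, _, _ = two_arm_profile(
            {"left": 1000.0, "right": 1000.0}, reads=1_000_000, seed=9
        )
        m = lt.fit_piecewise(profile, lt.PiecewiseSpec.constant(profile.arm_spans))
        res = lt.likelihood_ratio_test(m, m)
        assert res.statistic == 0 and res.p == 1.0

    def test_strong_contrast_underflows_gracefully(self, two_arm_profile):
        vbar = 1000.0
        spec_v = (np.array([0.0, 1e6]), np.array([vbar * 1.3, vbar * 0.7]))
        profile, _, _ = two_arm_profile(
            {"left": spec_v, "right": spec_v}, reads=6_000_000, seed=10
        )
        null = lt.fit_piecewise(
            profile, lt.PiecewiseSpec.constant(profile.arm_spans, slope_sharing="shared")
        )
        full_spec = lt.PiecewiseSpec(
            knots={("sim", a): np.array([0.0, 1e6, 2e6]) for a in ("left", "right")}
        )
        full = lt.fit_piecewise(profile, full_spec)
        res = lt.likelihood_ratio_test(null, full)
        assert res.log10_p < -30
        assert "p <" in str(res) or res.p > 0

    def test_non_nested_rejected(self, two_arm_profile):
        profile, _, _ = two_arm_profile(
            {"left": 1000.0, "right": 1000.0}, reads=1_000_000, seed=9
        )
        a = lt.fit_piecewise(
            profile,
            lt.PiecewiseSpec(
                knots={("sim", a): np.array([0.0, 0.9e6, 2e6]) for a in ("left", "right")}
            ),
        )
        b = lt.fit_piecewise(
            profile,
            lt.PiecewiseSpec(
                knots={("sim", a): np.array([0.0, 1.1e6, 2e6]) for a in ("left", "right")}
            ),
        )
        with pytest.raises(ValueError, match="nested"):
            lt.likelihood_ratio_test(a, b)


class TestResolutionFormulas:
    def test_sigma_tau_scaling_and_anchor(self):
        k = 1e-3
        assert lt.sigma_tau(4e6, k) == pytest.approx(lt.sigma_tau(1e6, k) / 2)
        # 6e6 reads at 1/k_G = 2449 s gives ~1 s resolution
        assert lt.sigma_tau(6e6, 1 / 2449.0) == pytest.approx(1.0, abs=0.001)

    def test_sigma_v_scaling_and_anchor(self):
        kwargs = dict(depth_per_base=1.5, v=1000.0, k_G=1000.0 / 2.74e6)
        r1 = lt.sigma_v_relative(knot_spacing=100_000.0, **kwargs)
        r2 = lt.sigma_v_relative(knot_spacing=50_000.0, **kwargs)
        assert r2 / r1 == pytest.approx(2 ** 1.5)
        assert r1 == pytest.approx(0.1, abs=0.001)

    def test_sigma_tau_monte_carlo(self):
        # Poisson counting noise on a locus with N expected reads
        rng = np.random.default_rng(55)
        k = 1e-3
        N = 100_000
        taus = np.log(N / rng.poisson(N, size=200)) / k
        assert taus.std() == pytest.approx(lt.sigma_tau(N, k), rel=0.2)

    def test_sigma_v_monte_carlo(self):
        # velocity from the lag-time difference of two adjacent knot
        # windows, each integrating n*dl reads
        rng = np.random.default_rng(56)
        k = 1000.0 / 2.74e6
        n, dl, v = 1.5, 100_000.0, 1000.0
        expect = n * dl
        drop = math.exp(-k * dl / v)
        n1 = rng.poisson(expect, size=200)
        n2 = rng.poisson(expect * drop, size=200)
        v_hat = dl * k / np.log(n1 / n2)
        rel = v_hat.std() / v
        assert rel == pytest.approx(
            lt.sigma_v_relative(n, dl, v, k), rel=0.2
        )


class TestLagTimeTable:
    def test_origin_zero_and_knot_values(self, two_arm_profile):
        T = 1800.0
        k = math.log(2) / T
        profile, _, _ = two_arm_profile(
            {"left": 1000.0, "right": 1000.0}, T_s=T, reads=2_000_000,
            seed=61, pauses=[("right", 1e6, 150.0)],
        )
        spec = lt.PiecewiseSpec(
            knots={("sim", a): np.array([0.0, 1e6, 2e6]) for a in ("left", "right")},
            pauses=[lt.PauseLocus("sim", "right", 1e6, group="p")],
        )
        model = lt.fit_piecewise(profile, spec)
        table = model.lag_times(k)
        origin = table[table.position == 0.0]
        assert np.allclose(origin.tau_s, 0.0) and np.allclose(origin.se_s, 0.0)
        # terminus of the pause-free left arm: ~2e6 bp at 1 kb/s
        left_end = table[(table.arm == "left") & (table.position == 2e6)]
        assert left_end.tau_s.iloc[0] == pytest.approx(2000.0, rel=0.02)
        assert left_end.se_s.iloc[0] > 0
        # right arm end carries the extra 150 s pause
        right_end = table[(table.arm == "right") & (table.position == 2e6)]
        assert right_end.tau_s.iloc[0] - left_end.tau_s.iloc[0] == pytest.approx(
            150.0, abs=3 * right_end.se_s.iloc[0]
        )

    def test_diagnostics_residuals_small(self, two_arm_profile):
        profile, _, _ = two_arm_profile(
            {"left": 1000.0, "right": 1000.0}, reads=2_000_000, seed=62
        )
        model = lt.fit_piecewise(
            profile, lt.PiecewiseSpec.constant(profile.arm_spans)
        )
        diag = model.diagnostics(profile)
        assert len(diag) == len(profile.data)
        # chi2 recomputed from the diagnostics table matches the model
        assert float(np.sum(diag.w * diag.residual ** 2)) == pytest.approx(
            model.chi2, rel=1e-9
        )
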