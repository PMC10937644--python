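"""MR estimator tests: closed-form and weighted-least-squares oracles,
robustness properties, MR-PRESSO null/power behaviour, MVMR algebra."""

import numpy as np
import pytest
from sklearn.base import clone

from netmr import (
    IVW,
    HarmonizedSet,
    MREgger,
    MRPRESSO,
    MVMRIVW,
    WeightedMedian,
    cochran_q,
    egger,
    ivw,
    mr_presso,
    mvmr_ivw,
    weighted_median,
)


def hs(bx, by, se_y, se_x=None, k=1):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n = len(by)
    if se_x is None:
        se_x = np.full_like(np.atleast_2d(bx.T).reshape(n, -1), 0.01)
    return HarmonizedSet(
        variant_ids=[f"v{i}" for i in range(n)],
        beta_exposures=bx,
        se_exposures=se_x,
        beta_outcome=by,
        se_outcome=se_y,
        exposure_names=[f"x{j}" for j in range(k)],
    )


class TestIVW:
    def test_single_snp_wald_ratio(self):
        r = ivw(hs([0.1], [0.05], [0.01]))
        assert r.method == "WaldRatio"
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)

    def test_three_snp_fixed_effect_arithmetic(self):
        # sum(w bx by)/sum(w bx^2) = 0.037/0.0725 with equal se_y
        r = ivw(hs([0.1, 0.2, 0.15], [0.05, 0.10, 0.08], [0.01] * 3))
        assert r.estimate == pytest.approx(0.5103448275862069, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        bx = rng.normal(0.1, 0.03, 25)
        se_y = rng.uniform(0.01, 0.05, 25)
        by = 0.4 * bx + rng.normal(0, se_y)
        r = ivw(hs(bx, by, se_y))
        fit = sm.WLS(by, bx[:, None], weights=1 / se_y**2).fit()
        assert r.estimate == pytest.approx(fit.params[0], abs=1e-10)
        # multiplicative random effects: inflate only when Q/df > 1
        q = float(np.sum((1 / se_y**2) * (by - fit.params[0] * bx) ** 2))
        infl = max(1.0, np.sqrt(q / 24))
        se_fixed = float(np.sqrt(1 / np.sum(bx**2 / se_y**2)))
        assert r.se == pytest.approx(se_fixed * infl, abs=1e-12)

    def test_exact_proportionality_gives_zero_heterogeneity(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        r = ivw(hs(bx, 0.7 * bx, [0.01, 0.02, 0.01, 0.03]))
        assert r.estimate == pytest.approx(0.7, abs=1e-12)
        assert r.q_stat == pytest.approx(0.0, abs=1e-20)
        assert r.i2 == 0.0

    def test_equal_se_reduces_to_ols_through_origin(self):
        rng = np.random.default_rng(3)
        bx = rng.normal(0.1, 0.05, 30)
        by = 0.3 * bx + rng.normal(0, 0.01, 30)
        r = ivw(hs(bx, by, np.full(30, 0.02)))
        ols = float(bx @ by / (bx @ bx))
        assert r.estimate == pytest.approx(ols, abs=1e-12)

    def test_all_zero_exposure_unidentified(self):
        with pytest.raises(ValueError, match="unidentified"):
            ivw(hs([0.0, 0.0], [0.1, 0.2], [0.01, 0.01]))


class TestEgger:
    def test_exact_affine_fit(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.01 + 0.5 * bx
        r = egger(hs(bx, by, [0.01] * 4))
        assert r.egger_intercept == pytest.approx(0.01, abs=1e-12)
        assert r.estimate == pytest.approx(0.5, abs=1e-12)
        assert r.q_stat == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_wls_oracle(self):
        import statsmodels.api as sm

        bx = np.array([0.08, -0.12, 0.2, 0.15])
        by = np.array([0.03, -0.07, 0.11, 0.06])
        se_y = np.array([0.01, 0.02, 0.015, 0.01])
        r = egger(hs(bx, by, se_y))
        flip = np.sign(bx)
        X = sm.add_constant(bx * flip)
        fit = sm.WLS(by * flip, X, weights=1 / se_y**2).fit()
        assert r.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert r.estimate == pytest.approx(fit.params[1], abs=1e-10)

    def test_orientation_invariance(self):
        # jointly flipping any (bx, by) pair leaves the fit unchanged
        bx = np.array([0.1, 0.2, 0.15, 0.12])
        by = 0.01 + 0.5 * bx
        se_y = np.array([0.01, 0.02, 0.01, 0.015])
        r1 = egger(hs(bx, by, se_y))
        bx2, by2 = bx.copy(), by.copy()
        bx2[1], by2[1] = -bx2[1], -by2[1]
        r2 = egger(hs(bx2, by2, se_y))
        assert r2.estimate == pytest.approx(r1.estimate, abs=1e-12)
        assert r2.egger_intercept == pytest.approx(r1.egger_intercept, abs=1e-12)

    def test_less_biased_than_ivw_under_directional_pleiotropy(self):
        """200 replicates, 50 SNPs, strong directional pleiotropy: the
        median absolute bias of the Egger slope is below the IVW one."""
        truth = 0.3
        bias_ivw, bias_egger = [], []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            bx_true = rng.uniform(0.05, 0.2, 50)
            se_y = np.full(50, 0.01)
            alpha = rng.normal(0.02, 0.02, 50)  # directional pleiotropy
            by = rng.normal(truth * bx_true + alpha, se_y)
            bx = rng.normal(bx_true, 0.003)
            h = hs(bx, by, se_y)
            bias_ivw.append(abs(ivw(h).estimate - truth))
            bias_egger.append(abs(egger(h).estimate - truth))
        assert np.median(bias_egger) < np.median(bias_ivw)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger(hs([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.4])
        r = weighted_median(hs(bx, 0.5 * bx, [0.01, 0.03, 0.02]), seed=1)
        assert r.estimate == pytest.approx(0.5, abs=1e-12)

    def test_equal_weights_middle_of_odd_set(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.04, 0.05, 0.06])
        r = weighted_median(hs(bx, by, [0.01] * 3), seed=1)
        assert r.estimate == pytest.approx(0.5, abs=1e-12)

    def test_matches_cumulative_weight_oracle(self):
        bx = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        by = np.array([0.04, 0.11, 0.06, 0.14, 0.13])
        se_y = np.array([0.01, 0.02, 0.015, 0.02, 0.01])
        r = weighted_median(hs(bx, by, se_y), seed=1)
        # independent re-implementation of the interpolated weighted median
        ratios = by / bx
        w = bx**2 / se_y**2
        order = np.argsort(ratios)
        ratios, w = ratios[order], w[order]
        cum = (np.cumsum(w) - 0.5 * w) / w.sum()
        below = np.where(cum < 0.5)[0][-1]
        expected = ratios[below] + (ratios[below + 1] - ratios[below]) * (
            0.5 - cum[below]
        ) / (cum[below + 1] - cum[below])
        assert r.estimate == pytest.approx(expected, abs=1e-12)

    def test_duplication_invariance(self):
        bx = np.array([0.1, 0.2, 0.15, 0.3])
        by = np.array([0.04, 0.11, 0.06, 0.14])
        se_y = np.array([0.01, 0.02, 0.015, 0.02])
        single = WeightedMedian._point(bx, by, se_y)
        doubled = WeightedMedian._point(
            np.tile(bx, 2), np.tile(by, 2), np.tile(se_y, 2)
        )
        assert doubled == pytest.approx(single, abs=1e-12)

    def test_zero_exposure_snp_dropped(self):
        bx = np.array([0.0, 0.1, 0.2, 0.15])
        by = np.array([0.9, 0.05, 0.1, 0.07])
        r = weighted_median(hs(bx, by, [0.01] * 4), seed=1)
        assert r.n_snp == 3

    def test_bootstrap_se_reproducible(self):
        bx = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        by = np.array([0.04, 0.11, 0.06, 0.14, 0.13])
        r1 = weighted_median(hs(bx, by, [0.01] * 5), seed=42)
        r2 = weighted_median(hs(bx, by, [0.01] * 5), seed=42)
        assert r1.se == r2.se


class TestMRPRESSO:
    def test_homogeneous_null_rarely_flags(self):
        """All true ratios equal with correct SEs: outliers flagged in at
        most 5% of 200 seeded replicates, global p far from degenerate."""
        flagged = 0
        global_ps = []
        for rep in range(200):
            rng = np.random.default_rng(2000 + rep)
            bx = rng.uniform(0.05, 0.2, 10)
            se_y = np.full(10, 0.01)
            by = rng.normal(0.5 * bx, se_y)
            r = mr_presso(hs(bx, by, se_y), n_sim=1000, seed=rep)
            flagged += bool(r.outliers_removed)
            global_ps.append(r.global_p)
        assert flagged / 200 <= 0.05
        assert 0.3 < np.mean(global_ps) < 0.7  # roughly uniform null p

    def test_outlier_removal_reduces_bias(self):
        rng = np.random.default_rng(77)
        truth = 0.5
        bx = rng.uniform(0.05, 0.2, 20)
        se_y = np.full(20, 0.01)
        by = rng.normal(truth * bx, se_y)
        by[0] += 10 * se_y[0]
        h = hs(bx, by, se_y)
        raw = ivw(h)
        corrected = mr_presso(h, n_sim=1000, seed=5)
        assert "v0" in corrected.outliers_removed
        assert abs(corrected.estimate - truth) < abs(raw.estimate - truth)

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValueError, match="at least 4"):
            mr_presso(hs([0.1, 0.2, 0.15], [0.05, 0.1, 0.07], [0.01] * 3))
        with pytest.raises(ValueError, match="n_sim"):
            mr_presso(
                hs([0.1, 0.2, 0.15, 0.3], [0.05, 0.1, 0.07, 0.15], [0.01] * 4),
                n_sim=10,
            )


class TestCochranQ:
    def test_identical_ratios_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        q, i2 = cochran_q(hs(bx, 0.5 * bx, [0.01] * 3), 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert i2 == 0.0

    def test_unit_weight_arithmetic(self):
        # ratios {0.4, 0.5, 0.6}, unit weights, estimate 0.5 -> Q = 0.02
        bx = np.ones(3)
        by = np.array([0.4, 0.5, 0.6])
        q, _ = cochran_q(hs(bx, by, np.ones(3)), 0.5)
        assert q == pytest.approx(0.02, abs=1e-15)


class TestMVMR:
    def test_exact_linear_algebra(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0.1, 0.05, size=(20, 2))
        by = 0.5 * X[:, 0] - 0.3 * X[:, 1]
        r = mvmr_ivw(hs(X, by, np.full(20, 0.01), se_x=np.full((20, 2), 0.01), k=2))
        np.testing.assert_allclose(r.estimates, [0.5, -0.3], atol=1e-10)

    def test_k1_reduces_to_univariable_ivw(self):
        rng = np.random.default_rng(13)
        bx = rng.normal(0.1, 0.05, 15)
        se_y = rng.uniform(0.01, 0.03, 15)
        by = 0.4 * bx + rng.normal(0, se_y)
        h1 = hs(bx, by, se_y)
        uni = ivw(h1)
        multi = MVMRIVW().fit(bx[:, None], by, se_y)
        assert multi.estimates_[0] == pytest.approx(uni.estimate, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        X = rng.normal(0.1, 0.05, size=(30, 2))
        se_y = rng.uniform(0.01, 0.05, 30)
        by = 0.5 * X[:, 0] - 0.3 * X[:, 1] + rng.normal(0, se_y)
        r = mvmr_ivw(hs(X, by, se_y, se_x=np.full((30, 2), 0.01), k=2))
        fit = sm.WLS(by, X, weights=1 / se_y**2).fit()
        np.testing.assert_allclose(r.estimates, fit.params, atol=1e-10)

    def test_orthogonal_columns_equal_univariable_estimates(self):
        rng = np.random.default_rng(31)
        n = 40
        se_y = rng.uniform(0.01, 0.03, n)
        w = 1 / se_y**2
        x1 = rng.normal(0.1, 0.05, n)
        x2_raw = rng.normal(0.1, 0.05, n)
        x2 = x2_raw - x1 * (np.sum(w * x1 * x2_raw) / np.sum(w * x1**2))
        X = np.column_stack([x1, x2])
        by = 0.5 * x1 - 0.3 * x2 + rng.normal(0, se_y)
        multi = MVMRIVW().fit(X, by, se_y)
        uni1 = IVW().fit(x1, by, se_y)
        uni2 = IVW().fit(x2, by, se_y)
        assert multi.estimates_[0] == pytest.approx(uni1.estimate_, abs=1e-10)
        assert multi.estimates_[1] == pytest.approx(uni2.estimate_, abs=1e-10)

    def test_collinear_exposures_named_in_error(self):
        X = np.column_stack([np.linspace(0.1, 0.3, 10)] * 2)
        with pytest.raises(ValueError, match="rank deficient"):
            MVMRIVW().fit(X, X[:, 0] * 0.5, np.full(10, 0.01))

    def test_recovers_direct_not_total_mediator_effect(self):
        """DAG with mediation: the MVMR coefficient of the mediator recovers
        its direct outcome effect within +/-3 SE in >= 95% of 200 seeded
        replicates — the property that makes the mediation arithmetic valid."""
        from netmr import simulate_sumstats, study_truth

        from conftest import small_dag

        hits = 0
        reps = 200
        b_true = float(small_dag(0).theta_med_to_outcome[0, 0])
        for rep in range(200):
            cfg = small_dag(40_000 + rep, n_snps_per_trait=50)
            tables = simulate_sumstats(cfg)
            med, out = cfg.mediator_names[0], cfg.outcome_names[0]
            X = np.column_stack([tables[med]["beta"], tables["education"]["beta"]])
            se_x = np.column_stack([tables[med]["se"], tables["education"]["se"]])
            m = MVMRIVW().fit(X, tables[out]["beta"].to_numpy(),
                              tables[out]["se"].to_numpy(), se_x=se_x)
            hits += abs(m.estimates_[0] - b_true) <= 3 * m.ses_[0]
        assert hits / reps >= 0.95


class TestSklearnCompat:
    @pytest.mark.parametrize(
        "est",
        [IVW(), MREgger(), WeightedMedian(n_boot=50, random_state=3),
         MRPRESSO(n_sim=1000, random_state=4), MVMRIVW()],
        ids=lambda e: type(e).__name__,
    )
    def test_clone_and_params_round_trip(self, est):
        params = est.get_params()
        cloned = clone(est)
        assert cloned.get_params() == params
        cloned.set_params(**params)
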