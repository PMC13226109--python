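"""Spearman correlation, BH-FDR, standardized OLS and the suite wrapper."""

import numpy as np
import pandas as pd
import pytest

from sleepfusion.assoc import association_suite, bh_fdr, spearman, standardized_ols


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -(x ** 3))[0] == pytest.approx(-1.0)

    def test_hand_computed_rank_example(self):
        # d^2 = (1,1,1,1,0) -> rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-9)

    def test_matches_scipy_with_ties(self, rng):
        from scipy import stats

        for _ in range(50):
            x = rng.integers(0, 8, 30).astype(float)  # heavy ties
            y = rng.integers(0, 8, 30).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y ** 3 + 5 * y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10.0))


class TestBhFdr:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_step_up_enumeration_example(self):
        q = bh_fdr([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04], atol=1e-12)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(2, 20))
            q = bh_fdr(p)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_ref, atol=1e-12)

    def test_q_geq_p_and_monotone(self, rng):
        for _ in range(20):
            p = np.sort(rng.random(15))
            q = bh_fdr(p)
            assert (q >= p - 1e-12).all()
            assert (np.diff(q) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestStandardizedOls:
    def test_exact_linear_fit(self):
        x = np.arange(20.0)
        z = (x - x.mean()) / x.std(ddof=1)
        res = standardized_ols(2.0 * z, x)
        assert res.beta == pytest.approx(1.0, abs=1e-9)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_beta_equals_pearson_for_lone_predictor(self, rng):
        x = rng.normal(size=50)
        y = -0.6 * x + rng.normal(0, 0.8, 50)
        res = standardized_ols(y, x)
        assert res.beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-9)

    def test_recovers_planted_effect(self):
        betas = []
        for seed in range(200):
            gen = np.random.default_rng(seed)
            x = gen.normal(size=44)
            y = -0.5 * x + gen.normal(0, np.sqrt(1 - 0.25), 44)
            betas.append(standardized_ols(y, x).beta)
        assert abs(np.mean(betas) - (-0.5)) < 0.1

    def test_collinear_design_named(self, rng):
        x = rng.normal(size=30)
        cov = pd.DataFrame({"dup": 2.0 * x})
        with pytest.raises(ValueError, match="dup"):
            standardized_ols(rng.normal(size=30), x, covariates=cov)

    def test_binary_covariates_left_unstandardized(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        cov = pd.DataFrame({"sex": rng.integers(0, 2, 40),
                            "age": rng.normal(65, 8, 40)})
        res = standardized_ols(y, x, covariates=cov)
        assert res.covariate_encoding["sex"].startswith("binary")
        assert res.covariate_encoding["age"] == "z-scored"

    def test_matches_normal_equations(self, rng):
        """Full agreement with an independent closed-form solve."""
        for _ in range(20):
            x = rng.normal(size=30)
            age = rng.normal(60, 10, 30)
            y = rng.normal(size=30)
            res = standardized_ols(y, x, pd.DataFrame({"age": age}))

            def z(v):
                return (v - v.mean()) / v.std(ddof=1)

            X = np.column_stack([np.ones(30), z(x), z(age)])
            beta = np.linalg.solve(X.T @ X, X.T @ z(y))
            assert res.beta == pytest.approx(beta[1], abs=1e-9)


class TestAssociationSuite:
    def _cohort(self, seed=0, n=44, rho=-0.5):
        from sleepfusion.synthgen import (
            pearson_for_spearman, simulate_demographics, slope_for_pearson,
        )

        gen = np.random.default_rng(seed)
        rem = np.clip(gen.normal(13, 5, n), 2, 30)
        noise = 2.5
        slope = slope_for_pearson(pearson_for_spearman(rho), rem.std(), noise)
        psqi = 7 + slope * (rem - 13) + gen.normal(0, noise, n)
        ess = 7 + gen.normal(0, noise, n)
        ids = [f"s{i}" for i in range(n)]
        scales = pd.DataFrame({"psqi": psqi, "ess": ess}, index=ids)
        cov = simulate_demographics(n, gen)
        cov.index = pd.Index(ids)
        return pd.Series(rem, index=ids), scales, cov

    def test_recovers_planted_negative_effect(self):
        rem, scales, cov = self._cohort(seed=1)
        report = association_suite(rem, scales, cov)
        psqi = next(c for c in report.correlations if "psqi" in c.pair)
        assert psqi.rho < -0.3
        assert psqi.q < 0.05

    def test_null_scale_not_significant(self):
        rhos = [
            next(
                c.rho
                for c in association_suite(*self._cohort(seed=s)).correlations
                if "ess" in c.pair
            )
            for s in range(20)
        ]
        assert abs(np.mean(rhos)) < 0.15

    def test_family_size_equals_tests_submitted(self):
        rem, scales, cov = self._cohort(seed=2)
        report = association_suite(rem, scales, cov)
        assert len(report.correlations) == scales.shape[1]
        assert len(report.regressions) == scales.shape[1]

    def test_misaligned_ids_listed(self):
        rem, scales, cov = self._cohort(seed=3)
        bad = scales.rename(index={"s0": "zzz"})
        with pytest.raises(ValueError, match="zzz"):
            association_suite(rem, bad, cov)

    def test_q_geq_p(self):
        rem, scales, cov = self._cohort(seed=4)
        for c in association_suite(rem, scales, cov).correlations:
            assert c.q >= c.p - 1e-12
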