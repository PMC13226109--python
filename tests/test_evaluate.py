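"""Epoch metrics, balanced subsets, night summaries and agreement stats."""

import numpy as np
import pytest

from sleepfusion.evaluate import (
    balanced_subset, bland_altman, epoch_metrics, icc_a1, night_summary,
)
from sleepfusion.io import Hypnogram


class TestEpochMetrics:
    def test_perfect_predictions(self):
        labels = np.array([0, 1, 2] * 10)
        m = epoch_metrics(labels, labels)
        np.testing.assert_array_equal(m.precision, 1.0)
        np.testing.assert_array_equal(m.recall, 1.0)
        np.testing.assert_array_equal(m.f1, 1.0)
        assert np.trace(m.confusion) == 30

    def test_hand_tallied_example(self):
        ref = [0, 0, 1, 1, 2, 2]
        pred = [0, 1, 1, 1, 2, 0]
        m = epoch_metrics(ref, pred)
        np.testing.assert_allclose(m.precision, [0.5, 2 / 3, 1.0], atol=1e-9)
        np.testing.assert_allclose(m.recall, [0.5, 1.0, 0.5], atol=1e-9)

    def test_single_class_predictions(self):
        ref = np.array([0, 0, 1, 2])
        pred = np.zeros(4, dtype=int)
        m = epoch_metrics(ref, pred)
        assert m.recall[0] == 1.0
        assert m.recall[1] == 0.0 and m.recall[2] == 0.0
        assert "precision:NREM" in m.undefined

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            epoch_metrics([0, 1], [0])

    def test_confusion_row_sums_equal_support(self, rng):
        ref = rng.integers(0, 3, 500)
        pred = rng.integers(0, 3, 500)
        m = epoch_metrics(ref, pred)
        np.testing.assert_array_equal(m.confusion.sum(axis=1), m.support)
        assert abs(m.accuracy - (ref == pred).mean()) < 1e-12

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        for _ in range(25):
            ref = rng.integers(0, 3, 200)
            pred = rng.integers(0, 3, 200)
            m = epoch_metrics(ref, pred)
            p, r, f, s = precision_recall_fscore_support(
                ref, pred, labels=[0, 1, 2], zero_division=0
            )
            np.testing.assert_allclose(m.precision, p, atol=1e-12)
            np.testing.assert_allclose(m.recall, r, atol=1e-12)
            np.testing.assert_allclose(m.f1, f, atol=1e-12)


class TestBalancedSubset:
    def test_exact_counts(self, rng):
        ref = rng.integers(0, 3, 3000)
        pred = rng.integers(0, 3, 3000)
        sub = balanced_subset(ref, per_class=200, seed=1, predicted=pred)
        assert len(sub["reference"]) == 600
        assert (np.bincount(sub["reference"]) == 200).all()

    def test_pairs_preserved(self, rng):
        ref = rng.integers(0, 3, 900)
        pred = rng.integers(0, 3, 900)
        sub = balanced_subset(ref, per_class=50, seed=2, predicted=pred)
        np.testing.assert_array_equal(sub["reference"], ref[sub["index"]])
        np.testing.assert_array_equal(sub["predicted"], pred[sub["index"]])

    def test_reproducible(self, rng):
        ref = rng.integers(0, 3, 900)
        a = balanced_subset(ref, per_class=10, seed=3)
        b = balanced_subset(ref, per_class=10, seed=3)
        np.testing.assert_array_equal(a["index"], b["index"])

    def test_insufficient_class_named(self):
        ref = np.array([0] * 10 + [1] * 10 + [2] * 2)
        with pytest.raises(ValueError, match="REM"):
            balanced_subset(ref, per_class=3)


class TestNightSummary:
    def test_direct_arithmetic(self):
        labels = np.array([0] * 75 + [1] * 100 + [2] * 25)
        s = night_summary(Hypnogram("s", labels))
        assert s.tst_minutes == 62.5
        assert s.rem_pct == 20.0
        assert s.nrem_pct == 80.0

    def test_all_rem(self):
        s = night_summary(Hypnogram("s", np.full(10, 2)))
        assert s.rem_pct == 100.0 and s.nrem_pct == 0.0

    def test_all_wake_flagged(self):
        s = night_summary(Hypnogram("s", np.zeros(10, dtype=int)))
        assert s.tst_minutes == 0.0
        assert s.undefined_percent
        assert np.isnan(s.rem_pct)

    def test_percentages_sum_to_100(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 3, 200)
            s = night_summary(Hypnogram("s", labels))
            if not s.undefined_percent:
                assert abs(s.rem_pct + s.nrem_pct - 100.0) < 1e-9


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        bias, lo, hi, mae = bland_altman([10, 20, 30], [12, 19, 33])
        sd = np.std([-2, 1, -3], ddof=1)
        np.testing.assert_allclose(bias, -4 / 3, atol=1e-9)
        np.testing.assert_allclose(lo, -4 / 3 - 1.96 * sd, atol=1e-4)
        np.testing.assert_allclose(hi, -4 / 3 + 1.96 * sd, atol=1e-4)
        assert mae == 2.0

    def test_rem_nrem_antisymmetry(self, rng):
        """NREM% = 100 - REM% mirrors the full Bland-Altman report."""
        rem_auto = rng.uniform(5, 30, 20)
        rem_man = rem_auto + rng.normal(0, 0.8, 20)
        b_rem = bland_altman(rem_auto, rem_man)
        b_nrem = bland_altman(100 - rem_auto, 100 - rem_man)
        np.testing.assert_allclose(b_nrem[0], -b_rem[0], atol=1e-9)
        np.testing.assert_allclose(b_nrem[1], -b_rem[3 - 1], atol=1e-9)
        np.testing.assert_allclose(b_nrem[2], -b_rem[1], atol=1e-9)
        np.testing.assert_allclose(b_nrem[3], b_rem[3], atol=1e-9)

    def test_mae_at_least_abs_bias(self, rng):
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            bias, lo, hi, mae = bland_altman(a, b)
            assert mae >= abs(bias) - 1e-12
            assert lo <= bias <= hi

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])


def _icc_bruteforce(auto, manual):
    """Independent two-way ANOVA via explicit cell enumeration."""
    data = np.stack([auto, manual], axis=1)
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (
                data[i, j] - data[i].mean() - data[:, j].mean() + grand
            ) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIcc:
    def test_perfect_agreement(self, rng):
        x = rng.normal(50, 10, 12)
        icc, lo, hi = icc_a1(x, x.copy())
        assert icc == pytest.approx(1.0)

    def test_constant_offset_penalised(self):
        manual = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        icc, _, _ = icc_a1(manual + 5.0, manual)
        assert icc < 1.0
        assert icc == pytest.approx(_icc_bruteforce(manual + 5.0, manual), abs=1e-12)

    def test_independent_noise_near_zero(self):
        # 100-seed average of ICC between independent vectors
        vals = []
        for seed in range(100):
            gen = np.random.default_rng(seed)
            vals.append(icc_a1(gen.normal(size=200), gen.normal(size=200))[0])
        assert abs(np.mean(vals)) < 0.1

    def test_matches_bruteforce_anova(self, rng):
        for _ in range(50):
            a = rng.normal(50, 10, 8)
            b = a + rng.normal(0, 3, 8)
            icc, _, _ = icc_a1(a, b)
            assert icc == pytest.approx(_icc_bruteforce(a, b), abs=1e-9)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        for seed in range(5):
            gen = np.random.default_rng(seed)
            a = gen.normal(20, 6, 15)
            b = a + gen.normal(0, 2, 15)
            icc, lo, hi = icc_a1(a, b)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(15), 2),
                    "raters": ["auto", "manual"] * 15,
                    "scores": np.column_stack([a, b]).reshape(-1),
                }
            )
            ref = pg.intraclass_corr(
                df, targets="targets", raters="raters", ratings="scores"
            )
            row = ref[ref["Type"].str.contains("A,1|ICC2")].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-9)
            # pingouin rounds its CI to two decimals
            np.testing.assert_allclose([lo, hi], row["CI95"], atol=6e-3)

    def test_degenerate_table_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc_a1(np.full(6, 3.0), np.full(6, 3.0))
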