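import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from extinctrl.psychophys import (
    block_average,
    correct_rating_table,
    correct_scr_table,
    differential,
    exclude_incomplete,
    group_test,
    holm_correct,
    log_range_correct,
    pearson_correlation,
    range_correct_rating,
    reinstatement_contrast,
)


class TestLogRangeCorrect:
    def test_hand_computed_example(self):
        out = log_range_correct([0.2, 0.4, 0.8])
        expected = [math.log1p(v) / math.log1p(0.8) for v in (0.2, 0.4, 0.8)]
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, [0.3101, 0.5724, 1.0], atol=2e-4)

    def test_all_zero_day(self):
        np.testing.assert_array_equal(log_range_correct([0.0, 0.0]), [0.0, 0.0])

    def test_max_is_one(self):
        rng = np.random.default_rng(0)
        out = log_range_correct(rng.uniform(0.01, 3.0, 40))
        assert out.max() == pytest.approx(1.0, abs=1e-15)
        assert np.all((out >= 0) & (out <= 1))

    def test_order_preserved(self):
        rng = np.random.default_rng(1)
        amp = rng.uniform(0, 5, 30)
        out = log_range_correct(amp)
        rho = stats.spearmanr(amp, out).statistic
        assert rho == pytest.approx(1.0)

    def test_missing_propagates(self):
        out = log_range_correct([0.5, np.nan, 1.0])
        assert np.isnan(out[1]) and out[2] == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_range_correct([-0.1, 0.5])


class TestRangeCorrectRating:
    def test_simple(self):
        np.testing.assert_allclose(range_correct_rating([50.0, 100.0]), [0.5, 1.0])

    def test_self_normalisation(self):
        np.testing.assert_allclose(range_correct_rating([20.0, 20.0]), [1.0, 1.0])

    def test_degenerate_zeros(self):
        np.testing.assert_array_equal(range_correct_rating([0.0, 0.0]), [0.0, 0.0])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            range_correct_rating([50.0, 101.0])


class TestTables:
    def test_scr_table_grouping(self):
        df = pd.DataFrame(
            dict(
                subject=["s1"] * 4 + ["s2"] * 2,
                day=[1, 1, 2, 2, 1, 1],
                trial_index=[1, 2, 1, 2, 1, 2],
                cs_type=["CS_PLUS", "CS_MINUS"] * 3,
                value=[0.2, 0.4, 0.1, 0.3, 1.0, 2.0],
            )
        )
        out = correct_scr_table(df)
        # each subject-day is normalised independently
        for (_, _), idx in df.groupby(["subject", "day"]).groups.items():
            assert out.loc[idx, "corrected"].max() == pytest.approx(1.0)

    def test_rating_table(self):
        df = pd.DataFrame(
            dict(
                subject=["s1", "s1"], day=[1, 1], trial_index=[1, 2],
                cs_type=["CS_PLUS", "CS_MINUS"], value=[40.0, 80.0],
            )
        )
        out = correct_rating_table(df)
        np.testing.assert_allclose(out["corrected"], [0.5, 1.0])

    def test_exclude_incomplete(self):
        df = pd.DataFrame(
            dict(
                subject=["s1"] * 6 + ["s2"] * 6,
                day=[1] * 12,
                trial_index=list(range(6)) * 2,
                cs_type=["CS_PLUS"] * 12,
                value=[1.0] * 6 + [np.nan, np.nan, np.nan, 1.0, 1.0, 1.0],
            )
        )
        kept = exclude_incomplete(df, max_missing_frac=1 / 3)
        assert set(kept["subject"]) == {"s1"}


class TestBlockAverage:
    def test_constant(self):
        np.testing.assert_allclose(block_average([0.5] * 24), [0.5, 0.5, 0.5])

    def test_step(self):
        vals = [1.0] * 8 + [0.0] * 16
        np.testing.assert_allclose(block_average(vals), [1.0, 0.0, 0.0])

    def test_loop_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=24)
        expected = [np.mean(vals[i * 8 : (i + 1) * 8]) for i in range(3)]
        np.testing.assert_allclose(block_average(vals), expected, atol=1e-12)

    def test_missing_ignored(self):
        vals = np.array([1.0, np.nan] * 4 + [np.nan] * 8 + [0.0] * 8)
        out = block_average(vals)
        assert out[0] == 1.0 and np.isnan(out[1]) and out[2] == 0.0

    def test_partial_block_flagged(self):
        with pytest.warns(UserWarning, match="partial"):
            out = block_average(np.ones(20), block_size=8)
        assert out.size == 3

    def test_bad_block_size(self):
        with pytest.raises(ValueError):
            block_average([1.0], block_size=0)


class TestDifferential:
    def test_identical_series(self):
        np.testing.assert_array_equal(differential([0.4, 0.4], [0.4, 0.4]), [0, 0])

    def test_simple(self):
        np.testing.assert_allclose(differential([0.9], [0.3]), [0.6])

    def test_loop_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(2, 30))
        np.testing.assert_allclose(
            differential(a, b), [x - y for x, y in zip(a, b)], atol=1e-15
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            differential([1.0], [1.0, 2.0])


class TestReinstatementContrast:
    def test_hand_arithmetic(self):
        c = reinstatement_contrast(
            pre_csplus=[0.5] * 8, pre_csminus=[0.5] * 8,
            post_csplus=[0.2, 0.4, 0.6, 0.0], post_csminus=[0.1, 0.1, 0.1, 0.0],
            k=3,
        )
        assert c.post_csplus == pytest.approx(0.4)
        assert c.post_differential == pytest.approx(0.3)

    def test_identical_pre_post(self):
        # pre uses the LAST 3 trials, post the FIRST 3
        series = [0.3, 0.2, 0.5, 0.4]
        c = reinstatement_contrast(series, series, series, series, k=3)
        assert c.pre_csplus == pytest.approx(np.mean(series[-3:]))
        assert c.post_csplus == pytest.approx(np.mean(series[:3]))
        symmetric = [0.3, 0.2, 0.3]
        c2 = reinstatement_contrast(symmetric, symmetric, symmetric, symmetric, k=3)
        assert c2.pre_csplus == pytest.approx(c2.post_csplus)

    def test_k_one_boundary_trials(self):
        c = reinstatement_contrast([0.1, 0.9], [0.2, 0.3], [0.7, 0.0], [0.4, 0.0], k=1)
        assert c.pre_csplus == 0.9 and c.post_csplus == 0.7
        assert c.pre_csminus == 0.3 and c.post_csminus == 0.4

    def test_block_mode(self):
        c = reinstatement_contrast(
            np.arange(8.0), np.zeros(8), np.arange(8.0) + 1, np.zeros(8), k=8
        )
        assert c.pre_csplus == pytest.approx(3.5)
        assert c.post_csplus == pytest.approx(4.5)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            reinstatement_contrast([1.0], [1.0], [1.0], [1.0], k=3)


class TestGroupTest:
    def test_identical_groups(self):
        res = group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_cohens_d_hand_computed(self):
        res = group_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.cohens_d == pytest.approx(-1.0)

    def test_one_sided_direction(self):
        a, b = [0.0, 0.1, 0.2], [1.0, 1.1, 1.2]
        assert group_test(a, b, sided="less").p < 0.05
        assert group_test(a, b, sided="greater").p > 0.5

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            group_test(rng.normal(size=20), rng.normal(size=20)).p < 0.05
            for _ in range(1000)
        )
        assert 0.035 <= rejections / 1000 <= 0.065

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            group_test([1.0], [1.0, 2.0])


def test_holm_correction():
    adj = holm_correct([0.01, 0.04, 0.03])
    np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
    assert np.all(adj >= [0.01, 0.04, 0.03])


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, x)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_t_and_p_consistent_with_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        res = pearson_correlation(x, y)
        r, p = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r)
        assert res.p == pytest.approx(p, rel=1e-10)
        assert res.t == pytest.approx(r * math.sqrt(23 / (1 - r**2)))
        assert res.ci_low < res.r < res.ci_high

    def test_simulation_mean_r(self):
        # at rho = 0.5, E[r] ~= rho - rho(1-rho^2)/(2(n-1)) ~= 0.495 for n=40
        rng = np.random.default_rng(13)
        rho, n, reps = 0.5, 40, 500
        cov = [[1, rho], [rho, 1]]
        rs = np.empty(reps)
        for i in range(reps):
            x, y = rng.multivariate_normal([0, 0], cov, size=n).T
            rs[i] = pearson_correlation(x, y).r
        se = rs.std(ddof=1) / math.sqrt(reps)
        expected = rho - rho * (1 - rho**2) / (2 * (n - 1))
        assert abs(rs.mean() - expected) < 3 * se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, np.inf, 3.0], [1.0, 2.0, 3.0])
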