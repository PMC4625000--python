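"""Paired t, Pearson r, RM-ANOVA, standardized alpha, scale scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import screenuse as su
from helpers import anova_ss_oracle, paired_t_oracle, pearson_oracle


class TestPairedT:
    def test_identical_vectors(self):
        res = su.paired_t([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_shift_gives_infinite_t(self):
        res = su.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.mean_diff == -1.0
        assert res.t == -math.inf and res.p == 0.0

    def test_sign_convention_and_df(self):
        res = su.paired_t([3.0, 4.0, 6.0], [1.0, 2.0, 1.0])
        assert res.df == 2
        assert np.sign(res.t) == np.sign(res.mean_diff) == 1

    def test_too_few_pairs(self):
        with pytest.raises(su.ValidationError):
            su.paired_t([1.0], [2.0])

    def test_matches_formula_and_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = x + rng.normal(0.3, 1.0, size=n)
            res = su.paired_t(x, y)
            assert res.t == pytest.approx(paired_t_oracle(x, y), rel=1e-10)
            ref = sps.ttest_rel(x, y)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_nan_pairs_dropped(self):
        res = su.paired_t([1.0, 2.0, np.nan, 4.0], [0.0, 1.0, 5.0, 2.0])
        assert res.n == 3


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = su.pearson(x, 2 * x + 1)
        assert res.r == 1.0 and res.df == 8

    def test_zero_variance_is_error(self):
        with pytest.raises(su.ValidationError):
            su.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_independent_permutation_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=4000)
        res = su.pearson(x, rng.permutation(x))
        assert abs(res.r) < 0.05

    def test_matches_covariance_oracle_and_scipy(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            res = su.pearson(x, y)
            assert res.r == pytest.approx(pearson_oracle(list(x), list(y)), rel=1e-12)
            ref = sps.pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestRmAnova:
    def test_no_condition_effect(self):
        mat = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        res = su.rm_anova_one_way(mat)
        assert res.F == 0.0 and res.partial_eta_sq == 0.0

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 30))
            k = int(rng.integers(2, 6))
            mat = rng.normal(size=(n, k)) + rng.normal(size=(1, k))
            res = su.rm_anova_one_way(mat)
            F, df_e, df_r, eta = anova_ss_oracle(mat)
            assert res.F == pytest.approx(F, rel=1e-9)
            assert (res.df_effect, res.df_error) == (df_e, df_r)
            assert res.partial_eta_sq == pytest.approx(eta, rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(19)
        mat = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        long = mat.reset_index().melt(
            id_vars="index", var_name="cond", value_name="y"
        )
        ref = pg.rm_anova(
            data=long, dv="y", within="cond", subject="index", detailed=True
        )
        res = su.rm_anova_one_way(mat)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)
        ss_cond, ss_err = float(ref["SS"].iloc[0]), float(ref["SS"].iloc[1])
        assert res.partial_eta_sq == pytest.approx(
            ss_cond / (ss_cond + ss_err), rel=1e-9
        )

    def test_df_structure_for_27_subjects_4_levels(self):
        rng = np.random.default_rng(23)
        res = su.rm_anova_one_way(rng.normal(size=(27, 4)))
        assert (res.df_effect, res.df_error) == (3, 78)

    def test_invariance_under_constant_shift_and_rescale(self):
        rng = np.random.default_rng(29)
        mat = rng.normal(size=(10, 4))
        base = su.rm_anova_one_way(mat)
        shifted = su.rm_anova_one_way(mat + 7.5)
        scaled = su.rm_anova_one_way(mat * 3.0)
        assert shifted.F == pytest.approx(base.F, rel=1e-9)
        assert scaled.partial_eta_sq == pytest.approx(base.partial_eta_sq, rel=1e-9)

    def test_lsd_pairwise_are_uncorrected_paired_t(self):
        rng = np.random.default_rng(31)
        mat = pd.DataFrame(rng.normal(size=(9, 3)), columns=["m", "a", "e"])
        res = su.rm_anova_one_way(mat)
        assert len(res.pairwise) == 3
        for a, b, p in res.pairwise:
            assert p == pytest.approx(su.paired_t(mat[a], mat[b]).p, rel=1e-12)

    def test_incomplete_matrix_rejected(self):
        mat = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(su.ValidationError):
            su.rm_anova_one_way(mat)


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        rng = np.random.default_rng(37)
        col = rng.normal(size=50)
        items = np.tile(col[:, None], (1, 27))
        assert su.cronbach_alpha_standardized(items) == pytest.approx(1.0)

    def test_two_item_closed_form(self):
        rng = np.random.default_rng(41)
        x = rng.normal(size=400)
        y = 0.5 * x + math.sqrt(1 - 0.25) * rng.normal(size=400)
        items = np.column_stack([x, y])
        r = su.pearson(x, y).r
        expected = 2 * r / (1 + r)
        assert su.cronbach_alpha_standardized(items) == pytest.approx(expected)

    def test_zero_variance_item_named(self):
        items = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(su.ValidationError, match="0"):
            su.cronbach_alpha_standardized(items)


class TestMppusScoring:
    @staticmethod
    def _responses(totals):
        rows = []
        for i, total in enumerate(totals):
            base, rem = divmod(total, 27)
            items = [base + 1] * rem + [base] * (27 - rem)
            rows.append([f"P{i:02d}", *items])
        return pd.DataFrame(
            rows, columns=["participant_id", *(f"item_{j:02d}" for j in range(1, 28))]
        )

    def test_strictly_greater_boundary(self):
        scores = su.mppus_score_and_flag(
            self._responses([140, 141]), norm_mean=100.0, norm_sd=20.0
        )
        assert scores["problem_flag"].tolist() == [False, True]

    def test_totals_are_item_sums(self):
        scores = su.mppus_score_and_flag(
            self._responses([135, 27]), norm_mean=100.0, norm_sd=20.0
        )
        assert scores["total"].tolist() == [135, 27]

    def test_missing_norms_rejected(self):
        with pytest.raises(su.ConfigError):
            su.mppus_score_and_flag(self._responses([100]), None, None)


class TestComparisonMatrix:
    @staticmethod
    def _summaries(actual_uses, actual_dur):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i:02d}" for i in range(len(actual_uses))],
                "mean_daily_uses": actual_uses,
                "mean_total_daily_duration_h": actual_dur,
            }
        )

    @staticmethod
    def _reports(est_uses, est_dur):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i:02d}" for i in range(len(est_uses))],
                "estimated_daily_uses": est_uses,
                "estimated_daily_duration_h": est_dur,
            }
        )

    def test_identical_estimates_give_unit_correlation(self):
        uses = [10.0, 20.0, 30.0, 40.0]
        dur = [1.0, 2.0, 3.0, 4.0]
        tables = su.comparison_matrix(
            self._summaries(uses, dur), self._reports(uses, dur)
        )
        assert tables.correlation("estimated_uses", "actual_uses").r == pytest.approx(
            1.0
        )
        assert tables.correlation(
            "estimated_duration", "actual_duration"
        ).r == pytest.approx(1.0)

    def test_symmetric_lookup(self):
        rng = np.random.default_rng(43)
        tables = su.comparison_matrix(
            self._summaries(rng.normal(50, 10, 10), rng.normal(5, 1, 10)),
            self._reports(rng.normal(40, 10, 10), rng.normal(4, 1, 10)),
        )
        ab = tables.correlation("actual_uses", "estimated_duration")
        ba = tables.correlation("estimated_duration", "actual_uses")
        assert ab.r == ba.r

    def test_insufficient_pairs_reported_unavailable(self):
        tables = su.comparison_matrix(
            self._summaries([10.0, 20.0], [1.0, 2.0]),
            self._reports([12.0, 21.0], [1.2, 2.2]),
        )
        assert tables.correlations["r"].isna().all()

    def test_paired_tests_present_with_df(self):
        rng = np.random.default_rng(47)
        tables = su.comparison_matrix(
            self._summaries(rng.normal(85, 20, 24), rng.normal(5, 1, 24)),
            self._reports(rng.normal(37, 15, 24), rng.normal(4, 1, 24)),
        )
        assert tables.paired_tests["uses"].df == 23
        assert tables.paired_tests["duration"].n == 24
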