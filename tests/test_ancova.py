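"""Quade rank ANCOVA, adjusted means, trend test, covariate imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nordicdiet as nd
from nordicdiet.ancova import (
    adjusted_means,
    impute_covariates,
    quade_ancova,
    quartile_groups,
    trend_test,
)

from conftest import QUADE_FIXTURE_F, QUADE_FIXTURE_P, make_quade_fixture


class TestQuartileGroups:
    def test_uniform_scores_give_near_equal_groups(self):
        scores = np.repeat(np.arange(2, 26), 4)  # 24 levels x 4
        labels = quartile_groups(scores)
        sizes = np.bincount(labels)[1:]
        assert sizes.sum() == len(scores)
        assert sizes.max() - sizes.min() <= len(scores) // 4

    def test_heavy_ties_share_a_group(self):
        scores = [1, 2, 3] + [10] * 8 + [20, 21, 22, 23, 24]
        labels = quartile_groups(scores)
        assert len(set(labels[3:11])) == 1  # the eight tied scores share a group
        sizes = np.bincount(labels)[1:]
        assert len(set(sizes[sizes > 0])) > 1  # unequal quartile sizes

    def test_labels_monotone_in_score(self):
        scores = np.random.default_rng(1).integers(2, 26, size=200)
        labels = quartile_groups(scores)
        order = np.argsort(scores)
        assert (np.diff(labels[order]) >= 0).all()

    def test_all_equal_scores_degenerate_downstream(self):
        scores = [12] * 20
        labels = quartile_groups(scores)
        assert len(set(labels)) == 1
        df = pd.DataFrame({"hpl_total": np.random.default_rng(0).random(20)})
        with pytest.raises(ValueError, match="degenerate"):
            quade_ancova(df, labels, covariate_set=())


class TestQuadeAncova:
    def test_matches_brute_force_oracle(self):
        df, g = make_quade_fixture()
        F, p, df_fp = quade_ancova(df, g, covariate_set=("cov",))
        assert F == pytest.approx(QUADE_FIXTURE_F, rel=1e-12)
        assert p == pytest.approx(QUADE_FIXTURE_P, rel=1e-12)
        assert df_fp == (3, 12)

    def test_no_covariates_equals_anova_on_ranks(self):
        # independent oracle: scipy one-way ANOVA on the rank-transformed outcome
        rng = np.random.default_rng(8)
        y = rng.poisson(2.0, size=12).astype(float)
        g = np.repeat([1, 2, 3], 4)
        df = pd.DataFrame({"hpl_total": y})
        F, p, _ = quade_ancova(df, g, covariate_set=())
        ranks = stats.rankdata(y)
        F_ref, p_ref = stats.f_oneway(*(ranks[g == k] for k in (1, 2, 3)))
        assert F == pytest.approx(F_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_identical_group_multisets_give_zero_F(self):
        block = pd.DataFrame({"hpl_total": [1.0, 2.0, 3.0, 4.0], "cov": [5.0, 6.0, 7.0, 8.0]})
        df = pd.concat([block, block], ignore_index=True)
        g = np.repeat([1, 2], 4)
        F, p, _ = quade_ancova(df, g, covariate_set=("cov",))
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_outcome_degenerate(self):
        df = pd.DataFrame({"hpl_total": [2.0] * 8, "cov": np.arange(8.0)})
        with pytest.raises(ValueError, match="constant"):
            quade_ancova(df, np.repeat([1, 2], 4), covariate_set=("cov",))

    def test_collinear_ranked_covariates_named(self):
        df = pd.DataFrame({
            "hpl_total": np.random.default_rng(0).random(12),
            "a": np.arange(12.0), "b": np.arange(12.0) * 2,  # identical ranks
        })
        with pytest.raises(ValueError, match="rank-deficient"):
            quade_ancova(df, np.repeat([1, 2, 3], 4), covariate_set=("a", "b"))

    def test_invariant_to_monotone_outcome_transforms(self):
        df, g = make_quade_fixture()
        F0, p0, _ = quade_ancova(df, g, covariate_set=("cov",))
        for transform in (np.exp, lambda v: 3.0 * v - 7.0):
            df2 = df.assign(hpl_total=transform(df["hpl_total"].to_numpy()))
            F, p, _ = quade_ancova(df2, g, covariate_set=("cov",))
            assert F == pytest.approx(F0, rel=1e-12)
            assert p == pytest.approx(p0, rel=1e-12)

class TestAdjustedMeans:
    @staticmethod
    def _simulated(n, rng, offsets=(0.4, 0.2, 0.1, 0.0)):
        g = rng.integers(1, 5, size=n)
        cov = rng.normal(size=n)  # independent of group
        y = np.asarray(offsets)[g - 1] + 0.5 * cov + rng.normal(size=n)
        return pd.DataFrame({"hpl_total": y, "cov": cov}), g

    def test_orthogonal_covariates_reduce_to_raw_means(self):
        rng = np.random.default_rng(5)
        n = 400
        g = np.repeat([1, 2, 3, 4], n // 4)
        cov = np.tile(np.arange(n // 4), 4).astype(float)  # identical per group
        y = rng.normal(size=n) + 0.3 * (g == 1)
        df = pd.DataFrame({"hpl_total": y, "cov": cov})
        table, diff, ci, p = adjusted_means(df, g, covariate_set=("cov",))
        raw = pd.Series(y).groupby(g).mean()
        np.testing.assert_allclose(table["adj_mean"].to_numpy(), raw.to_numpy(), atol=1e-10)

    def test_textbook_single_covariate_formula(self):
        # classic ANCOVA: adj mean_g = ybar_g - b_w (xbar_g - xbar), with the
        # pooled within-group slope b_w; computed here from first principles
        df, g = make_quade_fixture()
        y, x = df["hpl_total"].to_numpy(), df["cov"].to_numpy()
        num = den = 0.0
        for k in np.unique(g):
            sel = g == k
            num += ((x[sel] - x[sel].mean()) * (y[sel] - y[sel].mean())).sum()
            den += ((x[sel] - x[sel].mean()) ** 2).sum()
        b_w = num / den
        expected = [y[g == k].mean() - b_w * (x[g == k].mean() - x.mean()) for k in np.unique(g)]
        table, *_ = adjusted_means(df, g, covariate_set=("cov",))
        np.testing.assert_allclose(table["adj_mean"].to_numpy(), expected, atol=1e-10)

    def test_known_offsets_recovered_at_scale(self):
        rng = np.random.default_rng(17)
        df, g = self._simulated(20_000, rng)
        table, diff, ci, p = adjusted_means(df, g, covariate_set=("cov",))
        se = (ci[1] - ci[0]) / (2 * 1.96)
        assert diff == pytest.approx(0.4, abs=3 * se)
        assert ci[0] < diff < ci[1]

    def test_extreme_diff_antisymmetric_under_label_reversal(self):
        df, g = make_quade_fixture()
        _, diff, ci, _ = adjusted_means(df, g, covariate_set=("cov",))
        _, diff_r, ci_r, _ = adjusted_means(df, 5 - g, covariate_set=("cov",))
        assert diff_r == pytest.approx(-diff, rel=1e-10)
        assert ci_r[0] == pytest.approx(-ci[1], rel=1e-10)


class TestTrendTest:
    def test_perfect_linear_trend_detected(self):
        g = np.repeat([1, 2, 3, 4], 10)
        y = g * 2.0 + np.random.default_rng(0).normal(scale=0.01, size=40)
        df = pd.DataFrame({"hpl_total": y})
        p = trend_test(df, g, covariate_set=())
        assert p < 1e-20

    def test_null_rejection_rate(self):
        """Permuted labels: ~5% rejections at alpha=0.05 over 1000 replicates."""
        rng = np.random.default_rng(77)
        n, reps, rejections = 400, 1000, 0
        g_base = np.repeat([1, 2, 3, 4], n // 4)
        for _ in range(reps):
            df = pd.DataFrame({
                "hpl_total": rng.exponential(2.0, size=n), "c1": rng.normal(size=n),
            })
            p = trend_test(df, rng.permutation(g_base), covariate_set=("c1",))
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_power_on_simulated_monotone_effect(self):
        rng = np.random.default_rng(19)
        df, g = TestAdjustedMeans._simulated(20_000, rng)
        assert trend_test(df, g, covariate_set=("cov",)) < 1e-3


class TestImputeCovariates:
    @staticmethod
    def _cohort(**overrides):
        base = {
            "ltpa_kj": [100.0, 200.0, np.nan],
            "marital": ["couple", "couple", "other"],
            "age": [42, 48, 54], "exam_year": [1984, 1985, 1986],
            "energy_kj": [9000.0, 9500.0, 9800.0], "ses": [8.0, 9.0, 7.0],
            "smoking": ["never", "current", "previous"],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_ltpa_mean_imputation(self):
        out, counts = impute_covariates(self._cohort())
        assert out.loc[2, "ltpa_kj"] == pytest.approx(150.0)
        assert counts == {"ltpa_kj": 1, "marital": 0}

    def test_marital_mode_imputation(self):
        df = self._cohort(
            ltpa_kj=[100.0, 200.0, 300.0, 400.0],
            marital=["couple", "couple", "other", np.nan],
            age=[42, 48, 54, 60], exam_year=[1984, 1985, 1986, 1987],
            energy_kj=[9000.0] * 4, ses=[8.0] * 4,
            smoking=["never", "never", "current", "previous"],
        )
        out, counts = impute_covariates(df)
        assert out.loc[3, "marital"] == "couple"
        assert counts == {"ltpa_kj": 0, "marital": 1}

    def test_no_missing_is_identity(self):
        df = self._cohort(ltpa_kj=[100.0, 200.0, 300.0])
        out, counts = impute_covariates(df)
        pd.testing.assert_frame_equal(out, df)
        assert counts == {"ltpa_kj": 0, "marital": 0}

    def test_unruled_missing_covariate_rejected(self):
        df = self._cohort(ses=[8.0, np.nan, 7.0])
        with pytest.raises(ValueError, match="ses"):
            impute_covariates(df)
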