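"""Statistical battery: elementary tests, ANCOVA, mixed ANOVA, Tukey,
regression, outliers — each checked against an independent route."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from interorsa.stats import (
    ancova,
    bonferroni_threshold,
    fisher_rz_compare,
    independent_t_test,
    mahalanobis_outliers,
    mixed_anova,
    pearson,
    reciprocal_normalize,
    shapiro_wilk,
    simple_regression,
    spearman,
    tukey_hsd,
)
from interorsa.synth import synth_proxemics_cells


class TestTTest:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        t, df, p = independent_t_test(x, y)
        # brute-force pooled formula
        sp2 = ((19) * x.var(ddof=1) + (24) * y.var(ddof=1)) / 43
        t_ref = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 20 + 1 / 25))
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == 43
        ref = st.ttest_ind(x, y)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_samples(self):
        t, _, p = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == 1

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate samples"):
            independent_t_test([0.0, 0.0], [1.0, 1.0])


class TestShapiro:
    def test_normal_quantiles_near_one(self):
        q = st.norm.ppf(np.linspace(0.01, 0.99, 50))
        W, p = shapiro_wilk(q)
        assert W > 0.99

    def test_skewed_rejected(self):
        _, p = shapiro_wilk([1, 1, 1, 1, 100])
        assert p < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])


class TestCorrelations:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_spearman_is_pearson_on_midranks(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        x[3] = x[4]  # force ties
        mine = spearman(x, y)
        rx, ry = st.rankdata(x), st.rankdata(y)
        assert mine.r == pytest.approx(pearson(rx, ry).r, abs=0)
        ref = st.spearmanr(x, y)
        assert mine.r == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert spearman(np.exp(x), y).r == pytest.approx(spearman(x, y).r)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherRZ:
    def test_closed_form(self):
        z = fisher_rz_compare(0.5, 20, -0.5, 20)
        expected = 2 * np.arctanh(0.5) / np.sqrt(2 / 17)
        assert z.z == pytest.approx(expected)
        assert round(z.z, 2) == 3.20

    def test_antisymmetry(self):
        a = fisher_rz_compare(0.37, 24, -0.21, 30)
        b = fisher_rz_compare(-0.21, 30, 0.37, 24)
        assert a.z == -b.z

    def test_identical_correlations(self):
        assert fisher_rz_compare(0.4, 20, 0.4, 20).z == 0

    def test_invalid(self):
        with pytest.raises(ValueError, match="transform undefined"):
            fisher_rz_compare(1.0, 20, 0.4, 20)


def test_bonferroni():
    assert bonferroni_threshold(0.05, 2) == 0.025
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.01, 4) == 0.0025


class TestAncova:
    @staticmethod
    def _cohort(n=60, gap=2.0, beta=0.3, seed=5):
        rng = np.random.default_rng(seed)
        g = np.repeat(["A", "B"], n // 2)
        age = rng.normal(25, 5, n)
        y = gap * (g == "B") + beta * age + rng.normal(0, 1, n)
        return pd.DataFrame({"y": y, "group": g, "age": age, "flat": 1.0})

    def test_constant_covariate_reduces_to_anova(self):
        df = self._cohort()
        with pytest.warns(UserWarning, match="constant"):
            res = ancova(df, "y", "group", ["flat"])
        f_anova = st.f_oneway(df.y[df.group == "A"], df.y[df.group == "B"]).statistic
        assert res.table.loc["group", "F"] == pytest.approx(f_anova, abs=1e-9)

    def test_recovers_planted_gap(self):
        df = self._cohort(gap=2.0)
        res = ancova(df, "y", "group", ["age"])
        mm = res.marginal_means.set_index("group")
        diff = mm.loc["B", "adjusted_mean"] - mm.loc["A", "adjusted_mean"]
        se = np.hypot(mm.loc["A", "se"], mm.loc["B", "se"])
        assert abs(diff - 2.0) < 2 * se

    def test_marginal_means_equal_raw_means_in_balanced_design(self):
        # identical covariate values in both groups: adjustment changes nothing
        age = np.tile([20.0, 25.0, 30.0, 35.0], 2)
        g = np.repeat(["A", "B"], 4)
        y = np.array([1, 2, 3, 4, 3, 4, 5, 6], dtype=float)
        df = pd.DataFrame({"y": y, "group": g, "age": age})
        res = ancova(df, "y", "group", ["age"])
        mm = res.marginal_means.set_index("group")["adjusted_mean"]
        assert mm["A"] == pytest.approx(y[:4].mean())
        assert mm["B"] == pytest.approx(y[4:].mean())

    def test_rank_deficient(self):
        df = self._cohort()
        df["age2"] = df["age"]
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova(df, "y", "group", ["age", "age2"])


class TestMixedAnova:
    # Reference F values for the seed-42, n=12/group planted-interaction
    # dataset, computed with R: aov(reactivity ~ bmi*distance*gaze*group
    # + Error(subject/(bmi*distance*gaze))).
    R_REFERENCE = {
        "group": 0.067,
        "bmi": 20.680,
        "bmi x group": 3.757,
        "distance": 6.330,
        "distance x group": 7.406,
        "gaze": 7.245,
        "gaze x group": 10.796,
        "bmi x distance": 2.725,
        "bmi x distance x group": 19.275,
        "bmi x gaze": 5.624,
        "bmi x gaze x group": 19.601,
        "distance x gaze": 11.450,
        "distance x gaze x group": 4.999,
        "bmi x distance x gaze": 1.087,
        "bmi x distance x gaze x group": 1.727,
    }

    @pytest.fixture(scope="class")
    def cells(self):
        df, _ = synth_proxemics_cells(rng=42, n_per_group=12)
        return df

    def test_matches_r_aov(self, cells):
        res = mixed_anova(cells, "reactivity", ["bmi", "distance", "gaze"], "group", "subject")
        got = dict(zip(res["effect"], res["F"]))
        for effect, f_ref in self.R_REFERENCE.items():
            assert got[effect] == pytest.approx(f_ref, abs=2e-3), effect
        assert (res["df_num"] == 1).all()
        assert (res["df_den"] == 22).all()

    def test_null_data_all_zero_f(self):
        rows = []
        for s in range(6):
            for b in "tb":
                for d in "fn":
                    for g in "gn":
                        rows.append(
                            {
                                "subject": s,
                                "group": "A" if s < 3 else "B",
                                "bmi": b,
                                "distance": d,
                                "gaze": g,
                                "y": 1.0,
                            }
                        )
        res = mixed_anova(pd.DataFrame(rows), "y", ["bmi", "distance", "gaze"], "group", "subject")
        assert np.allclose(res["F"], 0.0)

    def test_subject_relabeling_invariance(self, cells):
        res1 = mixed_anova(cells, "reactivity", ["bmi", "distance", "gaze"], "group", "subject")
        relabeled = cells.copy()
        relabeled["subject"] = "X" + relabeled["subject"]
        res2 = mixed_anova(relabeled, "reactivity", ["bmi", "distance", "gaze"], "group", "subject")
        np.testing.assert_allclose(res1["F"], res2["F"])

    def test_missing_cell_reported(self, cells):
        broken = cells.iloc[:-1]
        with pytest.raises(ValueError, match="incomplete design"):
            mixed_anova(broken, "reactivity", ["bmi", "distance", "gaze"], "group", "subject")

    def test_planted_interaction_power(self):
        """The 4-way interaction is detected in >= 80% of replicates at the
        generator's planted effect size (n = 24/group)."""
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            df, _ = synth_proxemics_cells(rng=20_000 + i, n_per_group=24)
            res = mixed_anova(df, "reactivity", ["bmi", "distance", "gaze"], "group", "subject")
            row = res[res["effect"] == "bmi x distance x gaze x group"]
            hits += float(row["p"].iloc[0]) < 0.05
        assert hits / n_rep >= 0.80


class TestTukey:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(1, 1, 10), rng.normal(0.5, 1, 10)]
        )
        return pd.DataFrame({"y": vals, "cell": np.repeat(["a", "b", "c"], 10)})

    def test_matches_statsmodels(self, toy):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        mine = tukey_hsd(toy, "y", "cell")
        ref = pairwise_tukeyhsd(toy["y"], toy["cell"])
        np.testing.assert_allclose(mine["p"], ref.pvalues, atol=2e-3)

    def test_matches_direct_studentized_range(self, toy):
        mine = tukey_hsd(toy, "y", "cell")
        groups = {c: g["y"].to_numpy() for c, g in toy.groupby("cell")}
        mse = np.mean([g.var(ddof=1) for g in groups.values()])
        for _, row in mine.iterrows():
            q = abs(row["diff"]) / np.sqrt(mse / 10)
            p = st.studentized_range.sf(q, 3, 27)
            assert row["p"] == pytest.approx(p, abs=1e-12)


class TestTransformsRegressionOutliers:
    def test_reciprocal(self):
        assert reciprocal_normalize(100.0) == pytest.approx(0.01)
        d = np.array([50.0, 100.0, 200.0])
        out = reciprocal_normalize(d)
        assert np.all(np.diff(out) < 0)
        with pytest.raises(ValueError, match="invalid distance"):
            reciprocal_normalize(0.0)

    def test_regression_identities(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = -0.5 * x + rng.normal(0, 0.8, 30)
        res = simple_regression(y, x)
        r = pearson(x, y).r
        assert res.b == pytest.approx(r, abs=1e-12)
        assert res.r2 == pytest.approx(r**2, abs=1e-12)
        assert res.F == pytest.approx(res.t**2, abs=1e-9)

    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = simple_regression(x, x)
        assert res.b == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError, match="degenerate predictor"):
            simple_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_constructed_outlier_flagged(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        X.iloc[7] = [12.0, -12.0]
        flags = mahalanobis_outliers(X, alpha=0.001)
        assert flags.iloc[7]
        assert flags.sum() == 1

    def test_chi_square_calibration(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        assert 0 <= int(mahalanobis_outliers(X, alpha=0.001).sum()) <= 5

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        A = np.array([[2.0, 0.5], [-1.0, 3.0]])
        Y = pd.DataFrame(X.to_numpy() @ A.T + [5.0, -3.0], columns=["a", "b"])
        np.testing.assert_array_equal(
            mahalanobis_outliers(X, 0.01).to_numpy(),
            mahalanobis_outliers(Y, 0.01).to_numpy(),
        )

    def test_singular_covariance(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="singular covariance"):
            mahalanobis_outliers(X)
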