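"""Association statistics: chi-square, ANCOVA + Tukey, normality gate.

The chi-square worked examples reproduce the twelve published association
statistics of the four-cohort ALS subtyping study from its demographic
table (no continuity correction, 2 x k category-vs-complement tables; the
van Rheenen onset comparison is the direct limb-vs-bulbar 2 x 3 table).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alssubtypes.cohort_tables import (BINARY_COUNTS, CLUSTER_SIZES,
                                       VAN_RHEENEN_ONSET)
from alssubtypes.phenotype import (ContingencyTable, ancova_oneway,
                                   build_binary_table,
                                   categorical_association_tests,
                                   chi_square_independence, normality_gate,
                                   tukey_hsd)

PUBLISHED_CHI2 = [
    ("male", "kcl", 0.43),
    ("c9_positive", "kcl", 4.24),
    ("bulbar_onset", "kcl", 0.18),
    ("limb_and_bulbar_onset", "kcl", 0.95),
    ("male", "targetals", 2.48),
    ("c9_positive", "targetals", 3.45),
    ("limb_onset", "targetals", 13.49),
    ("bulbar_onset", "targetals", 20.10),
    ("limb_and_bulbar_onset", "targetals", 3.25),
    ("male", "zucca", 2.02),
    ("male", "van_rheenen", 0.88),
]


class TestChiSquare:
    @pytest.mark.parametrize("category,cohort,expected", PUBLISHED_CHI2)
    def test_published_statistics_reproduced(self, category, cohort,
                                             expected):
        table = build_binary_table(BINARY_COUNTS[category][cohort],
                                   CLUSTER_SIZES[cohort], category=category)
        res = chi_square_independence(table)
        assert round(res.statistic, 2) == pytest.approx(expected, abs=0.005)

    def test_published_limb_bulbar_ratio_reproduced(self):
        table = ContingencyTable(
            observed=np.array([VAN_RHEENEN_ONSET["limb"],
                               VAN_RHEENEN_ONSET["bulbar"]]),
            row_labels=["limb", "bulbar"],
            col_labels=["c1", "c2", "c3"])
        res = chi_square_independence(table)
        assert round(res.statistic, 2) == 1.78
        assert res.p_value == pytest.approx(0.41, abs=0.005)

    def test_homogeneous_table_gives_null(self):
        table = ContingencyTable(observed=np.full((2, 2), 10.0),
                                 row_labels=["a", "b"],
                                 col_labels=["x", "y"])
        res = chi_square_independence(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_expected_margins_conserved(self):
        table = build_binary_table((7, 1, 0), (60, 28, 24))
        res = chi_square_independence(table)
        assert np.allclose(res.expected.sum(axis=0),
                           table.observed.sum(axis=0), atol=1e-9)
        assert np.allclose(res.expected.sum(axis=1),
                           table.observed.sum(axis=1), atol=1e-9)

    def test_permutation_invariance(self, rng):
        obs = rng.integers(1, 30, size=(3, 4)).astype(float)
        t1 = ContingencyTable(obs, list("abc"), list("wxyz"))
        perm_r, perm_c = rng.permutation(3), rng.permutation(4)
        t2 = ContingencyTable(obs[np.ix_(perm_r, perm_c)], list("abc"),
                              list("wxyz"))
        assert (chi_square_independence(t1).statistic
                == pytest.approx(chi_square_independence(t2).statistic))

    def test_zero_marginal_rejected(self):
        table = build_binary_table((10, 5), (10, 5))
        with pytest.raises(ValueError):
            chi_square_independence(table)


class TestBuildBinaryTable:
    def test_complement_row(self):
        table = build_binary_table((7, 1, 0), (60, 28, 24))
        assert table.observed[1].tolist() == [53.0, 27.0, 24.0]

    def test_zero_positives(self):
        table = build_binary_table((0, 0), (5, 9))
        assert table.observed[1].tolist() == [5.0, 9.0]

    def test_positives_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            build_binary_table((10, 3), (5, 9))


def _brute_force_f(y, clusters, cov):
    """Normal-equations oracle for the cluster-factor F statistic."""
    levels = np.unique(clusters)
    dummies = np.column_stack([(clusters == lv).astype(float)
                               for lv in levels[1:]])
    Xf = np.column_stack([np.ones(len(y)), dummies, cov])
    Xr = np.column_stack([np.ones(len(y)), cov])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return r @ r

    rf, rr = rss(Xf), rss(Xr)
    df1 = len(levels) - 1
    df2 = len(y) - Xf.shape[1]
    return ((rr - rf) / df1) / (rf / df2)


class TestAncova:
    def test_matches_brute_force_oracle_on_toy(self):
        y = np.array([3.1, 2.9, 4.2, 5.0, 4.8, 5.3, 7.1, 6.8, 7.4, 2.2,
                      5.1, 6.9])
        clusters = np.array([1, 1, 2, 2, 2, 2, 3, 3, 3, 1, 2, 3])
        cov = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
                       dtype=float)[:, None]
        res = ancova_oneway(y, clusters, covariates=pd.DataFrame(cov))
        expected = _brute_force_f(y, clusters, cov)
        assert res.f_statistic == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(3)
        frame = pd.DataFrame({
            "y": rng.normal(size=90),
            "g": np.repeat(["a", "b", "c"], 30),
            "x": rng.normal(size=90),
        })
        fit = ols("y ~ C(g) + x", data=frame).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        res = ancova_oneway(frame["y"].to_numpy(), frame["g"].to_numpy(),
                            covariates=frame[["x"]])
        assert res.f_statistic == pytest.approx(anova.loc["C(g)", "F"],
                                                rel=1e-8)
        assert res.p_value == pytest.approx(anova.loc["C(g)", "PR(>F)"],
                                            rel=1e-6)

    def test_no_cluster_effect_gives_zero_f(self):
        # identical within-cluster value patterns: the cluster dummies
        # explain exactly nothing
        pattern = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.tile(pattern, 3)
        clusters = np.repeat([1, 2, 3], 4)
        res = ancova_oneway(y, clusters)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_noise_covariate_barely_moves_f(self):
        rng = np.random.default_rng(11)
        n = 300
        clusters = rng.integers(1, 4, size=n)
        y = clusters * 1.0 + rng.normal(0, 1, n)
        plain = ancova_oneway(y, clusters)
        noisy = ancova_oneway(y, clusters,
                              covariates=pd.DataFrame(
                                  {"z": rng.normal(size=n)}))
        assert abs(noisy.f_statistic - plain.f_statistic) \
            < 0.1 * plain.f_statistic

    def test_rank_deficient_design_rejected(self):
        y = np.arange(8.0)
        clusters = np.repeat([1, 2], 4)
        cov = pd.DataFrame({"dup": (clusters == 2).astype(float)})
        with pytest.raises(np.linalg.LinAlgError):
            ancova_oneway(y, clusters, covariates=cov)

    def test_listwise_deletion_of_missing(self):
        y = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0])
        clusters = np.repeat([1, 2], 4)
        res = ancova_oneway(y, clusters)
        assert res.df_den == 7 - 2  # n=7 after deletion, 2 parameters


class TestTukey:
    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        y = np.concatenate([a, b])
        g = np.repeat([1, 2], [20, 25])
        res = ancova_oneway(y, g)
        _, t_p = stats.ttest_ind(a, b)
        assert res.tukey_p[(1, 2)] == pytest.approx(t_p, abs=1e-6)

    def test_identical_means_give_p_one(self):
        means = {1: 5.0, 2: 5.0, 3: 5.0}
        sizes = {1: 10, 2: 10, 3: 10}
        p = tukey_hsd(means, sizes, residual_variance=2.0, df_resid=27)
        assert all(v >= 0.999 for v in p.values())

    def test_p_monotone_in_mean_difference(self):
        sizes = {1: 15, 2: 15}
        last = 1.1
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            p = tukey_hsd({1: 0.0, 2: delta}, sizes, 1.0, 28)[(1, 2)]
            assert p <= last + 1e-12
            last = p

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({1: 0.0}, {1: 5}, 1.0, 4)


class TestNormalityGate:
    def test_normal_sample_kept_at_nominal_rate(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(400):
            try:
                _, decision = normality_gate(rng.normal(size=200))
            except ValueError:
                # normality rejected and the log transform refused the
                # negative values: still a rejection of normality
                decision = "log"
            rejections += decision == "log"
        assert rejections / 400 < 0.10  # type-I error near alpha = 0.05

    def test_lognormal_sample_transformed_and_repaired(self):
        rng = np.random.default_rng(1)
        repaired = 0
        for _ in range(40):
            x = np.exp(rng.normal(size=200))
            out, decision = normality_gate(x)
            assert decision == "log"
            if stats.shapiro(out).pvalue >= 0.05:
                repaired += 1
        assert repaired >= 38  # >= 95% of reps

    def test_nonpositive_values_refuse_silent_shift(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(size=100))
        x[0] = -1.0
        x[1] = 5000.0  # force rejection of normality
        with pytest.raises(ValueError, match="positive"):
            normality_gate(x)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            normality_gate(np.full(10, 3.0))


def test_categorical_tests_run_on_generated_phenotypes(small_discovery):
    _, pheno = small_discovery
    out = categorical_association_tests(pheno,
                                        pheno["cluster"].to_numpy())
    assert {"male", "c9_positive"} <= set(out["category"])
    assert np.all((out["p_value"] >= 0) & (out["p_value"] <= 1))
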