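import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mariabands.errors import (
    DegenerateInputError,
    EmptyGroupError,
    SingularCovarianceError,
)
from mariabands.stats import (
    ANALYSIS_VARIABLES,
    anova_oneway,
    build_separation_report,
    compare_schemes,
    cv_percent,
    da_contributions,
    describe_group,
    homogeneity_percent,
    lda_homogeneity,
    mahalanobis_matrix,
    manova_wilks,
    pairwise_markers,
    round_half_away,
    t_confidence_interval,
)


def rand_groups(rng, sizes=(12, 15, 10), p=5, shift=2.0):
    """Random multivariate groups with increasing means."""
    return [rng.normal(loc=shift * i, scale=1.0, size=(n, p))
            for i, n in enumerate(sizes)]


class TestDescriptives:
    def test_matches_independent_formulas(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        d = describe_group(values)
        assert d.mean == pytest.approx(values.mean())
        assert d.sd == pytest.approx(values.std(ddof=1))
        assert d.cv == pytest.approx(100 * d.sd / d.mean)
        # adjusted Fisher-Pearson G1 / excess G2, explicit moment oracle
        n = len(values)
        m2 = ((values - values.mean()) ** 2).mean()
        m3 = ((values - values.mean()) ** 3).mean()
        m4 = ((values - values.mean()) ** 4).mean()
        g1 = m3 / m2 ** 1.5
        G1 = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        g2 = m4 / m2 ** 2 - 3
        G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        assert d.skewness == pytest.approx(G1)
        assert d.kurtosis == pytest.approx(G2)
        assert d.normality_p == pytest.approx(sps.shapiro(values).pvalue)

    def test_ci_from_summary_stats(self):
        lo, hi = t_confidence_interval(3.38, 0.37, 5)
        assert round_half_away(lo) == 2.92
        assert round_half_away(hi) == 3.84
        assert round_half_away(cv_percent(3.38, 0.37)) == 10.95

    def test_constant_vector_degenerate(self):
        d = describe_group([4.0, 4.0, 4.0])
        assert d.degenerate
        assert d.sd == 0 and d.cv == 0
        assert d.ci_low == d.ci_high == 4.0
        assert d.skewness is None and d.normality_p is None

    def test_small_n_flags(self):
        d2 = describe_group([1.0, 2.0])
        assert d2.skewness is None and d2.kurtosis is None
        d3 = describe_group([1.0, 2.0, 4.0])
        assert d3.skewness is not None and d3.kurtosis is None

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroupError):
            describe_group([])

    def test_invariant_min_mean_max(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = rng.normal(10, 3, size=rng.integers(4, 30))
            d = describe_group(v)
            assert d.minimum <= d.mean <= d.maximum
            assert d.ci_low < d.mean < d.ci_high


class TestManova:
    def test_identical_group_means_lambda_one(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(10, 3))
        lam, F, _, p = manova_wilks([g, g.copy(), g.copy()])
        assert lam == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_one_variable_reduces_to_anova_f(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(i, 1, size=(8, 1)) for i in range(3)]
        lam, F, (df1, df2), p = manova_wilks(groups)
        F_aov, p_aov = anova_oneway([g.ravel() for g in groups])
        assert F == pytest.approx(F_aov)
        assert p == pytest.approx(p_aov)
        assert (df1, df2) == (2, 21)

    def test_determinant_ratio_oracle(self):
        """Explicit det(W)/det(W+B) on a fixed small dataset."""
        groups = [
            np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0]]),
            np.array([[4.0, 5.0], [5.0, 4.0], [6.0, 6.0]]),
            np.array([[8.0, 9.0], [9.0, 8.0], [10.0, 10.0]]),
        ]
        lam, *_ = manova_wilks(groups)
        grand = np.vstack(groups).mean(0)
        W = np.zeros((2, 2))
        T = np.zeros((2, 2))
        for g in groups:
            W += (g - g.mean(0)).T @ (g - g.mean(0))
        allx = np.vstack(groups)
        T = (allx - grand).T @ (allx - grand)
        assert lam == pytest.approx(np.linalg.det(W) / np.linalg.det(T))

    def test_matches_statsmodels_wilks(self):
        statsmodels = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(7)
        groups = rand_groups(rng, p=4)
        lam, F, (df1, df2), p = manova_wilks(groups)
        endog = np.vstack(groups)
        labels = np.repeat([0, 1, 2], [len(g) for g in groups])
        exog = pd.get_dummies(labels, drop_first=False).to_numpy(float)
        mv = statsmodels.MANOVA(endog, exog)
        table = mv.mv_test(
            hypotheses=[("group", np.array([[1, -1, 0], [0, 1, -1]]))]
        ).results["group"]["stat"]
        row = table.loc["Wilks' lambda"]
        assert lam == pytest.approx(float(row["Value"]), rel=1e-8)
        assert F == pytest.approx(float(row["F Value"]), rel=1e-6)
        assert p == pytest.approx(float(row["Pr > F"]), abs=1e-9)

    def test_singular_scatter_informative_error(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 1))
        groups = [np.hstack([base, 2 * base]),
                  np.hstack([base + 1, 2 * base + 2]),
                  np.hstack([base + 2, 2 * base + 4])]
        with pytest.raises(SingularCovarianceError, match="variable"):
            manova_wilks(groups)

    def test_lambda_decreases_with_added_offset(self):
        rng = np.random.default_rng(4)
        groups = rand_groups(rng, shift=0.5)
        lam0, *_ = manova_wilks(groups)
        shifted = [g.copy() for g in groups]
        shifted[2] = shifted[2] + 1.5
        lam1, *_ = manova_wilks(shifted)
        assert 0 < lam1 < lam0 <= 1


class TestAnova:
    def test_equal_group_means_f_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        F, p = anova_oneway([g, g + 0.0, g.copy()])
        assert F == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 9)
        F, p = anova_oneway([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t.statistic ** 2)
        assert p == pytest.approx(t.pvalue)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(i, 1, size=10) for i in range(3)]
        F, p = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_within_variance_flagged_infinite(self):
        F, p = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(F) and p == 0.0


class TestMarkers:
    def test_full_separation_pattern(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(1, 0.5, 10), rng.normal(5, 0.5, 10),
                  rng.normal(20, 0.5, 10)]
        assert pairwise_markers(groups) == ("", "*1", "*2")

    def test_all_equal_no_markers(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 15) for _ in range(3)]
        assert pairwise_markers(groups) == ("", "", "")

    def test_only_extreme_group_shifted(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 20)
        groups = [base, rng.normal(0, 1, 20), rng.normal(10, 1, 20)]
        assert pairwise_markers(groups) == ("", "", "*2")

    def test_markers_follow_value_order_not_group_order(self):
        """ADC-style variable: the highest mean sits in the first group."""
        rng = np.random.default_rng(10)
        groups = [rng.normal(20, 0.5, 10), rng.normal(5, 0.5, 10),
                  rng.normal(1, 0.5, 10)]
        assert pairwise_markers(groups) == ("*2", "*1", "")


class TestMahalanobis:
    def test_identical_means_zero(self):
        rng = np.random.default_rng(11)
        g = rng.normal(size=(20, 4))
        D = mahalanobis_matrix([g, g + 0.0])
        assert D[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_euclidean_reduction_identity_covariance(self):
        """Pooled covariance built to equal I: D is plain Euclidean."""
        s = np.sqrt(1.5)
        block = s * np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        a = block + np.array([0.0, 0.0])
        b = block + np.array([3.0, 4.0])
        S_pool_df = 2 * 4 - 2
        W = 2 * (block.T @ block)
        np.testing.assert_allclose(W / S_pool_df, np.eye(2), atol=1e-12)
        D = mahalanobis_matrix([a, b])
        assert D[0, 1] == pytest.approx(5.0)

    def test_solve_based_oracle(self):
        rng = np.random.default_rng(12)
        groups = rand_groups(rng, sizes=(9, 11, 8), p=3)
        D = mahalanobis_matrix(groups)
        N = sum(len(g) for g in groups)
        W = sum((g - g.mean(0)).T @ (g - g.mean(0)) for g in groups)
        S = W / (N - 3)
        for a in range(3):
            for b in range(3):
                diff = groups[a].mean(0) - groups[b].mean(0)
                expected = np.sqrt(diff @ np.linalg.solve(S, diff))
                assert D[a, b] == pytest.approx(expected)

    def test_symmetry_zero_diagonal_nonnegative(self):
        rng = np.random.default_rng(13)
        D = mahalanobis_matrix(rand_groups(rng))
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0)
        assert np.all(D >= 0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(14)
        groups = rand_groups(rng, p=4)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4)
        transformed = [g @ A.T + b for g in groups]
        np.testing.assert_allclose(mahalanobis_matrix(groups),
                                   mahalanobis_matrix(transformed), atol=1e-8)

    def test_one_dimensional_reduction(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, (15, 1))
        b = rng.normal(3, 1, (12, 1))
        D = mahalanobis_matrix([a, b])
        s_pooled = np.sqrt(
            (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 25)
        assert D[0, 1] == pytest.approx(abs(a.mean() - b.mean()) / s_pooled)

    def test_squared_flag(self):
        rng = np.random.default_rng(16)
        groups = rand_groups(rng)
        D = mahalanobis_matrix(groups)
        D2 = mahalanobis_matrix(groups, squared=True)
        np.testing.assert_allclose(D ** 2, D2, atol=1e-10)


class TestHomogeneity:
    def test_published_arithmetic(self):
        assert homogeneity_percent(61, 63) == 96.83
        assert homogeneity_percent(12, 14) == 85.71

    def test_perfect_separation_hundred_percent(self):
        rng = np.random.default_rng(17)
        groups = rand_groups(rng, shift=25.0)
        for n_correct, n_total, pct in lda_homogeneity(groups):
            assert n_correct == n_total and pct == 100.0

    def test_matches_sklearn_lda_resubstitution(self):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(18)
        groups = rand_groups(rng, shift=1.5)
        X = np.vstack(groups)
        y = np.repeat([0, 1, 2], [len(g) for g in groups])
        clf = sklearn_da.LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
        pred = clf.fit(X, y).predict(X)
        ours = lda_homogeneity(groups)
        for gi in range(3):
            assert ours[gi][0] == int(np.sum(pred[y == gi] == gi))

    def test_scale_invariance(self):
        rng = np.random.default_rng(19)
        groups = rand_groups(rng, shift=1.0)
        scaled = [g * np.array([100.0, 1.0, 0.01, 1.0, 5.0]) for g in groups]
        assert lda_homogeneity(groups) == lda_homogeneity(scaled)


class TestContributions:
    def test_informative_variable_dominates(self):
        rng = np.random.default_rng(20)
        sizes = (15, 15, 15)
        info = [rng.normal(10 * i, 1, (n, 1)) for i, n in enumerate(sizes)]
        noise = [rng.normal(0, 1, (n, 1)) for n in sizes]
        groups = [np.hstack([a, b]) for a, b in zip(info, noise)]
        contrib = da_contributions(groups)
        assert contrib[0] > 95

    def test_symmetric_variables_split_evenly(self):
        rng = np.random.default_rng(21)
        groups = []
        for i, n in enumerate((30, 30, 30)):
            col = rng.normal(3 * i, 1, (n, 1))
            col2 = rng.normal(3 * i, 1, (n, 1))
            groups.append(np.hstack([col, col2]))
        contrib = da_contributions(groups)
        assert contrib[0] == pytest.approx(50, abs=12)

    def test_sum_exactly_100_and_reorder_invariant(self):
        rng = np.random.default_rng(22)
        groups = rand_groups(rng)
        contrib = da_contributions(groups)
        assert contrib.sum() == pytest.approx(100, abs=1e-9)
        perm = [3, 0, 4, 1, 2]
        permuted = da_contributions([g[:, perm] for g in groups])
        np.testing.assert_allclose(permuted, contrib[perm], atol=1e-9)

    def test_sums_of_squares_oracle(self):
        groups = [
            np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]]),
            np.array([[4.0, 5.5], [5.0, 6.5], [6.0, 7.5]]),
        ]
        contrib = da_contributions(groups)
        allx = np.vstack(groups)
        ratios = []
        for j in range(2):
            grand = allx[:, j].mean()
            ssb = sum(len(g) * (g[:, j].mean() - grand) ** 2 for g in groups)
            ssw = sum(((g[:, j] - g[:, j].mean()) ** 2).sum() for g in groups)
            ratios.append(ssb / ssw)
        expected = 100 * np.array(ratios) / sum(ratios)
        np.testing.assert_allclose(contrib, expected)

    def test_zero_within_variance_rejected(self):
        groups = [np.array([[1.0, 1.0], [2.0, 1.0]]),
                  np.array([[3.0, 2.0], [4.0, 2.0]])]
        with pytest.raises(DegenerateInputError):
            da_contributions(groups)


def _report_from_random(rng, scheme="threshold", shift=2.0):
    frame = pd.DataFrame(
        np.vstack(rand_groups(rng, shift=shift)), columns=ANALYSIS_VARIABLES)
    labels = np.repeat([0, 1, 2], [12, 15, 10])
    return build_separation_report(frame, labels, scheme=scheme,
                                   index_kind="maria")


class TestReportAndComparison:
    def test_report_is_complete_and_consistent(self):
        rng = np.random.default_rng(23)
        rep = _report_from_random(rng)
        assert rep.group_sizes == (12, 15, 10)
        assert 0 < rep.wilks_lambda <= 1
        assert sum(rep.contributions.values()) == pytest.approx(100)
        assert set(rep.anova) == set(ANALYSIS_VARIABLES)
        M = np.asarray(rep.mahalanobis)
        np.testing.assert_allclose(M, M.T)

    def test_identical_reports_ratio_one(self):
        rng = np.random.default_rng(24)
        rep = _report_from_random(rng)
        cmp_ = compare_schemes(rep, rep)
        for row in cmp_["pairs"]:
            assert row["ratio"] == pytest.approx(1.0)
        assert not cmp_["b_larger_in_all_pairs"]

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(25)
        frame = pd.DataFrame(
            np.vstack(rand_groups(rng)), columns=ANALYSIS_VARIABLES)
        labels = np.repeat([0, 1, 1], [12, 15, 10])  # class 2 empty -> only 2 bands
        labels[0] = 2  # declare 3 bands but leave band 2 a singleton of size 1
        rep = build_separation_report(frame, labels, "x", "maria")
        assert rep.group_sizes[2] == 1  # singleton tolerated, tests degrade
        bad = np.repeat([0, 1, 2], [0, 22, 15])
        with pytest.raises(Exception):
            build_separation_report(frame, bad, "x", "maria")

    def test_mismatched_cohorts_rejected(self):
        rng = np.random.default_rng(26)
        rep_a = _report_from_random(rng)
        frame = pd.DataFrame(np.vstack(rand_groups(rng, sizes=(5, 6, 7))),
                             columns=ANALYSIS_VARIABLES)
        labels = np.repeat([0, 1, 2], [5, 6, 7])
        rep_b = build_separation_report(frame, labels, "y", "maria")
        with pytest.raises(ValueError, match="different size"):
            compare_schemes(rep_a, rep_b)
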