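"""Canonical discriminant analysis and ANOVA letter display."""

import numpy as np
import pytest
from scipy import stats

import hsicolor as h

#: Published canonical eigenvalues of the casing-treatment analysis.
TABLE_EIGENVALUES = (0.43, 0.09)


def _three_groups(rng, n=30, sep=4.0):
    means = np.array([[56.8, 6.2, 20.3],
                      [56.8 - sep, 7.1, 19.8],
                      [56.8 - sep, 5.7, 20.3 - sep / 2]])
    X = np.vstack([rng.normal(m, 1.5, size=(n, 3)) for m in means])
    groups = np.repeat(["control", "treatment1", "treatment2"], n)
    return X, groups


class TestWilksLambda:
    def test_function1_printed_value(self):
        assert round(h.wilks_lambda(TABLE_EIGENVALUES, 1), 2) == 0.64

    def test_function2_printed_value(self):
        assert round(h.wilks_lambda(TABLE_EIGENVALUES, 2), 2) == 0.92

    def test_no_discrimination_gives_one(self):
        assert h.wilks_lambda([0.0, 0.0], 1) == 1.0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k must"):
            h.wilks_lambda([0.4], 2)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            h.wilks_lambda([-0.1], 1)


class TestCanonicalCorrelation:
    @pytest.mark.parametrize("lam,expected", [(0.43, 0.55), (0.09, 0.29)])
    def test_printed_values(self, lam, expected):
        assert round(h.canonical_correlation(lam), 2) == expected

    def test_zero_eigenvalue(self):
        assert h.canonical_correlation(0.0) == 0.0

    def test_strictly_increasing_and_bounded(self):
        lams = np.linspace(0, 50, 200)
        rs = [h.canonical_correlation(l) for l in lams]
        assert all(a < b for a, b in zip(rs, rs[1:]))
        assert rs[-1] < 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            h.canonical_correlation(-0.5)


class TestFitCDA:
    def test_three_groups_three_variables_two_functions(self, rng):
        X, groups = _three_groups(rng)
        result = h.fit_cda(X, groups)
        assert result.n_functions == 2

    def test_eigenvalues_match_bruteforce_scatter_oracle(self, rng):
        """Small fixture against explicit Sw/Sb matrices solved with a
        plain (non-symmetric) eigendecomposition of Sw⁻¹Sb."""
        X = np.array([
            [55.0, 6.0, 20.0], [57.0, 6.5, 21.0], [56.0, 5.8, 19.5],
            [50.0, 7.0, 19.0], [51.5, 7.4, 20.0], [50.5, 6.8, 18.5],
            [52.0, 5.5, 17.0], [51.0, 5.9, 18.0], [53.0, 5.2, 17.5],
        ])
        groups = ["c"] * 3 + ["t1"] * 3 + ["t2"] * 3
        result = h.fit_cda(X, groups)
        # oracle: accumulate scatter matrices by direct summation
        grand = X.mean(axis=0)
        Sw = np.zeros((3, 3))
        Sb = np.zeros((3, 3))
        for g in ("c", "t1", "t2"):
            Xg = X[[i for i, gg in enumerate(groups) if gg == g]]
            mg = Xg.mean(axis=0)
            for row in Xg:
                Sw += np.outer(row - mg, row - mg)
            Sb += len(Xg) * np.outer(mg - grand, mg - grand)
        lam_oracle = np.sort(np.real(np.linalg.eigvals(np.linalg.solve(Sw, Sb))))[::-1][:2]
        np.testing.assert_allclose(result.eigenvalues, lam_oracle, atol=1e-10)

    def test_variance_pct_sums_to_100(self, rng):
        X, groups = _three_groups(rng)
        result = h.fit_cda(X, groups)
        assert result.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_wilks_consistent_with_eigenvalues(self, rng):
        X, groups = _three_groups(rng)
        result = h.fit_cda(X, groups)
        expected = np.prod(1.0 / (1.0 + result.eigenvalues))
        assert result.wilks[0] == pytest.approx(expected, abs=1e-12)

    def test_lightness_dominates_when_only_L_separates(self, rng):
        """Groups differing only in L*: the standardized L* coefficient
        of function 1 dominates."""
        n = 60
        X = np.vstack([
            np.column_stack([rng.normal(57, 1.0, n), rng.normal(6, 1.0, n),
                             rng.normal(20, 1.0, n)]),
            np.column_stack([rng.normal(50, 1.0, n), rng.normal(6, 1.0, n),
                             rng.normal(20, 1.0, n)]),
        ])
        groups = ["control"] * n + ["treated"] * n
        result = h.fit_cda(X, groups)
        coefs = np.abs(result.coefficients[:, 0])
        assert coefs[0] > coefs[1] and coefs[0] > coefs[2]

    def test_matches_sklearn_lda_eigenvalue_subspace(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, groups = _three_groups(rng)
        result = h.fit_cda(X, groups)
        lda = sklearn.LinearDiscriminantAnalysis(solver="eigen").fit(X, groups)
        ratios = lda.explained_variance_ratio_[:2]
        np.testing.assert_allclose(result.variance_pct / 100.0, ratios, atol=1e-8)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            h.fit_cda(rng.normal(size=(6, 3)), ["g"] * 6)

    def test_singular_within_scatter_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # exact collinearity
        with pytest.raises(ValueError, match="singular"):
            h.fit_cda(X, ["a"] * 5 + ["b"] * 5)


class TestEvaluateFunctions:
    def test_published_coefficients_on_control_means(self):
        score = h.evaluate_functions([0.47, 0.14, 0.40], [56.83, 6.23, 20.26])
        assert round(score, 2) == 35.69

    def test_zero_triplet(self):
        assert h.evaluate_functions([0.47, 0.14, 0.40], [0, 0, 0]) == 0.0
        assert h.evaluate_functions([-0.62, 0.80, 0.32], [0, 0, 0]) == 0.0

    def test_standardization_divides_by_sds(self):
        score = h.evaluate_functions([1.0, 1.0, 1.0], [10.0, 20.0, 30.0],
                                     standardization=[10.0, 10.0, 10.0])
        assert score == pytest.approx(6.0)

    def test_nonpositive_sds_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            h.evaluate_functions([1.0], [1.0], standardization=[0.0])


class TestClassify:
    def test_well_separated_groups_perfect(self, rng):
        n = 40
        X = np.vstack([rng.normal([60, 6, 20], 0.5, (n, 3)),
                       rng.normal([40, 6, 20], 0.5, (n, 3))])
        groups = ["hi"] * n + ["lo"] * n
        result = h.fit_cda(X, groups)
        assert result.correct_rate_pct == 100.0

    def test_identical_distributions_near_chance(self):
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal([55, 6, 20], 2.0, (3000, 3))
            groups = np.repeat(["g1", "g2", "g3"], 1000)
            rates.append(h.fit_cda(X, groups).correct_rate_pct)
        assert abs(np.mean(rates) - 100.0 / 3.0) < 5.0

    def test_centroid_sample_assigned_to_its_group(self, rng):
        X, groups = _three_groups(rng)
        result = h.fit_cda(X, groups)
        # reconstruct a feature vector scoring exactly at a centroid
        for gi, g in enumerate(result.group_names):
            mean_g = X[np.asarray(groups) == g].mean(axis=0)
            labels, _, _ = h.classify(result, mean_g)
            assert labels[0] == g

    def test_dimension_mismatch_rejected(self, rng):
        X, groups = _three_groups(rng)
        result = h.fit_cda(X, groups)
        with pytest.raises(ValueError, match="variables"):
            h.classify(result, np.ones((2, 5)))

    def test_rate_approaches_bayes_rate_spherical_gaussians(self):
        """Two spherical Gaussian groups at Mahalanobis distance d:
        Bayes accuracy is Phi(d/2); the empirical rate at n=3000 should
        sit within 5 points."""
        rng = np.random.default_rng(0)
        d = 2.0
        n = 1500
        X = np.vstack([rng.normal([0, 0, 0], 1.0, (n, 3)),
                       rng.normal([d, 0, 0], 1.0, (n, 3))])
        groups = ["g1"] * n + ["g2"] * n
        result = h.fit_cda(X, groups)
        bayes = 100.0 * stats.norm.cdf(d / 2)
        assert abs(result.correct_rate_pct - bayes) < 5.0


class TestAnovaLetters:
    def test_identical_groups_share_letter(self, rng):
        vals = {g: rng.normal(50, 2, 20) for g in ("a1", "a2", "a3")}
        summary = h.anova_letters(vals)
        assert set(summary.letters.values()) == {"a"}

    def test_one_distant_group_gets_own_letter(self, rng):
        vals = {"g1": rng.normal(0, 0.1, 10), "g2": rng.normal(0, 0.1, 10),
                "g3": rng.normal(50, 0.1, 10)}
        summary = h.anova_letters(vals)
        assert summary.letters["g1"] == summary.letters["g2"]
        assert summary.letters["g3"] != summary.letters["g1"]

    def test_tukey_pvalues_match_studentized_range_oracle(self, rng):
        """Independent recomputation of each pairwise Tukey p-value from
        the studentized range distribution."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        vals = {"g1": rng.normal(0, 1, 12), "g2": rng.normal(1, 1, 12),
                "g3": rng.normal(3, 1, 12)}
        flat = np.concatenate(list(vals.values()))
        labels = np.repeat(list(vals), [len(v) for v in vals.values()])
        tukey = pairwise_tukeyhsd(flat, labels)
        k, n = 3, len(flat)
        mse = np.sum([(v - v.mean()) ** 2 for v in
                      (np.asarray(vals[g]) for g in vals)]) / (n - k)
        names = list(vals)
        oracle = []
        for i in range(k):
            for j in range(i + 1, k):
                vi, vj = np.asarray(vals[names[i]]), np.asarray(vals[names[j]])
                se = np.sqrt(mse / 2 * (1 / len(vi) + 1 / len(vj)))
                q = abs(vi.mean() - vj.mean()) / se
                oracle.append(stats.studentized_range.sf(q, k, n - k))
        np.testing.assert_allclose(tukey.pvalues, oracle, atol=1e-6)

    def test_two_groups_reduce_to_pairwise_outcome(self, rng):
        far = {"g1": rng.normal(0, 0.5, 15), "g2": rng.normal(10, 0.5, 15)}
        summary = h.anova_letters(far)
        assert summary.letters["g1"] != summary.letters["g2"]
        near = {"g1": rng.normal(0, 5, 8), "g2": rng.normal(0.1, 5, 8)}
        summary = h.anova_letters(near)
        assert summary.letters["g1"] == summary.letters["g2"]

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2 values"):
            h.anova_letters({"g1": [1.0], "g2": [1.0, 2.0]})


def test_summarize_groups_table_shape():
    ss = h.simulate_sample_set(40, seed=0)
    table = h.summarize_groups(ss.colours, ss.groups)
    assert list(table.index) == ["control", "treatment1", "treatment2"]
    assert list(table.columns) == ["L", "a", "b"]
    assert all("±" in cell for cell in table.to_numpy().ravel())


def test_full_discrimination_on_reference_colour_model():
    """Sample sets drawn from the measured group colour distributions
    separate weakly but significantly — the realistic regime."""
    ss = h.simulate_sample_set(30, seed=1)
    result = h.fit_cda(ss.colours, ss.groups)
    assert result.eigenvalues[0] > result.eigenvalues[1] >= 0
    assert 33.3 < result.correct_rate_pct <= 100.0
    assert result.wilks[0] < 1.0
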