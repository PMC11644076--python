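"""Trait screening and genotype grouping: CV filter boundaries,
correlation matrices against brute-force arithmetic, eigen-analysis on
toy matrices, linkage behaviour on constructed point sets, and score-
based grouping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rhizoscreen.multivariate import (
    ahc_cluster,
    filter_by_cv,
    group_profiles,
    pca_standardized,
    pearson_with_p,
    sts_grouping,
)
from rhizoscreen.simulate import planted_cluster_matrix


class TestCvFilter:
    def test_threshold_inclusive(self):
        cvs = pd.Series({"a": 0.29, "b": 0.30, "c": 0.31})
        assert filter_by_cv(cvs) == ["b", "c"]

    def test_zero_threshold_keeps_all(self):
        cvs = pd.Series({"a": 0.0, "b": 0.9})
        assert filter_by_cv(cvs, threshold=0.0) == ["a", "b"]

    def test_derived_traits_droppable(self):
        cvs = pd.Series({"RL": 0.6, "RGR": 0.5, "RLD": 0.6, "MRD": 0.31})
        out = filter_by_cv(cvs, drop=("RGR", "RLD"))
        assert out == ["RL", "MRD"]

    def test_study_scale_control_cvs_all_retained(self):
        # control-treatment CVs of the twelve variable global traits
        cvs = pd.Series([0.31, 0.61, 0.50, 0.57, 0.79, 0.73, 0.65, 1.12,
                         0.51, 0.48, 0.45, 0.54],
                        index=["MRD", "RL", "RD", "RA", "RV", "SRL", "RLI",
                               "RTD", "RDW", "SDW", "TDM", "RSR"])
        assert len(filter_by_cv(cvs)) == 12


class TestPearson:
    def test_identical_vectors_unit_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                           "y": [1.0, 2.0, 3.0, 4.0]})
        out = pearson_with_p(df)
        assert out.r.loc["x", "y"] == pytest.approx(1.0)

    def test_brute_force_small_vectors(self):
        x = np.array([0.0, 1.0, -1.0, 2.0])
        y = np.array([1.0, 0.0, -1.0, 3.0])
        df = pd.DataFrame({"x": x, "y": y})
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        out = pearson_with_p(df)
        assert out.r.loc["x", "y"] == pytest.approx(r_hand, rel=1e-12)

    def test_zero_correlation_p_one_at_n3(self):
        # r = 0 gives t = 0, hence two-sided p = 1
        df = pd.DataFrame({"x": [0.0, 1.0, -1.0], "y": [1.0, 0.0, 0.0]})
        out = pearson_with_p(df)
        if abs(out.r.loc["x", "y"]) < 1e-12:
            assert out.p.loc["x", "y"] == pytest.approx(1.0)

    def test_constant_trait_flagged_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [5.0, 5.0, 5.0]})
        out = pearson_with_p(df)
        assert np.isnan(out.r.loc["x", "y"])

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(20, 4)),
                          columns=list("abcd"))
        out = pearson_with_p(df)
        np.testing.assert_allclose(out.r, out.r.T)
        np.testing.assert_allclose(np.diag(out.r), 1.0)
        assert ((out.r.to_numpy() >= -1) & (out.r.to_numpy() <= 1)).all()


class TestPCA:
    def test_rank_one_two_traits(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        out = pca_standardized(df)
        np.testing.assert_allclose(out.eigenvalues, [2.0, 0.0], atol=1e-9)
        assert out.explained_pct[0] == pytest.approx(100.0)
        assert out.n_retained == 1

    def test_three_trait_eigenvalues_match_characteristic_roots(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        out = pca_standardized(df)
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        # brute-force: roots of the characteristic polynomial
        roots = np.sort(np.real(np.roots(np.poly(corr))))[::-1]
        np.testing.assert_allclose(out.eigenvalues, roots, atol=1e-8)

    def test_eigenvalue_sum_equals_trait_count(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        df.columns = [f"t{i}" for i in range(6)]
        out = pca_standardized(df)
        assert out.eigenvalues.sum() == pytest.approx(6.0)
        assert out.explained_pct.sum() == pytest.approx(100.0)
        assert (np.diff(out.eigenvalues) <= 1e-12).all()

    def test_constant_trait_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                           "b": [2.0, 1.0, 4.0, 3.0],
                           "c": [7.0, 7.0, 7.0, 7.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = pca_standardized(df)
        assert out.dropped == ["c"]
        assert list(out.loadings.index) == ["a", "b"]


class TestAHC:
    def test_two_near_one_far(self):
        df = pd.DataFrame([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0]],
                          index=[1, 2, 3], columns=["x", "y"])
        out = ahc_cluster(df, k=2, standardize=False)
        assert out.labels[1] == out.labels[2]
        assert out.labels[3] != out.labels[1]

    def test_k_equals_n_gives_singletons(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 3)))
        out = ahc_cluster(df, k=5)
        assert out.labels.nunique() == 5

    def test_duplicates_merge_at_height_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        out = ahc_cluster(df, k=2, standardize=False)
        assert out.linkage[0, 2] == pytest.approx(0.0)

    def test_k_larger_than_n_errors(self):
        df = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            ahc_cluster(df, k=4)

    def test_merge_heights_non_decreasing(self):
        mat, _ = planted_cluster_matrix(n_genotypes=40, seed=4)
        out = ahc_cluster(mat, k=5)
        heights = out.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_permutation_invariance(self):
        mat, _ = planted_cluster_matrix(n_genotypes=30, seed=6)
        base = ahc_cluster(mat, k=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(mat))
        shuffled = ahc_cluster(mat.iloc[perm], k=3)
        aligned = shuffled.labels.reindex(base.labels.index)
        assert adjusted_rand_score(base.labels, aligned) == pytest.approx(1.0)

    def test_planted_structure_recovered(self):
        mat, truth = planted_cluster_matrix(n_genotypes=90, n_traits=12,
                                            k=3, seed=17)
        out = ahc_cluster(mat, k=3)
        assert adjusted_rand_score(truth, out.labels) >= 0.9


class TestGroupProfiles:
    def test_profiles_sum_to_one_per_trait(self):
        mat, _ = planted_cluster_matrix(n_genotypes=30, n_traits=4, seed=11)
        mat = mat.abs() + 0.1  # trait means must not cancel
        out = ahc_cluster(mat, k=3)
        profiles = group_profiles(mat, out.labels)
        np.testing.assert_allclose(profiles.sum(axis=0), 1.0, rtol=1e-9)


class TestStsGrouping:
    def test_brute_force_three_groups(self):
        scores = pd.Series({"g1": 10.0, "g2": 9.5, "g3": 1.0, "g4": 1.1,
                            "g5": 5.0})
        labels = sts_grouping(scores, k=3)
        # highest scores form Group 1, the middle Group 2, lowest Group 3
        assert labels["g1"] == labels["g2"] == 1
        assert labels["g5"] == 2
        assert labels["g3"] == labels["g4"] == 3

    def test_k_one_puts_everyone_in_group_one(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 5.0})
        assert (sts_grouping(scores, k=1) == 1).all()

    def test_top_scorer_lands_in_group_one(self):
        rng = np.random.default_rng(13)
        scores = pd.Series(rng.normal(5, 2, 50),
                           index=[f"g{i}" for i in range(50)])
        labels = sts_grouping(scores, k=5)
        assert labels[scores.idxmax()] == 1

    def test_all_equal_scores_error(self):
        scores = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0})
        with pytest.raises(ValueError, match="distinct"):
            sts_grouping(scores, k=2)

    def test_missing_scores_error(self):
        scores = pd.Series({"a": 1.0, "b": np.nan})
        with pytest.raises(ValueError, match="missing"):
            sts_grouping(scores, k=2)
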