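import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from coexnet.module_detection import (
    ModuleAssignment,
    _pam_assign,
    cluster_features,
    compute_eigengenes,
    dynamic_tree_cut,
    merge_close_modules,
)
from coexnet.simulation import SimulationDesign, evaluate_recovery, simulate_expression

from conftest import make_dataset
from oracles import average_linkage_naive, cophenetic_from_merges, leading_eigenvector_oracle


def block_dissimilarity(sizes, within=0.1, between=0.9):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


class TestClusterFeatures:
    def test_two_features_merge_at_their_dissimilarity(self):
        d = np.array([[0.0, 0.37], [0.37, 0.0]])
        Z = cluster_features(d)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.37)

    def test_block_diagonal_heights(self):
        d = block_dissimilarity([3, 3], within=0.0, between=1.0)
        Z = cluster_features(d)
        assert Z[-1, 2] == pytest.approx(1.0)
        assert np.all(Z[:-1, 2] == 0.0)

    def test_matches_naive_average_linkage_oracle(self, rng):
        for _ in range(5):
            n = 10
            d = rng.uniform(0.1, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            Z = cluster_features(d)
            merges = average_linkage_naive(d)
            coph_oracle = cophenetic_from_merges(merges, n)
            coph_impl = squareform(cophenet(Z))
            np.testing.assert_allclose(coph_impl, coph_oracle, atol=1e-10)

    def test_heights_non_decreasing(self, rng):
        d = rng.uniform(0, 1, size=(20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        Z = cluster_features(d)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_single_feature_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_features(np.zeros((1, 1)))

    def test_asymmetric_rejected(self, rng):
        d = rng.uniform(0, 1, size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            cluster_features(d)


class TestDynamicTreeCut:
    def test_planted_three_blocks_recovered_exactly(self):
        d = block_dissimilarity([30, 30, 30])
        Z = cluster_features(d)
        a = dynamic_tree_cut(Z, d, min_module_size=10)
        truth = pd.Series(np.repeat([1, 2, 3], 30), index=a.labels.index)
        rec = evaluate_recovery(truth, a)
        assert a.n_modules == 3
        assert rec["ari"] == pytest.approx(1.0)

    def test_min_size_above_feature_count_all_unassigned(self, caplog):
        d = block_dissimilarity([10, 10])
        Z = cluster_features(d)
        with caplog.at_level("WARNING"):
            a = dynamic_tree_cut(Z, d, min_module_size=21)
        assert a.n_modules == 0
        assert (a.labels == 0).all()
        assert any("unassigned" in r.message for r in caplog.records)

    def test_scattered_features_stay_unassigned(self):
        n = 55
        d = np.full((n, n), 0.95)
        d[:50, :50] = 0.1
        np.fill_diagonal(d, 0.0)
        Z = cluster_features(d)
        for pam in (False, True):
            a = dynamic_tree_cut(Z, d, min_module_size=10, pam_stage=pam)
            assert a.module_sizes() == {0: 5, 1: 50}

    def test_labels_ordered_by_decreasing_size(self):
        d = block_dissimilarity([10, 40, 25])
        Z = cluster_features(d)
        a = dynamic_tree_cut(Z, d, min_module_size=5, pam_stage=False)
        sizes = a.module_sizes()
        module_sizes = [sizes[l] for l in a.module_labels]
        assert module_sizes == sorted(module_sizes, reverse=True)

    def test_feature_permutation_changes_only_ordering(self, rng):
        d = block_dissimilarity([20, 20], within=0.2, between=0.95)
        ids = [f"g{i}" for i in range(40)]
        Z = cluster_features(d)
        a1 = dynamic_tree_cut(Z, d, min_module_size=5, feature_ids=ids)
        perm = rng.permutation(40)
        dp = d[np.ix_(perm, perm)]
        Zp = cluster_features(dp)
        a2 = dynamic_tree_cut(Zp, dp, min_module_size=5, feature_ids=[ids[i] for i in perm])
        sets1 = {frozenset(v) for v in a1.as_sets().values()}
        sets2 = {frozenset(v) for v in a2.as_sets().values()}
        assert sets1 == sets2

    def test_invalid_parameters(self):
        d = block_dissimilarity([5, 5])
        Z = cluster_features(d)
        with pytest.raises(ValueError, match="min_module_size"):
            dynamic_tree_cut(Z, d, min_module_size=1)
        with pytest.raises(ValueError, match="deep_split"):
            dynamic_tree_cut(Z, d, deep_split=7)


class TestPamStage:
    def test_assigns_only_when_joining_beats_unassigned(self):
        # feature 4 is inside module 1's radius and closer than overall;
        # feature 5 is equidistant noise and must stay unassigned
        d = np.array(
            [
                [0.0, 0.1, 0.3, 0.9, 0.2, 0.9],
                [0.1, 0.0, 0.3, 0.9, 0.2, 0.9],
                [0.3, 0.3, 0.0, 0.9, 0.2, 0.9],
                [0.9, 0.9, 0.9, 0.0, 0.9, 0.9],
                [0.2, 0.2, 0.2, 0.9, 0.0, 0.9],
                [0.9, 0.9, 0.9, 0.9, 0.9, 0.0],
            ]
        )
        labels = np.array([1, 1, 1, 0, 0, 0])
        out = _pam_assign(labels, d)
        assert out[4] == 1  # avg 0.2 < overall, within radius (member g3 has avg 0.3)
        assert out[3] == 0 and out[5] == 0


class TestEigengenes:
    def test_single_feature_module_is_standardized_profile(self, rng):
        X = rng.standard_normal((20, 1))
        ds = make_dataset(X)
        a = ModuleAssignment(labels=pd.Series([1], index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        x = X[:, 0]
        z = (x - x.mean()) / x.std(ddof=1)
        e = eig.eigengene(1)
        np.testing.assert_allclose(np.abs(e), np.abs(z), atol=1e-10)
        assert eig.variance_explained[1] == pytest.approx(1.0)
        assert np.corrcoef(e, z)[0, 1] > 0  # sign follows the mean profile

    def test_identical_features_variance_explained_one(self, rng):
        profile = rng.standard_normal(15)
        X = np.tile(profile[:, None], (1, 6))
        ds = make_dataset(X)
        a = ModuleAssignment(labels=pd.Series([1] * 6, index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        assert eig.variance_explained[1] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.eigengene(1), z, atol=1e-10)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((30, 20))
        ds = make_dataset(X)
        a = ModuleAssignment(labels=pd.Series([1] * 20, index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        scores, ve = leading_eigenvector_oracle(Xs)
        e = eig.eigengene(1)
        assert min(
            np.abs(e - scores).max(), np.abs(e + scores).max()
        ) < 1e-8
        assert eig.variance_explained[1] == pytest.approx(ve, abs=1e-10)

    def test_zero_mean_unit_variance(self, rng):
        ds = make_dataset(rng.standard_normal((25, 12)))
        a = ModuleAssignment(labels=pd.Series([1] * 6 + [2] * 6, index=ds.feature_ids))
        eig = compute_eigengenes(ds, a)
        for label in (1, 2):
            e = eig.eigengene(label)
            assert abs(e.mean()) < 1e-10
            assert e.std(ddof=1) == pytest.approx(1.0)

    def test_deterministic_recompute(self, rng):
        ds = make_dataset(rng.standard_normal((25, 12)))
        a = ModuleAssignment(labels=pd.Series([1] * 12, index=ds.feature_ids))
        e1 = compute_eigengenes(ds, a).eigengene(1)
        e2 = compute_eigengenes(ds, a).eigengene(1)
        np.testing.assert_array_equal(e1, e2)

    def test_constant_feature_error(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 0] = 2.0
        ds = make_dataset(X)
        a = ModuleAssignment(labels=pd.Series([1, 1, 1], index=ds.feature_ids))
        with pytest.raises(ValueError, match="constant"):
            compute_eigengenes(ds, a)


class TestMergeCloseModules:
    @staticmethod
    def truth_assignment(true_labels):
        return ModuleAssignment(labels=true_labels)

    def test_shared_factor_modules_merge(self):
        design = SimulationDesign(
            module_sizes=(80, 80), n_background=0, factor_correlation=0.9, seed=1
        )
        ds, truth, _ = simulate_expression(design)
        merged, eig = merge_close_modules(ds, self.truth_assignment(truth), 0.25)
        assert merged.n_modules == 1
        assert eig.module_labels == [1]

    def test_orthogonal_modules_unchanged(self):
        design = SimulationDesign(
            module_sizes=(80, 80), n_background=0, factor_correlation=0.0, seed=1
        )
        ds, truth, _ = simulate_expression(design)
        merged, _ = merge_close_modules(ds, self.truth_assignment(truth), 0.25)
        assert merged.n_modules == 2

    def test_zero_height_never_merges(self):
        design = SimulationDesign(
            module_sizes=(80, 80), n_background=0, factor_correlation=0.95, seed=2
        )
        ds, truth, _ = simulate_expression(design)
        merged, _ = merge_close_modules(ds, self.truth_assignment(truth), 0.0)
        assert merged.n_modules == 2

    def test_invalid_height(self, random_dataset):
        a = ModuleAssignment(
            labels=pd.Series([1] * random_dataset.n_features, index=random_dataset.feature_ids)
        )
        with pytest.raises(ValueError, match="merge_cut_height"):
            merge_close_modules(random_dataset, a, 1.5)
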