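"""Constraint mining: distance features, clustering, significance, PCA."""

import numpy as np
import pytest

from shakediff.chains import (
    build_chain,
    extended_chain_spec,
    make_two_mode_ensemble,
)
from shakediff.constraints import Conformation
from shakediff.mining import (
    DistanceFeatureMatrix,
    cluster,
    featurize,
    pca_constraint_loadings,
    significance,
    top_constraints,
)
from shakediff.projection import project


def _feature_matrix(vectors, n_atoms):
    pair_index = [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)]
    return DistanceFeatureMatrix(np.asarray(vectors, float), pair_index, n_atoms)


class TestFeaturize:
    def test_triangle_distances(self):
        conf = Conformation(np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]))
        feats = featurize([conf])
        assert feats.pair_index == [(0, 1), (0, 2), (1, 2)]
        assert np.allclose(feats.vectors[0], [1.0, 1.0, np.sqrt(2)])

    def test_two_atoms_single_pair(self):
        conf = Conformation(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        feats = featurize([conf, conf])
        assert feats.vectors.shape == (2, 1)

    def test_row_permutation_follows_conformer_order(self):
        a = Conformation(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        b = Conformation(np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        f_ab = featurize([a, b]).vectors
        f_ba = featurize([b, a]).vectors
        assert np.array_equal(f_ab[::-1], f_ba)

    def test_heterogeneous_atom_counts_rejected(self):
        a = Conformation(np.zeros((2, 3)) + np.arange(2)[:, None])
        b = Conformation(np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(ValueError):
            featurize([a, b])


class TestCluster:
    def test_separated_clusters_recovered(self, rng):
        lo = rng.normal(0.0, 0.05, size=(20, 3)) + 2.0
        hi = rng.normal(0.0, 0.05, size=(20, 3)) + 8.0
        feats = _feature_matrix(np.vstack([lo, hi]), 3)
        labels = cluster(feats, 2, seed=0)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_single_cluster(self, rng):
        feats = _feature_matrix(rng.uniform(1, 2, size=(10, 3)), 3)
        assert set(cluster(feats, 1, seed=0)) == {0}

    def test_determinism_given_seed(self, rng):
        feats = _feature_matrix(rng.uniform(1, 5, size=(30, 6)), 4)
        assert np.array_equal(cluster(feats, 3, seed=7), cluster(feats, 3, seed=7))

    def test_invalid_cluster_count(self, rng):
        feats = _feature_matrix(rng.uniform(1, 2, size=(4, 3)), 3)
        with pytest.raises(ValueError):
            cluster(feats, 0)
        with pytest.raises(ValueError):
            cluster(feats, 5)


class TestSignificance:
    def test_identical_conformers_zero_significance(self):
        feats = _feature_matrix(np.tile([1.0, 2.0, 3.0], (6, 1)), 3)
        report = significance(feats, np.array([0, 0, 0, 1, 1, 1]))
        assert np.all(report.significance == 0.0)

    def test_two_cluster_hand_example(self):
        # clusters differ only in pair (0, 4): 4.0 vs 3.0
        n_atoms = 5
        pair_index = [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)]
        col = pair_index.index((0, 4))
        base = np.full(len(pair_index), 2.0)
        va, vb = base.copy(), base.copy()
        va[col], vb[col] = 4.0, 3.0
        feats = _feature_matrix([va, va, vb, vb], n_atoms)
        report = significance(feats, np.array([0, 0, 1, 1]))
        assert report.global_mean[col] == pytest.approx(3.5)
        assert report.significance[0, col] == pytest.approx(0.5)
        assert report.significance[1, col] == pytest.approx(0.5)
        mask = np.arange(len(pair_index)) != col
        assert np.all(report.significance[:, mask] == 0.0)

    def test_scaling_coordinates_scales_significance(self, rng):
        modes = [extended_chain_spec(5, torsion=180.0),
                 extended_chain_spec(5, torsion=60.0)]
        confs, labels = make_two_mode_ensemble(modes, 30, seed=2)
        feats = featurize(confs)
        scaled = featurize([Conformation(c.coordinates * 2.0) for c in confs])
        r1 = significance(feats, labels)
        r2 = significance(scaled, labels)
        assert np.allclose(r2.significance, 2.0 * r1.significance, atol=1e-10)

    def test_empty_cluster_reported(self):
        feats = _feature_matrix(np.ones((3, 3)), 3)
        with pytest.raises(ValueError, match="cluster 1"):
            significance(feats, np.array([0, 0, 2]))


class TestTopConstraints:
    def _fixture_report(self):
        n_atoms = 5
        pair_index = [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)]
        col = pair_index.index((0, 4))
        base = np.full(len(pair_index), 2.0)
        va, vb = base.copy(), base.copy()
        va[col], vb[col] = 4.0, 3.0
        feats = _feature_matrix([va, va, vb, vb], n_atoms)
        return significance(feats, np.array([0, 0, 1, 1]))

    def test_top_pair_with_cluster_mean_target(self):
        report = self._fixture_report()
        cs = top_constraints(report, 1, 0)
        assert len(cs) == 1
        assert cs[0].atom_indices == (0, 4)
        assert cs[0].target == pytest.approx(4.0)

    def test_all_pairs_sorted_by_significance(self):
        report = self._fixture_report()
        cs = top_constraints(report, len(report.pair_index), 0)
        assert len(cs) == len(report.pair_index)
        assert cs[0].atom_indices == (0, 4)

    def test_ties_break_lexicographically(self):
        feats = _feature_matrix(np.tile([1.0, 2.0, 3.0], (4, 1)), 3)
        report = significance(feats, np.array([0, 0, 1, 1]))
        cs = top_constraints(report, 3, 0)  # all Delta equal (zero)
        assert [c.atom_indices for c in cs] == [(0, 1), (0, 2), (1, 2)]

    def test_bounded_mode_uses_cluster_std_as_slack(self, rng):
        modes = [extended_chain_spec(5, torsion=180.0),
                 extended_chain_spec(5, torsion=60.0)]
        confs, labels = make_two_mode_ensemble(modes, 40, seed=4)
        report = significance(featurize(confs), labels)
        cs = top_constraints(report, 3, 0, bounded=True)
        assert all(c.slack_max > 0 for c in cs)
        assert all(c.upper_final - c.lower_final == pytest.approx(2 * c.slack_max)
                   for c in cs)

    def test_invalid_arguments(self):
        report = self._fixture_report()
        with pytest.raises(ValueError):
            top_constraints(report, 1, 5)
        with pytest.raises(ValueError):
            top_constraints(report, 100, 0)


class TestPCALoadings:
    def test_single_variable_column_dominates_pc1(self, rng):
        X = np.tile([2.0, 3.0, 4.0], (30, 1))
        X[:, 1] += rng.normal(0, 1.0, 30)
        feats = _feature_matrix(X, 3)
        reports = pca_constraint_loadings(feats, 2, top=3)
        assert reports[0].ranked_pairs[0][0] == (0, 2)  # column 1 -> pair (0,2)
        assert abs(reports[0].loadings[1]) == pytest.approx(1.0, abs=1e-8)

    def test_full_basis_reconstructs_centered_features(self, rng):
        X = rng.uniform(1, 5, size=(12, 6))
        feats = _feature_matrix(X, 4)
        from sklearn.decomposition import PCA

        pca = PCA(n_components=6)
        centered = X - X.mean(axis=0)
        scores = pca.fit_transform(centered)
        recon = scores @ pca.components_
        assert np.abs(recon - centered).max() < 1e-8

    def test_representative_is_extreme_scorer(self, rng):
        lo = rng.normal(2.0, 0.01, size=(10, 3))
        hi = rng.normal(8.0, 0.01, size=(10, 3))
        feats = _feature_matrix(np.vstack([lo, hi]), 3)
        reports = pca_constraint_loadings(feats, 1, top=1)
        assert reports[0].representative_conformer in range(20)
        # sign flip of a component leaves the |loading| ranking unchanged
        flipped = [(p, l) for p, l in reports[0].ranked_pairs]
        assert flipped == sorted(flipped, key=lambda t: -t[1])


class TestMiningRecovery:
    def test_planted_pairs_recovered_across_draws(self):
        """Two geometric modes differing only in the final torsion of a
        5-atom chain separate exactly the pairs (0,4) and (1,4); mining must
        recover that pair set from every seeded draw."""
        from shakediff.chains import InternalChainSpec

        planted = {(0, 4), (1, 4)}
        modes = [
            InternalChainSpec([1.53] * 4, [112.5] * 3, [180.0, 180.0]),
            InternalChainSpec([1.53] * 4, [112.5] * 3, [180.0, 60.0]),
        ]
        for seed in range(20):
            confs, _ = make_two_mode_ensemble(modes, 60, seed=seed)
            feats = featurize(confs)
            labels = cluster(feats, 2, seed=seed)
            report = significance(feats, labels)
            for k in (0, 1):
                cs = top_constraints(report, len(planted), k)
                assert {c.atom_indices for c in cs} == planted

    def test_mined_constraints_are_feasible_for_cluster_members(self):
        modes = [extended_chain_spec(6, torsion=180.0),
                 extended_chain_spec(6, torsion=65.0)]
        confs, _ = make_two_mode_ensemble(modes, 50, seed=5)
        feats = featurize(confs)
        labels = cluster(feats, 2, seed=5)
        report = significance(feats, labels)
        for k in (0, 1):
            cs = top_constraints(report, 5, k)
            member = confs[int(np.flatnonzero(labels == k)[0])]
            res = project(member.coordinates, cs, tol=0.003)
            assert res.converged and res.iterations_used <= 10
            assert np.abs(cs.residuals(res.coordinates)).max() <= 0.003
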