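"""Similarity construction, spectral clustering, consensus and group logic."""

import itertools

import numpy as np
import pytest

from connparc.errors import DegenerateInputError
from connparc.parcellation import (ConnectivityProfileMatrix,
                                   SpectralParcellator, build_similarity,
                                   consensus_matrix, group_parcellation,
                                   reassign_isolated, spectral_parcellate)
from connparc.stability import nmi


def _profiles(counts):
    counts = np.asarray(counts, dtype=float)
    return ConnectivityProfileMatrix(counts=counts,
                                     seed_ids=np.arange(counts.shape[0]),
                                     target_ids=np.arange(counts.shape[1]))


class TestBuildSimilarity:
    @pytest.mark.parametrize("rows, expected", [
        ([[1, 2, 3], [1, 2, 3]], 1.0),
        ([[1, 2, 3], [3, 2, 1]], -1.0),
        ([[1, 0, 0, 1], [0, 1, 1, 0]], -1.0),
    ])
    def test_worked_correlations(self, rows, expected):
        sim = build_similarity(_profiles(rows))
        assert sim[0, 1] == pytest.approx(expected)

    def test_symmetric_unit_diagonal_bounded(self, small_subjects):
        sim = build_similarity(small_subjects[0])
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)
        assert sim.min() >= -1.0 and sim.max() <= 1.0

    def test_log_transform_dialect(self):
        raw = np.array([[1.0, 10.0, 100.0], [2.0, 20.0, 200.0],
                        [100.0, 10.0, 1.0]])
        sim = build_similarity(_profiles(raw), log_transform=True)
        expected = np.corrcoef(np.log1p(raw))
        assert np.allclose(sim, expected)

    def test_zero_variance_row_gets_zero_similarity(self):
        with pytest.warns(RuntimeWarning):
            sim = build_similarity(_profiles([[5, 5, 5], [1, 2, 3], [3, 1, 2]]))
        assert np.all(sim[0, 1:] == 0) and np.all(sim[1:, 0] == 0)
        assert sim[0, 0] == 1.0


def _block_similarity(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    sim = np.full((n, n), between)
    start = 0
    for s in sizes:
        sim[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(sim, 1.0)
    return sim


class TestSpectralParcellate:
    def test_two_block_similarity_recovered_exactly(self):
        sim = _block_similarity([4, 5])
        parc = spectral_parcellate(sim, 2, rng_seed=0)
        blocks = np.repeat([1, 2], [4, 5])
        assert nmi(parc.labels, blocks) == pytest.approx(1.0)

    def test_matches_exhaustive_min_cut_partition(self):
        # independent oracle: exhaustive search over all 2-partitions for the
        # minimum normalized cut of the same shifted affinity
        rng = np.random.default_rng(3)
        blocks = np.repeat([1, 2], [5, 5])
        sim = np.where(blocks[:, None] == blocks[None, :], 0.8, -0.2)
        sim += rng.uniform(-0.05, 0.05, sim.shape)
        sim = np.clip((sim + sim.T) / 2, -1, 1)
        np.fill_diagonal(sim, 1.0)
        A = (sim + 1) / 2
        n = len(A)
        best, best_val = None, np.inf
        for bits in itertools.product([0, 1], repeat=n - 1):
            lab = np.array((0,) + bits)
            if lab.sum() in (0, n):
                continue
            cut = A[lab == 0][:, lab == 1].sum()
            vol0, vol1 = A[lab == 0].sum(), A[lab == 1].sum()
            val = cut / vol0 + cut / vol1
            if val < best_val:
                best, best_val = lab, val
        parc = spectral_parcellate(sim, 2, rng_seed=0)
        assert nmi(parc.labels, best + 1) == pytest.approx(1.0)

    def test_agrees_with_sklearn_spectral_clustering(self):
        from sklearn.cluster import SpectralClustering

        sim = _block_similarity([6, 6, 6], within=0.9, between=0.05)
        A = (sim + 1) / 2
        ours = spectral_parcellate(sim, 3, rng_seed=0)
        ref = SpectralClustering(n_clusters=3, affinity="precomputed",
                                 random_state=0).fit_predict(A)
        assert nmi(ours.labels, ref + 1) == pytest.approx(1.0)

    def test_k_equals_n_gives_singletons(self):
        sim = np.eye(5)
        parc = spectral_parcellate(sim, 5, rng_seed=0, precomputed_affinity=True)
        assert len(np.unique(parc.labels)) == 5

    def test_k_range_validation(self):
        sim = _block_similarity([3, 3])
        with pytest.raises(ValueError):
            spectral_parcellate(sim, 1)
        with pytest.raises(ValueError):
            spectral_parcellate(sim, 7)

    def test_all_zero_affinity_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spectral_parcellate(np.zeros((6, 6)), 2, precomputed_affinity=True)

    def test_permutation_equivariance(self):
        sim = _block_similarity([5, 6, 7], within=0.9, between=-0.1)
        labels = spectral_parcellate(sim, 3, rng_seed=0).labels
        rng = np.random.default_rng(11)
        for _ in range(5):
            perm = rng.permutation(len(sim))
            permuted = spectral_parcellate(sim[np.ix_(perm, perm)], 3,
                                           rng_seed=0).labels
            assert nmi(permuted, labels[perm]) == pytest.approx(1.0)

    def test_deterministic_for_fixed_seed(self, small_subjects):
        sim = build_similarity(small_subjects[0])
        a = spectral_parcellate(sim, 3, rng_seed=42).labels
        b = spectral_parcellate(sim, 3, rng_seed=42).labels
        assert np.array_equal(a, b)


class TestSpectralParcellatorEstimator:
    def test_fit_predict_and_sklearn_params(self, small_subjects):
        est = SpectralParcellator(n_clusters=3, random_state=0)
        labels = est.fit_predict(small_subjects[0].counts)
        assert set(np.unique(labels)) == {1, 2, 3}
        assert est.get_params()["n_clusters"] == 3
        assert est.labels_ is labels

    def test_clip_dialect_differs_only_in_affinity(self, small_subjects):
        est = SpectralParcellator(n_clusters=3, affinity="clip",
                                  random_state=0).fit(small_subjects[0].counts)
        assert est.affinity_matrix_.min() >= 0.0


class TestConsensus:
    def test_worked_example(self):
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        assert np.array_equal(consensus_matrix(np.array([1, 1, 2])), expected)

    def test_single_cluster_all_ones(self):
        assert consensus_matrix(np.array([1, 1, 1])).all()

    def test_singletons_identity(self):
        assert np.array_equal(consensus_matrix(np.array([1, 2, 3])), np.eye(3))


class TestGroupParcellation:
    def test_shared_labeling_recovered(self):
        labels = np.repeat([1, 2], [4, 4])
        gp = group_parcellation([labels] * 5, 2, rng_seed=0)
        assert nmi(gp.labels, labels) == pytest.approx(1.0)

    def test_relabeled_subjects_agree(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([2, 2, 1, 1])
        gp = group_parcellation([a, b], 2, rng_seed=0)
        assert nmi(gp.labels, a) == pytest.approx(1.0)

    def test_idempotent_on_copies(self, small_subjects):
        sim = build_similarity(small_subjects[0])
        parc = spectral_parcellate(sim, 3, rng_seed=0)
        gp = group_parcellation([parc] * 4, 3, rng_seed=0)
        assert nmi(gp.labels, parc.labels) == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_parcellation([], 2)


class TestNoiselessRecovery:
    def test_group_parcellation_matches_planted_labels(self, small_geometry,
                                                       noiseless_subjects):
        truth, subjects = noiseless_subjects
        idx = small_geometry.indices("left")
        parcs = [spectral_parcellate(build_similarity(c.subset(idx)), 3,
                                     rng_seed=0) for c in subjects]
        gp = group_parcellation(parcs, 3, rng_seed=0)
        assert nmi(gp.labels, truth.labels_true[idx]) == pytest.approx(1.0)


class TestReassignIsolated:
    def test_nearest_neighbor_label(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [10, 0, 0], [11, 0, 0]])
        labels = np.array([1, 1, 2, 2])
        out = reassign_isolated(labels, coords, np.array([False, True, False, False]))
        assert out[1] == 1

    def test_all_isolated_degenerate(self):
        with pytest.raises(DegenerateInputError):
            reassign_isolated(np.array([1, 2]), np.zeros((2, 3)),
                              np.array([True, True]))
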