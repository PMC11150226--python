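import numpy as np
import pytest

from habitatpipe.habitat_mapping import (
    canonicalize_labels,
    consensus_select_k,
    entropy_map,
    habitat_masks,
    kmeans_voxels,
    smooth_in_mask,
    voxel_features,
)
from habitatpipe.imaging_io import CTVolume, Mask

from oracles import entropy_oracle


def _vol_mask(data):
    return CTVolume(np.asarray(data, float)), Mask(np.ones(np.shape(data)))


class TestEntropyMap:
    def test_constant_neighborhood_zero_entropy(self):
        vol, mask = _vol_mask(np.full((5, 5, 5), 100.0))
        ent = entropy_map(vol, mask, kernel_radius=2, n_bins=32)
        np.testing.assert_allclose(ent, 0.0, atol=1e-12)

    def test_two_equal_bins_one_bit(self):
        # a 2x2x2 volume alternating between two bins: every clipped window
        # holds the 8 voxels, split 4/4 -> H = 1 bit
        data = np.zeros((2, 2, 2))
        data[::1, :, 1] = 128.0
        vol, mask = _vol_mask(data)
        ent = entropy_map(vol, mask, kernel_radius=1, n_bins=32)
        np.testing.assert_allclose(ent, 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        data = np.clip(rng.normal(120, 60, size=(7, 8, 6)), 0, 255)
        mask = rng.random((7, 8, 6)) < 0.7
        mask[3, 3, 3] = True
        vol = CTVolume(data)
        ent = entropy_map(vol, Mask(mask.astype(int)), kernel_radius=2, n_bins=32)
        for coord in [(0, 0, 0), (3, 3, 3), (6, 7, 5), (2, 5, 1)]:
            if not mask[coord]:
                continue
            expected = entropy_oracle(data, mask, coord, radius=2, n_bins=32)
            assert ent[coord] == pytest.approx(expected, abs=1e-10)

    def test_bounded_by_log2_bins(self, rng):
        data = rng.uniform(0, 255, size=(9, 9, 9))
        vol, mask = _vol_mask(data)
        for n_bins in (4, 16):
            ent = entropy_map(vol, mask, kernel_radius=2, n_bins=n_bins)
            assert ent.max() <= np.log2(n_bins) + 1e-12
            assert ent.min() >= 0

    def test_invariant_to_affine_intensity_after_normalization(self, rng):
        from habitatpipe.imaging_io import normalize_grayscale

        data = rng.normal(80, 30, size=(8, 8, 8))
        mask = Mask(np.ones((8, 8, 8)))
        a = entropy_map(normalize_grayscale(CTVolume(data), mask), mask)
        b = entropy_map(normalize_grayscale(CTVolume(2.0 * data - 5.0), mask), mask)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_smooth_in_mask_preserves_mean_and_support(self, rng):
        field = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.6
        mask[2, 2, 2] = True
        out = smooth_in_mask(field, mask)
        assert np.all(out[~mask] == 0)
        # smoothing is an average of in-mask values: range cannot expand
        assert out[mask].max() <= field[mask].max() + 1e-12
        assert out[mask].min() >= field[mask].min() - 1e-12


class TestKMeans:
    def test_k1_centroid_is_mean(self, rng):
        X = rng.normal(size=(50, 2))
        labels, cent, _ = kmeans_voxels(X, 1, seed=0)
        assert set(labels) == {0}
        np.testing.assert_allclose(cent[0], X.mean(axis=0), atol=1e-9)

    def test_two_planted_blobs_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score

        a = rng.normal([0, 0], 0.05, size=(40, 2))
        b = rng.normal([10, 10], 0.05, size=(40, 2))
        X = np.vstack([a, b])
        truth = np.repeat([0, 1], 40)
        labels, _, _ = kmeans_voxels(X, 2, seed=3)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(100, 2))
        l1, c1, _ = kmeans_voxels(X, 4, seed=11)
        l2, c2, _ = kmeans_voxels(X, 4, seed=11)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(c1, c2)

    def test_fewer_distinct_points_reduces_k_with_warning(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="reduced k"):
            labels, cent, info = kmeans_voxels(X, 3, seed=0)
        assert len(cent) == 2
        assert info["provenance"]

    def test_objective_reported_and_converged(self, rng):
        X = rng.normal(size=(200, 2))
        _, _, info = kmeans_voxels(X, 3, seed=0)
        assert info["inertia"] >= 0
        assert info["converged"]


class TestCanonicalization:
    def test_orders_by_intensity(self):
        labels = np.array([0, 0, 1, 1])
        cent = np.array([[200.0, 1.0], [50.0, 2.0]])
        coords = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]])
        h = canonicalize_labels(labels, cent, coords, (1, 1, 4))
        # original cluster 1 (intensity 50) becomes habitat 1
        np.testing.assert_array_equal(h.labels[0, 0], [2, 2, 1, 1])
        assert h.centroids[0, 0] < h.centroids[1, 0]

    def test_tie_broken_by_entropy(self):
        labels = np.array([0, 1])
        cent = np.array([[100.0, 2.0], [100.0, 0.5]])
        coords = np.array([[0, 0, 0], [0, 0, 1]])
        h = canonicalize_labels(labels, cent, coords, (1, 1, 2))
        np.testing.assert_array_equal(h.labels[0, 0], [2, 1])  # lower entropy first

    def test_invariant_to_input_label_permutation(self, rng):
        X = np.vstack([
            rng.normal([10, 1], 0.1, size=(20, 2)),
            rng.normal([50, 2], 0.1, size=(20, 2)),
            rng.normal([90, 3], 0.1, size=(20, 2)),
        ])
        coords = np.argwhere(np.ones((4, 5, 3)))
        labels = np.repeat([0, 1, 2], 20)
        cent = np.vstack([X[labels == c].mean(axis=0) for c in range(3)])
        perm = np.array([2, 0, 1])
        h1 = canonicalize_labels(labels, cent, coords, (4, 5, 3))
        h2 = canonicalize_labels(perm[labels], cent[np.argsort(perm)], coords, (4, 5, 3))
        np.testing.assert_array_equal(h1.labels, h2.labels)


class TestConsensus:
    def test_separable_items_give_binary_consensus_and_zero_pac(self, rng):
        X = np.vstack([
            np.tile([0.0, 0.0], (30, 1)) + rng.normal(0, 1e-3, (30, 2)),
            np.tile([50.0, 50.0], (30, 1)) + rng.normal(0, 1e-3, (30, 2)),
        ])
        res = consensus_select_k(X, k_range=range(2, 5), n_resamples=20, seed=0)
        m = res.consensus_matrices[2]
        co_sampled = m[np.triu_indices_from(m, 1)]
        assert np.all((co_sampled < 1e-9) | (co_sampled > 1 - 1e-9))
        assert res.pac_scores[2] == 0.0

    def test_k_range_has_nine_candidates(self, rng):
        X = rng.normal(size=(60, 2))
        res = consensus_select_k(X, k_range=range(2, 11), n_resamples=5, seed=1)
        assert res.k_range == list(range(2, 11))
        assert len(res.cdf_areas) == 9

    def test_consensus_matrix_properties(self, rng):
        X = rng.normal(size=(40, 2))
        res = consensus_select_k(X, k_range=range(2, 5), n_resamples=10, seed=2)
        for m in res.consensus_matrices.values():
            np.testing.assert_allclose(m, m.T)
            assert np.all((m >= 0) & (m <= 1))
            np.testing.assert_allclose(np.diag(m), 1.0)

    def test_too_few_resamples_raises(self, rng):
        with pytest.raises(ValueError, match="n_resamples"):
            consensus_select_k(rng.normal(size=(20, 2)), n_resamples=1)

    def test_patient_level_items_alternative(self, rng):
        """Patient-summary mode: one quantile row per patient, usable as
        consensus items."""
        from habitatpipe.habitat_mapping import VoxelFeatureMatrix, pool_patient_summaries

        vfms = []
        for _ in range(6):
            n = int(rng.integers(50, 120))
            coords = np.argwhere(np.ones((10, 10, 10)))[:n]
            vfms.append(VoxelFeatureMatrix(rng.normal(size=(n, 2)), coords, (10, 10, 10)))
        items = pool_patient_summaries(vfms, n_quantiles=5)
        assert items.shape == (6, 10)
        res = consensus_select_k(items, k_range=range(2, 4), n_resamples=5, seed=0)
        assert res.k_selected in (2, 3)


class TestHabitatMasks:
    def test_partition_and_empty_flag(self, preprocessed_patient):
        from habitatpipe.habitat_mapping import compute_habitat_map

        norm, mask, ent = preprocessed_patient
        h = compute_habitat_map(norm, mask, 3, seed=0, entropy=ent)
        masks = habitat_masks(h)
        assert len(masks) == 3
        total = sum(m.sum() for m, _ in masks)
        assert total == mask.n_voxels  # union is the VOI, partition disjoint
        overlap = sum(
            np.logical_and(masks[i][0], masks[j][0]).sum()
            for i in range(3) for j in range(i + 1, 3)
        )
        assert overlap == 0
        assert not any(empty for _, empty in masks)

    def test_empty_habitat_flagged(self):
        from habitatpipe.habitat_mapping import HabitatMap

        labels = np.zeros((2, 2, 2), dtype=np.int16)
        labels[0, 0, 0] = 1  # habitat 2 exists nowhere
        h = HabitatMap(labels=labels, k=2, centroids=np.zeros((2, 2)))
        masks = habitat_masks(h)
        assert masks[0][1] is False and masks[1][1] is True


def test_habitat_recovery_on_separated_regime(preprocessed_patient, small_patient):
    """ARI >= 0.8 against the planted truth in the generator's separated
    three-habitat regime (means 60/120/180, sd 10)."""
    from sklearn.metrics import adjusted_rand_score

    from habitatpipe.habitat_mapping import compute_habitat_map

    norm, mask, ent = preprocessed_patient
    h = compute_habitat_map(norm, mask, 3, seed=0, entropy=ent)
    sel = (small_patient.truth_habitats > 0) & (h.labels > 0)
    ari = adjusted_rand_score(small_patient.truth_habitats[sel], h.labels[sel])
    assert ari >= 0.8
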