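import numpy as np
import pytest

from lesionbow.bow import (
    Codebook,
    FeatureVector,
    PatchSet,
    PhaseSubsetEmpty,
    assign_codeword,
    assign_codewords,
    bow_feature,
    extract_patches,
    filter_patches,
    patient_feature,
    region_histogram,
    train_codebook,
)
from conftest import make_roi


def _codebook(words):
    words = np.asarray(words, dtype=np.float64)
    return Codebook(words=words, patch_size=int(round(np.sqrt(words.shape[1]))), seed=0,
                    n_training=0)


class TestExtractPatches:
    def test_one_patch_per_labeled_pixel(self):
        roi = make_roi(np.full((14, 16), 50), lesion=np.ones((14, 16)))
        patches = extract_patches(roi)
        assert len(patches) == 14 * 16
        assert patches.descriptors.shape == (224, 49)

    def test_corner_patch_zero_padded(self):
        roi = make_roi(np.full((10, 10), 9), lesion=np.ones((10, 10)))
        patches = extract_patches(roi)
        corner = patches.descriptors[0].reshape(7, 7)
        assert patches.centers[0].tolist() == [0, 0]
        assert (corner[:3, :] == 0).all() and (corner[:, :3] == 0).all()
        assert (corner[3:, 3:] == 9).all()

    def test_constant_crop_interior_descriptors_identical(self):
        roi = make_roi(np.full((12, 12), 7), lesion=np.ones((12, 12)))
        patches = extract_patches(roi)
        interior = [
            patches.descriptors[i]
            for i in range(len(patches))
            if (patches.centers[i] >= 3).all() and (patches.centers[i] < 9).all()
        ]
        assert all((d == interior[0]).all() for d in interior)

    def test_unlabeled_pixels_skipped(self):
        crop = np.full((10, 10), 50)
        roi = make_roi(crop, lesion=np.zeros((10, 10)))
        roi.labels[:5] = 0  # half the crop outside any region
        assert len(extract_patches(roi)) == 50

    def test_region_carried_from_center_pixel(self, disk_roi):
        patches = extract_patches(disk_roi)
        assert (patches.regions == disk_roi.labels[disk_roi.labels > 0]).sum() == len(patches)


class TestFilterPatches:
    @pytest.mark.parametrize("n_nonzero,kept", [(15, False), (16, True), (49, True)])
    def test_strict_threshold(self, n_nonzero, kept):
        descriptor = np.zeros(49)
        descriptor[:n_nonzero] = 5.0
        patches = PatchSet(
            descriptors=descriptor[None, :],
            centers=np.zeros((1, 2), int),
            regions=np.ones(1, int),
            patch_size=7,
        )
        assert len(filter_patches(patches)) == (1 if kept else 0)

    def test_all_nonzero_crop_keeps_everything(self):
        roi = make_roi(np.full((12, 12), 80), lesion=np.ones((12, 12)))
        patches = extract_patches(roi)
        # corner windows are zero-padded below the threshold; interior survives
        kept = filter_patches(patches)
        full = patches.descriptors[(patches.descriptors != 0).sum(axis=1) > 15]
        assert len(kept) == len(full) > 0


class TestCodebook:
    def test_two_blob_centroids(self):
        rng = np.random.default_rng(0)
        blobs = np.vstack(
            [rng.normal(50.0, 0.5, (400, 49)), rng.normal(200.0, 0.5, (400, 49))]
        )
        codebook = train_codebook(blobs, n_words=2, seed=0)
        means = np.sort(codebook.words.mean(axis=1))
        assert abs(means[0] - 50.0) < 1.0 and abs(means[1] - 200.0) < 1.0

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 256, (500, 49)).astype(float)
        a = train_codebook(data, n_words=8, seed=3)
        b = train_codebook(data, n_words=8, seed=3)
        assert (a.words == b.words).all()

    def test_too_few_distinct_descriptors(self):
        data = np.tile(np.arange(49.0), (100, 1))  # one distinct descriptor
        with pytest.raises(ValueError, match="smaller"):
            train_codebook(data, n_words=4, seed=0)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        codebook = train_codebook(rng.integers(0, 256, (300, 49)).astype(float),
                                  n_words=4, seed=0)
        codebook.save(tmp_path / "cb.npz")
        loaded = Codebook.load(tmp_path / "cb.npz")
        assert (loaded.words == codebook.words).all()
        assert loaded.patch_size == 7


class TestAssignment:
    def test_exact_word_and_tie_rule(self):
        words = np.zeros((5, 2))
        words[1] = [4, 0]
        words[3] = [10, 10]
        words[4] = [0, 4]  # same distance from [2,2] as word 1
        codebook = _codebook(words)
        assert assign_codeword(words[3], codebook) == 3
        assert assign_codeword(np.array([2.0, 2.0]), codebook) == 0  # ties -> lowest
        assert assign_codeword(np.array([3.0, 0.0]), codebook) == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        words = rng.integers(0, 256, (32, 49)).astype(float)
        descriptors = rng.integers(0, 256, (1000, 49)).astype(float)
        codebook = _codebook(words)
        fast = assign_codewords(descriptors, codebook)
        for i in range(len(descriptors)):
            dists = [np.linalg.norm(descriptors[i] - w) for w in words]
            assert fast[i] == int(np.argmin(dists))

    def test_duplicate_word_at_higher_index_never_wins(self):
        rng = np.random.default_rng(5)
        words = rng.integers(0, 256, (8, 49)).astype(float)
        dup = np.vstack([words, words[2]])
        descriptors = rng.integers(0, 256, (200, 49)).astype(float)
        assert (
            assign_codewords(descriptors, _codebook(words))
            == assign_codewords(descriptors, _codebook(dup))
        ).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            assign_codeword(np.zeros(10), _codebook(np.zeros((3, 49))))


class TestRegionHistogram:
    def _patches(self, descriptors, regions):
        descriptors = np.asarray(descriptors, float)
        return PatchSet(
            descriptors=descriptors,
            centers=np.zeros((len(descriptors), 2), int),
            regions=np.asarray(regions),
            patch_size=7,
        )

    def test_counting_example(self):
        words = np.arange(8)[:, None] * np.ones((8, 49)) * 10
        codebook = _codebook(words)
        patches = self._patches([words[2], words[2], words[5]], [1, 1, 1])
        hist = region_histogram(patches, 1, codebook)
        assert hist.n_patches == 3
        expected = np.zeros(8)
        expected[2], expected[5] = 2 / 3, 1 / 3
        assert np.allclose(hist.x, expected)

    def test_empty_region_is_zero_vector(self):
        codebook = _codebook(np.zeros((8, 49)))
        hist = region_histogram(self._patches(np.zeros((0, 49)), []), 2, codebook)
        assert hist.n_patches == 0 and (hist.x == 0).all()

    def test_nonempty_histogram_sums_to_one(self, disk_roi):
        rng = np.random.default_rng(6)
        codebook = _codebook(rng.integers(0, 256, (16, 49)))
        patches = filter_patches(extract_patches(disk_roi))
        for region in range(1, 5):
            hist = region_histogram(patches, region, codebook)
            if hist.n_patches:
                assert np.isclose(hist.x.sum(), 1.0)


class TestBowFeature:
    def test_dimension_is_regions_plus_one_times_words(self, disk_roi):
        rng = np.random.default_rng(7)
        codebook = _codebook(rng.integers(0, 256, (8, 49)))
        feat = bow_feature(disk_roi, codebook)
        assert feat.dimension == (disk_roi.s + 1) * 8
        assert feat.provenance == "regional_bow"
        # vector sums to the number of nonempty regions
        assert np.isclose(feat.values.sum(), round(feat.values.sum()))

    def test_single_region_concentrates_mass(self):
        roi = make_roi(np.full((12, 12), 100), lesion=np.ones((12, 12)), s=3)
        rng = np.random.default_rng(8)
        codebook = _codebook(rng.integers(0, 256, (8, 49)))
        feat = bow_feature(roi, codebook)
        assert np.isclose(feat.values[:8].sum(), 1.0)
        assert (feat.values[8:] == 0).all()

    def test_patch_order_invariance(self, disk_roi):
        rng = np.random.default_rng(9)
        codebook = _codebook(rng.integers(0, 256, (8, 49)))
        patches = filter_patches(extract_patches(disk_roi))
        perm = rng.permutation(len(patches))
        shuffled = PatchSet(
            descriptors=patches.descriptors[perm],
            centers=patches.centers[perm],
            regions=patches.regions[perm],
            patch_size=7,
        )
        for region in range(1, 5):
            assert np.allclose(
                region_histogram(patches, region, codebook).x,
                region_histogram(shuffled, region, codebook).x,
            )


class TestPatientFeature:
    def _feat(self, values, phase):
        return FeatureVector(np.asarray(values, float), "regional_bow", "image",
                             patient_id="P1", label="HCC", phase=phase)

    def test_mean_of_one_is_identity(self):
        out = patient_feature([self._feat([1, 2, 3], "AP")], ("AP",))
        assert (out.values == [1, 2, 3]).all()
        assert out.level == "patient"

    def test_elementwise_mean(self):
        out = patient_feature(
            [self._feat([0, 1], "AP"), self._feat([1, 0], "PVP")], ("AP", "PVP")
        )
        assert np.allclose(out.values, [0.5, 0.5])

    def test_phase_subset_averaging_counts(self):
        # a patient with 1 AP + 3 PVP + 2 DP images: the PVP feature averages
        # 3 images, AP+PVP averages 4, the triple phase averages all 6
        feats = (
            [self._feat([1.0], "AP")]
            + [self._feat([v], "PVP") for v in (2.0, 4.0, 6.0)]
            + [self._feat([v], "DP") for v in (10.0, 20.0)]
        )
        assert np.isclose(patient_feature(feats, ("PVP",)).values[0], 4.0)
        assert np.isclose(patient_feature(feats, ("AP", "PVP")).values[0], 13.0 / 4)
        assert np.isclose(patient_feature(feats, ("AP", "PVP", "DP")).values[0], 43.0 / 6)

    def test_missing_phase_raises_skip_signal(self):
        with pytest.raises(PhaseSubsetEmpty):
            patient_feature([self._feat([1.0], "AP")], ("DP",))
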