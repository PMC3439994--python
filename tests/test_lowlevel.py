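import numpy as np
import pytest

from lesionbow.lowlevel import (
    GLCM_LEVELS,
    ShapeSignature,
    all_lowlevel,
    boundary_signature,
    feature_names,
    gabor_features,
    glcm_features,
    intensity_features,
    lowlevel_feature,
    shape_features,
    wavelet_texture_features,
)
from conftest import disk_mask, make_roi


class TestIntensity:
    def test_constant_region(self):
        feats = intensity_features(make_roi(np.full((10, 10), 80), np.ones((10, 10))))
        assert np.allclose(feats, [80, 0, 0, 0, 0])

    def test_symmetric_two_point_distribution(self):
        crop = np.zeros((10, 10))
        crop[:, ::2] = 255
        feats = intensity_features(make_roi(crop, np.ones((10, 10))))
        mean, sd, entropy, skew, kurt = feats
        assert mean == 127.5 and sd == 127.5
        assert np.isclose(entropy, 1.0)  # 1 bit
        assert np.isclose(skew, 0.0)
        assert np.isclose(kurt, 1.0)  # non-excess kurtosis of a fair Bernoulli

    def test_matches_moment_oracle(self):
        rng = np.random.default_rng(0)
        crop = rng.integers(0, 256, (15, 17))
        lesion = rng.random((15, 17)) > 0.4
        lesion[7, 8] = True
        feats = intensity_features(make_roi(crop, lesion))
        v = crop[lesion].astype(float)
        assert np.isclose(feats[0], v.mean())
        assert np.isclose(feats[1], np.sqrt(((v - v.mean()) ** 2).mean()))
        assert np.isclose(feats[3], (((v - v.mean()) / v.std()) ** 3).mean())
        assert np.isclose(feats[4], (((v - v.mean()) / v.std()) ** 4).mean())

    def test_too_few_pixels_rejected(self):
        lesion = np.zeros((10, 10), bool)
        lesion[5, 5] = True
        with pytest.raises(ValueError):
            intensity_features(make_roi(np.zeros((10, 10)), lesion))


class TestGLCM:
    def test_constant_region_degenerate_stats(self):
        feats = glcm_features(make_roi(np.full((10, 10), 64), np.ones((10, 10))))
        contrast, homog, energy, corr = feats.reshape(4, 4)
        assert (contrast == 0).all()
        assert (homog == 1).all()
        assert (energy == 1).all()
        assert (corr == 0).all()  # zero marginal variance -> correlation 0

    def test_vertical_stripes_hand_oracle(self):
        # columns alternating 0 / 255 quantize to levels 0 / 31: every
        # horizontal pair differs by 31 levels, every vertical pair matches
        crop = np.tile(np.array([0, 255] * 7), (12, 1))[:, :14]
        feats = glcm_features(make_roi(crop, np.ones((12, 14)))).reshape(4, 4)
        contrast = feats[0]
        assert np.isclose(contrast[0], 31.0**2)  # 0 deg
        assert np.isclose(contrast[2], 0.0)  # 90 deg
        assert np.isclose(feats[1][2], 1.0)  # homogeneity along stripes

    def test_matches_skimage_on_full_rectangle(self):
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(1)
        crop = rng.integers(0, 256, (12, 14)).astype(np.uint8)
        mine = glcm_features(make_roi(crop, np.ones((12, 14)))).reshape(4, 4)
        q = ((crop.astype(np.int64) * GLCM_LEVELS) // 256).astype(np.uint8)
        ref = graycomatrix(q, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                           levels=GLCM_LEVELS, symmetric=True, normed=True)
        for i, stat in enumerate(("contrast", "homogeneity", "energy", "correlation")):
            assert np.allclose(mine[i], graycoprops(ref, stat)[0])

    def test_pairs_restricted_to_lesion(self):
        # bright parenchyma ring must not leak into the co-occurrence counts
        crop = np.full((12, 12), 255.0)
        lesion = np.zeros((12, 12), bool)
        lesion[4:8, 4:8] = True
        crop[lesion] = 64.0
        feats = glcm_features(make_roi(crop, lesion)).reshape(4, 4)
        assert (feats[0] == 0).all()  # constant within the lesion


class TestGabor:
    def test_output_length_and_constant_image(self):
        feats = gabor_features(make_roi(np.full((24, 24), 90), np.ones((24, 24))))
        assert feats.shape == (48,)
        means, sds = feats[0::2], feats[1::2]
        assert np.allclose(sds, 0, atol=1e-9)
        assert (means >= 0).all()

    def test_rotating_texture_permutes_orientation_blocks(self):
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[0:32, 0:32]
        stripes = (127 + 120 * np.sin(2 * np.pi * 0.2 * xx)).astype(np.uint8)
        a = gabor_features(make_roi(stripes, np.ones((32, 32)))).reshape(4, 6, 2)
        b = gabor_features(make_roi(np.rot90(stripes).copy(),
                                    np.ones((32, 32)))).reshape(4, 6, 2)
        # 90-degree rotation shifts orientation k -> k+3 (mod 6)
        assert np.allclose(a[:, :, 0], np.roll(b[:, :, 0], -3, axis=1), rtol=0.15, atol=2.0)


class TestWaveletTexture:
    def test_constant_lesion_is_zero(self):
        feats = wavelet_texture_features(make_roi(np.full((20, 20), 130),
                                                  np.ones((20, 20))))
        assert feats.shape == (12,)
        assert np.allclose(feats, 0, atol=1e-9)

    def test_contrast_scaling_homogeneity(self):
        rng = np.random.default_rng(3)
        crop = rng.integers(0, 120, (20, 22)).astype(float)
        lesion = np.ones((20, 22), bool)
        f1 = wavelet_texture_features(make_roi(crop, lesion))
        f2 = wavelet_texture_features(make_roi(2 * crop, lesion))
        assert np.allclose(f2, 2 * f1)

    def test_small_crop_padded_not_failing(self):
        lesion = np.ones((8, 9), bool)
        feats = wavelet_texture_features(make_roi(np.full((8, 9), 50), lesion))
        assert np.isfinite(feats).all()


class TestBoundarySignature:
    def test_digital_disk_radius_band(self):
        sig = boundary_signature(disk_mask(radius=10))
        assert sig.n_points == 128 and sig.S.shape == (128,)
        assert sig.S.min() >= 9.5 and sig.S.max() <= 10.5

    def test_translation_invariance(self):
        mask = disk_mask((32, 32), (16, 16), 9)
        big = np.zeros((48, 48), np.uint8)
        big[10:42, 4:36] = mask
        assert np.allclose(boundary_signature(mask).S, boundary_signature(big).S)

    def test_square_alternates_between_halfside_and_corner(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[5:15, 5:15] = 1  # side 10, half-side 5
        S = boundary_signature(mask).S
        assert np.isclose(S.min(), 5.0, atol=0.3)
        # subpixel contour chamfers the corner by half a pixel
        assert 5 * np.sqrt(2) - 0.5 <= S.max() <= 5 * np.sqrt(2) + 0.2

    def test_multi_component_uses_largest(self):
        mask = disk_mask(radius=8)
        mask[1, 1] = 1  # stray speck
        with pytest.warns(UserWarning, match="largest"):
            sig = boundary_signature(mask)
        assert sig.S.max() < 12

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            boundary_signature(np.zeros((10, 10), np.uint8))


class TestShapeFeatures:
    def _sig(self, S):
        S = np.asarray(S, float)
        return ShapeSignature(S=S, boundary=np.zeros((len(S), 2)),
                              centroid=(0.0, 0.0), n_points=len(S))

    def test_constant_signature(self):
        feats = shape_features(self._sig(np.full(128, 7.0)))
        assert feats.shape == (12,)
        assert feats[0] > 0  # approximation mean carries the radius
        assert np.allclose(feats[2:], 0, atol=1e-9)  # all detail stats vanish

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(4)
        S = 10 + rng.random(128)
        f1 = shape_features(self._sig(S))
        f3 = shape_features(self._sig(3 * S))
        assert np.allclose(f3[0::2], 3 * f1[0::2])  # means scale linearly
        assert np.allclose(f3[1::2], 9 * f1[1::2])  # variances scale quadratically

    def test_short_signature_rejected(self):
        with pytest.raises(ValueError):
            shape_features(self._sig(np.ones(16)))


class TestFullBank:
    def test_93_values_groups_and_determinism(self, disk_roi):
        block = all_lowlevel(disk_roi)
        concat = block.concat
        assert concat.shape == (93,)
        assert np.isfinite(concat).all()
        assert np.allclose(concat[:5], intensity_features(disk_roi))
        assert np.allclose(concat[5:21], glcm_features(disk_roi))
        assert np.allclose(concat[21:69], gabor_features(disk_roi))
        assert np.allclose(concat[69:81], wavelet_texture_features(disk_roi))
        assert np.allclose(concat[81:], shape_features(boundary_signature(disk_roi.lesion_mask)))
        assert np.allclose(all_lowlevel(disk_roi).concat, concat)

    def test_translation_invariance_of_bank(self):
        rng = np.random.default_rng(5)
        from lesionbow.io import LesionMask, PhaseImage
        from lesionbow.partition import build_roi

        texture = rng.integers(60, 200, (96, 96)).astype(np.uint8)
        mask = np.zeros((96, 96), np.uint8)
        mask[30:50, 30:50] = disk_mask((20, 20), (10, 10), 8)
        image = PhaseImage(texture, "AP", "P1")
        f1 = all_lowlevel(build_roi(image, LesionMask(mask), s=3)).concat

        shifted_mask = np.roll(np.roll(mask, 17, axis=0), -12, axis=1)
        shifted_img = PhaseImage(np.roll(np.roll(texture, 17, axis=0), -12, axis=1), "AP", "P1")
        f2 = all_lowlevel(build_roi(shifted_img, LesionMask(shifted_mask), s=3)).concat
        assert np.allclose(f1, f2)

    def test_finite_across_phantom_rois(self, phantom_manifest):
        import lesionbow as lb

        recs = lb.read_manifest(phantom_manifest)[::10]  # subsample for speed
        for rec in recs:
            image = lb.load_image(rec)
            roi = lb.build_roi(image, lb.load_mask(rec, image), s=3, label=rec.label)
            assert np.isfinite(lowlevel_feature(roi).values).all()

    def test_feature_names_align(self):
        names = feature_names()
        assert len(names) == 93
        assert names[0] == "intensity_mean" and names[5].startswith("glcm_")
        assert names[21].startswith("gabor_") and names[69].startswith("wavelet_")
        assert names[81].startswith("shape_")
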