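"""Profile extraction, moment features, sliding Mahalanobis and border calls."""

import numpy as np
import pytest
from scipy import stats

from negmap import (ContourPair, GLIImage, VolumeGrid, area_volume,
                    asymmetry_test, border_detection_pipeline, build_prob_map,
                    detect_borders, extract_profiles, features_matrix,
                    gen_histology_phantom, gen_volume, profile_features,
                    sliding_mahalanobis, standardize_features)
from negmap.synthdata import (HistologyPhantomSpec, default_templates,
                              laminar_template)


def brute_force_distance(X, b):
    """Independent double-loop reference for the sliding D^2 curve."""
    n, p = X.shape
    out = []
    for x in range(b, n - b + 1):
        X1, X2 = X[x - b:x], X[x:x + b]
        S = ((b - 1) * np.cov(X1, rowvar=False, ddof=1)
             + (b - 1) * np.cov(X2, rowvar=False, ddof=1)) / (2 * b - 2)
        d = X1.mean(0) - X2.mean(0)
        out.append(float(d @ np.linalg.inv(S) @ d))
    return np.array(out)


class TestExtractProfiles:
    def test_uniform_image_constant_profiles(self):
        img = GLIImage(np.full((50, 30), 0.4), 20.0)
        contours = ContourPair(np.array([[0.0, 5.0], [29.0, 5.0]]),
                               np.array([[0.0, 44.0], [29.0, 44.0]]))
        profs = extract_profiles(img, contours, spacing_um=20.0)
        assert np.allclose(profs, 0.4)

    def test_profile_count_is_floor_L_over_s_plus_1(self):
        img = GLIImage(np.full((50, 30), 0.4), 10.0)
        contours = ContourPair(np.array([[0.0, 5.0], [29.0, 5.0]]),
                               np.array([[0.0, 44.0], [29.0, 44.0]]))
        # arc length 29 px * 10 um = 290 um; spacing 40 um -> floor+1 = 8
        profs = extract_profiles(img, contours, spacing_um=40.0)
        assert profs.shape[0] == int(np.floor(290.0 / 40.0)) + 1

    def test_phantom_profiles_match_template_within_1pct(self):
        spec = HistologyPhantomSpec(noise_sd=0.0,
                                    templates=(laminar_template(n=256),),
                                    borders=())
        img, _ = gen_histology_phantom(spec, 0)
        profs = extract_profiles(img, spec.contours(),
                                 spacing_um=spec.pixel_size_um)
        template = np.interp(np.linspace(0, 1, 100),
                             np.linspace(0, 1, 256), laminar_template(n=256))
        assert np.max(np.abs(profs - template)) < 0.01

    def test_traverse_leaving_image_raises(self):
        img = GLIImage(np.full((20, 20), 0.5), 20.0)
        contours = ContourPair(np.array([[0.0, 2.0], [19.0, 2.0]]),
                               np.array([[0.0, 30.0], [19.0, 30.0]]))
        with pytest.raises(ValueError, match="traverse"):
            extract_profiles(img, contours, spacing_um=20.0)


class TestProfileFeatures:
    def test_symmetric_peak_centroid_50_skew_0(self):
        prof = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        f = profile_features(prof)
        assert f[1] == pytest.approx(50.0)   # centroid depth %
        assert f[3] == pytest.approx(0.0, abs=1e-12)  # skewness

    def test_hand_computed_moments_for_impulse(self):
        f = profile_features(np.array([0.0, 0.0, 1.0, 0.0, 0.0]))
        assert f[0] == pytest.approx(0.2)    # mean amplitude
        assert f[2] == pytest.approx(0.0)    # all mass at one depth: SD 0
        # |gradient| of the impulse: mass at depths 25 and 75, centroid 50
        assert f[5] == pytest.approx(np.mean([0, 0.02, 0.0, 0.02, 0]))
        assert f[6] == pytest.approx(50.0)
        assert f[7] == pytest.approx(25.0)   # SD of {25, 75} mass

    def test_constant_profile_flagged(self):
        with pytest.warns(RuntimeWarning):
            f = profile_features(np.full(50, 0.3))
        assert np.all(np.isfinite(f))

    def test_standardized_features_invariant_to_amplitude_scaling(self):
        rng = np.random.default_rng(0)
        profs = 0.3 + 0.1 * rng.random((30, 100))
        z1 = standardize_features(features_matrix(profs))
        z2 = standardize_features(features_matrix(profs * 1.7))
        assert np.allclose(z1, z2, atol=1e-8)

    def test_standardization_idempotent(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 10))
        z = standardize_features(X)
        assert np.allclose(standardize_features(z), z, atol=1e-12)


class TestSlidingMahalanobis:
    def test_identical_blocks_zero(self):
        half = np.random.default_rng(0).normal(size=(10, 5))
        X = np.vstack([half, half])  # two halves identical vector-by-vector
        dp = sliding_mahalanobis(X, 10)
        mid = np.where(dp.positions == 10)[0][0]
        assert dp.d2[mid] == pytest.approx(0.0, abs=1e-18)

    def test_one_dimensional_hand_computation(self):
        X = np.array([[0.1], [-0.1], [0.0], [1.1], [0.9], [1.0]])
        dp = sliding_mahalanobis(X, 3)
        s2 = (np.var([0.1, -0.1, 0.0], ddof=1)
              + np.var([1.1, 0.9, 1.0], ddof=1)) / 2
        assert dp.d2[np.where(dp.positions == 3)[0][0]] == pytest.approx(
            1.0 / s2)

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        dp = sliding_mahalanobis(X, 8)
        ref = brute_force_distance(X, 8)
        assert np.allclose(dp.d2, ref, rtol=1e-10)

    def test_hotelling_p_matches_direct_f_transform(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        b, p = 6, 4
        dp = sliding_mahalanobis(X, b)
        t2 = (b * b / (2 * b)) * dp.d2
        f = (2 * b - p - 1) / (p * (2 * b - 2)) * t2
        assert np.allclose(dp.p, stats.f.sf(f, p, 2 * b - p - 1))

    def test_singular_covariance_ridge_flagged(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(30, 3))
        X = np.hstack([base, base])  # duplicated columns: singular covariance
        with pytest.warns(RuntimeWarning):  # blocksize below feature dim / 2
            dp = sliding_mahalanobis(X, 2)
        assert dp.regularized
        assert np.all(np.isfinite(dp.d2))


class TestDetectBorders:
    def test_single_border_recovered(self):
        spec = HistologyPhantomSpec()
        for seed in range(5):
            img, (true_b,) = gen_histology_phantom(spec, 50 + seed)
            profs = extract_profiles(img, spec.contours(),
                                     spacing_um=spec.pixel_size_um)
            calls = border_detection_pipeline(profs)
            assert len(calls.borders) == 1
            assert abs(calls.borders[0] - true_b) <= 2

    def test_two_borders_recovered_ordered(self):
        t1, t2 = default_templates()
        t3 = laminar_template(layer4_amp=0.45, deep_amp=0.05)
        spec = HistologyPhantomSpec(n_traverses=110, templates=(t1, t2, t3),
                                    borders=(36, 73))
        img, _ = gen_histology_phantom(spec, 1)
        profs = extract_profiles(img, spec.contours(),
                                 spacing_um=spec.pixel_size_um)
        calls = border_detection_pipeline(profs)
        assert len(calls.borders) == 2
        assert abs(calls.borders[0] - 36) <= 2
        assert abs(calls.borders[1] - 73) <= 2

    def test_homogeneous_phantom_rarely_calls_borders(self):
        spec = HistologyPhantomSpec(templates=(laminar_template(),),
                                    borders=())
        called = 0
        for seed in range(15):
            img, _ = gen_histology_phantom(spec, 700 + seed)
            profs = extract_profiles(img, spec.contours(),
                                     spacing_um=spec.pixel_size_um)
            called += len(border_detection_pipeline(profs).borders) > 0
        assert called <= 1

    def test_d2_at_border_grows_with_template_separation(self):
        d2_at_border = []
        for sep in (0.3, 0.6, 1.0):
            spec = HistologyPhantomSpec(templates=default_templates(sep))
            img, (b,) = gen_histology_phantom(spec, 9)
            profs = extract_profiles(img, spec.contours(),
                                     spacing_um=spec.pixel_size_um)
            feats = standardize_features(features_matrix(profs))
            dp = sliding_mahalanobis(feats, 12)
            d2_at_border.append(dp.d2[np.where(dp.positions == b)[0][0]])
        assert d2_at_border[0] < d2_at_border[1] < d2_at_border[2]

    def test_needs_three_blocksizes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        with pytest.raises(ValueError):
            detect_borders([sliding_mahalanobis(X, 8)])


class TestVolumesAndMaps:
    def test_area_volume_single_section(self):
        assert area_volume([10.0], thickness_um=1000.0, interval=1) == 10.0

    def test_area_volume_shrinkage_linearity(self):
        v1 = area_volume([1.0, 2.0], 20.0, 15, shrinkage_factor=1.0)
        v2 = area_volume([1.0, 2.0], 20.0, 15, shrinkage_factor=2.0)
        assert v2 == pytest.approx(2 * v1)

    def test_area_volume_three_sections_arithmetic(self):
        assert area_volume([1.0, 2.0, 3.0], thickness_um=20.0,
                           interval=15) == pytest.approx(1.8)

    def test_area_volume_empty_raises(self):
        with pytest.raises(ValueError):
            area_volume([], 20.0, 15)

    def test_prob_map_identical_masks(self):
        mask = gen_volume((6, 6, 6), blobs=[{"center": (3, 3, 3), "radius": 2}])
        pm = build_prob_map([mask] * 10)
        assert np.array_equal(pm.data[mask.data > 0], np.ones(mask.count_nonzero()))

    def test_prob_map_9_of_10(self):
        present = gen_volume((4, 4, 4), blobs=[{"voxels": [(1, 1, 1)]}])
        absent = gen_volume((4, 4, 4))
        pm = build_prob_map([present] * 9 + [absent])
        assert pm.data[1, 1, 1] == pytest.approx(0.9)

    def test_prob_map_conservation_identity(self, rng):
        grids = []
        for _ in range(7):
            data = (rng.random((5, 5, 5)) > 0.6).astype(float)
            grids.append(VolumeGrid(data, np.diag([2.0, 2.0, 2.0, 1.0])))
        pm = build_prob_map(grids)
        vox = pm.voxel_volume_mm3
        mean_indiv = np.mean([g.count_nonzero() * vox for g in grids])
        assert pm.data.sum() * vox == pytest.approx(mean_indiv, rel=1e-12)

    def test_prob_map_misaligned_raises(self):
        a = VolumeGrid(np.zeros((4, 4, 4)), np.eye(4))
        b = VolumeGrid(np.zeros((4, 4, 4)), np.diag([2.0, 2.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            build_prob_map([a, b])

    def test_asymmetry_identical_hemispheres(self):
        res = asymmetry_test([400.0, 420.0, 380.0], [400.0, 420.0, 380.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_asymmetry_swap_negates(self, rng):
        left = rng.normal(421, 146, 10)
        right = rng.normal(354, 129, 10)
        r1 = asymmetry_test(left, right)
        r2 = asymmetry_test(right, left)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_asymmetry_null_calibrated(self):
        rng = np.random.default_rng(0)
        rej = 0
        n_sim = 300
        for _ in range(n_sim):
            left = rng.normal(400, 100, 10)
            right = rng.normal(400, 100, 10)
            rej += asymmetry_test(left, right).p < 0.05
        assert 0.02 <= rej / n_sim <= 0.08
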