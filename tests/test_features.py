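import numpy as np
import pytest

import _oracles as oracle
from conftest import digital_ball, random_roi, volume_from

from pcrad.features import (
    extract_features,
    gldm_dependence_variance,
    glrlm_lrhgle,
    glszm_hglze,
    kurtosis,
    sphericity,
)
from pcrad.image import BinaryMask, DiscretizedROI
from pcrad.synthetic import PhantomSpec, generate_phantom


class TestSphericity:
    def test_digital_ball_near_one(self):
        ball = digital_ball(20)
        assert 0.97 <= sphericity(ball) <= 1.001

    def test_scale_invariance(self):
        ball = digital_ball(8)
        s1 = sphericity(ball, (1.0, 1.0, 1.0))
        s2 = sphericity(ball, (2.0, 2.0, 2.0))
        assert s1 == pytest.approx(s2, rel=1e-4)

    def test_rod_less_spherical_than_ball(self):
        rod = np.zeros((24, 3, 3), bool)
        rod[2:22, 1, 1] = True
        assert sphericity(BinaryMask(rod, (1, 1, 1))) < sphericity(digital_ball(8))

    def test_single_voxel_valid_mesh(self):
        single = np.zeros((3, 3, 3), bool)
        single[1, 1, 1] = True
        s = sphericity(BinaryMask(single, (1, 1, 1)))
        assert 0.0 < s <= 1.001


class TestKurtosis:
    def test_hand_computed_four_values(self):
        # {1,2,3,4}: m2 = 1.25, m4 = 2.5625 -> 2.5625/1.5625 = 1.64
        vol = volume_from(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4))
        mask = BinaryMask(np.ones((1, 1, 4), bool), (1, 1, 1))
        assert kurtosis(vol, mask) == pytest.approx(1.64)

    def test_gaussian_limit(self, rng):
        x = rng.standard_normal((100, 100, 100))
        mask = BinaryMask(np.ones(x.shape, bool), (1, 1, 1))
        assert kurtosis(volume_from(x), mask) == pytest.approx(3.0, abs=0.02)

    def test_affine_invariance(self, rng):
        x = rng.random((5, 5, 5))
        mask = BinaryMask(np.ones(x.shape, bool), (1, 1, 1))
        k1 = kurtosis(volume_from(x), mask)
        k2 = kurtosis(volume_from(3.2 * x + 11.0), mask)
        assert k1 == pytest.approx(k2, rel=1e-10)

    def test_zero_variance_rejected(self):
        vol = volume_from(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            kurtosis(vol, BinaryMask(np.ones((2, 2, 2), bool), (1, 1, 1)))


class TestGLDM:
    def test_singleton_roi(self):
        levels = np.zeros((3, 3, 3), np.int64)
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        levels[1, 1, 1] = 2
        roi = DiscretizedROI(levels, mask, 4)
        assert gldm_dependence_variance(roi) == 0.0

    def test_constant_cube_matches_neighbor_count_variance(self):
        levels = np.full((3, 3, 3), 3, np.int64)
        mask = np.ones((3, 3, 3), bool)
        roi = DiscretizedROI(levels, mask, 4)
        got = gldm_dependence_variance(roi)
        expected = oracle.gldm_dependence_variance(levels, mask)
        assert got == pytest.approx(expected)
        # corner has 8 in-mask neighbors (dependence 9), center 27
        deps = [1 + sum(1 for d in oracle.NEIGHBORS_26
                        if all(0 <= v + dd < 3 for v, dd in zip(idx, d)))
                for idx in np.ndindex(3, 3, 3)]
        assert got == pytest.approx(np.var(deps))

    def test_alpha_tolerance_counts_near_levels(self):
        levels = np.array([[[1, 2, 4]]], np.int64)
        mask = np.ones((1, 1, 3), bool)
        roi = DiscretizedROI(levels, mask, 4)
        assert gldm_dependence_variance(roi, alpha=0) == pytest.approx(
            oracle.gldm_dependence_variance(levels, mask, alpha=0)
        )
        assert gldm_dependence_variance(roi, alpha=1) == pytest.approx(
            oracle.gldm_dependence_variance(levels, mask, alpha=1)
        )

    def test_neighbors_only_convention(self, roi_factory):
        roi = roi_factory()
        got = gldm_dependence_variance(roi, count_center=False)
        expected = oracle.gldm_dependence_variance(roi.levels, roi.mask, count_center=False)
        assert got == pytest.approx(expected)


class TestGLRLM:
    def test_hand_enumerated_line(self):
        # [1,1,2] along x: runs {(1,2),(2,1)} -> (1*4 + 4*1)/2 = 4 in that
        # direction; other directions contribute all-length-1 runs
        levels = np.array([[[1, 1, 2]]], np.int64)
        mask = np.ones((1, 1, 3), bool)
        roi = DiscretizedROI(levels, mask, 2)
        from pcrad.features import _runs_along

        lv, ln = _runs_along(levels, mask, (0, 0, 1))
        runs = sorted(zip(lv.tolist(), ln.tolist()))
        assert runs == [(1, 2), (2, 1)]
        stat = np.mean([i * i * j * j for i, j in runs])
        assert stat == 4.0

    def test_all_distinct_levels_only_unit_runs(self):
        levels = (np.arange(8, dtype=np.int64) + 1).reshape(2, 2, 2)
        mask = np.ones((2, 2, 2), bool)
        roi = DiscretizedROI(levels, mask, 8)
        # every run has length 1 in every direction: statistic = mean of i^2
        assert glrlm_lrhgle(roi) == pytest.approx(np.mean((np.arange(8) + 1.0) ** 2))

    def test_matches_scanner_oracle_on_random_roi(self, roi_factory):
        for _ in range(5):
            roi = roi_factory(max_side=4)
            assert glrlm_lrhgle(roi) == pytest.approx(
                oracle.glrlm_lrhgle(roi.levels, roi.mask)
            )


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        levels = np.full((3, 4, 2), 5, np.int64)
        mask = np.ones((3, 4, 2), bool)
        roi = DiscretizedROI(levels, mask, 8)
        assert glszm_hglze(roi) == 25.0

    def test_alternating_slabs(self):
        # 1-voxel-thick slabs of levels 1/2 along z: each slab is one zone
        levels = np.zeros((4, 3, 3), np.int64)
        for z in range(4):
            levels[z] = 1 if z % 2 == 0 else 2
        mask = np.ones((4, 3, 3), bool)
        roi = DiscretizedROI(levels, mask, 2)
        # zones: two level-1 slabs and two level-2 slabs -> mean of {1,1,4,4}
        assert glszm_hglze(roi) == pytest.approx(2.5)

    def test_matches_flood_fill_oracle_on_random_roi(self, roi_factory):
        for _ in range(5):
            roi = roi_factory(max_side=4)
            assert glszm_hglze(roi) == pytest.approx(
                oracle.glszm_hglze(roi.levels, roi.mask)
            )


class TestTextureProperties:
    """Invariants of the texture matrices on 100 random small ROIs."""

    def test_brute_force_equality_and_mass_conservation(self):
        from pcrad.features import DIRECTIONS_13, _runs_along
        from scipy import ndimage

        rng = np.random.default_rng(7)
        for _ in range(100):
            roi = random_roi(rng, max_side=5)
            nv = roi.n_voxels
            assert gldm_dependence_variance(roi) == pytest.approx(
                oracle.gldm_dependence_variance(roi.levels, roi.mask)
            )
            assert glrlm_lrhgle(roi) == pytest.approx(
                oracle.glrlm_lrhgle(roi.levels, roi.mask)
            )
            assert glszm_hglze(roi) == pytest.approx(
                oracle.glszm_hglze(roi.levels, roi.mask)
            )
            # run lengths of each direction partition the masked voxels
            for d in DIRECTIONS_13:
                _, lengths = _runs_along(roi.levels, roi.mask, d)
                assert lengths.sum() == nv
            # zone sizes partition the masked voxels
            assert sum(s for _, s in oracle.glszm_zones(roi.levels, roi.mask)) == nv


@pytest.fixture(scope="module")
def phantoms():
    sphere = PhantomSpec(grid_shape=(36, 36, 36), semi_axes=(10, 10, 10),
                         texture="correlated-noise", correlation_length=2.5, seed=11)
    rod = PhantomSpec(grid_shape=(44, 24, 24), semi_axes=(18, 3, 3),
                      texture="correlated-noise", correlation_length=2.5, seed=11)
    white = PhantomSpec(grid_shape=(36, 36, 36), semi_axes=(10, 10, 10),
                        texture="correlated-noise", correlation_length=0.3, seed=11)
    return {name: generate_phantom(s) for name, s in
            [("sphere", sphere), ("rod", rod), ("white", white)]}


class TestExtractFeatures:
    def test_consistency_with_single_channel_calls(self, phantoms):
        dyn, sub, mask = phantoms["sphere"]
        vec = extract_features(dyn, dyn, mask)
        from pcrad.image import discretize_fixed_bin_count, normalize_intensity, resample_isotropic

        vol, msk = resample_isotropic(normalize_intensity(dyn), mask, 0.9)
        roi = discretize_fixed_bin_count(vol, msk, 8)
        assert vec.F2 == pytest.approx(kurtosis(vol, msk))
        assert vec.F4 == pytest.approx(glrlm_lrhgle(roi))
        assert vec.F5 == pytest.approx(glszm_hglze(roi))
        assert vec.F1 == pytest.approx(sphericity(msk))
        assert vec.F3 == pytest.approx(gldm_dependence_variance(roi))

    def test_long_correlation_increases_long_run_emphasis(self, phantoms):
        dyn_l, sub_l, mask_l = phantoms["sphere"]
        dyn_w, sub_w, mask_w = phantoms["white"]
        f_long = extract_features(dyn_l, sub_l, mask_l)
        f_white = extract_features(dyn_w, sub_w, mask_w)
        assert f_long.F4 > f_white.F4

    def test_sphere_more_spherical_than_rod(self, phantoms):
        dyn_s, sub_s, mask_s = phantoms["sphere"]
        dyn_r, sub_r, mask_r = phantoms["rod"]
        f_s = extract_features(dyn_s, sub_s, mask_s)
        f_r = extract_features(dyn_r, sub_r, mask_r)
        assert f_s.F1 > f_r.F1

    def test_shift_invariance_of_all_features(self, phantoms):
        from pcrad.image import ImageVolume

        dyn, sub, mask = phantoms["sphere"]
        shifted = extract_features(
            ImageVolume(dyn.values + 123.0, dyn.spacing),
            ImageVolume(sub.values + 123.0, sub.spacing),
            mask,
        )
        base = extract_features(dyn, sub, mask)
        for f in ("F1", "F2", "F3", "F4", "F5"):
            assert getattr(shifted, f) == pytest.approx(getattr(base, f), rel=1e-9)
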