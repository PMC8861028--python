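"""Volumetry: reorientation, VOI, segmentation, voxel-count volumetrics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from tarsalct import (
    SegmentationParams,
    VoxelVolume,
    VOISpec,
    compute_histogram,
    extract_voi,
    find_voi_start,
    make_phantom,
    mask_volume,
    quantify,
    reorient_to_axis,
    segment_bone,
    segment_soft,
    suggest_threshold,
)
from tarsalct.errors import (
    AmbiguousAxisError,
    ContractError,
    DegenerateInputError,
    LandmarkError,
    RangeError,
    ThresholdError,
)
from tarsalct.phantom import Ellipsoid, PhantomSpec, rotated_spec
from tarsalct.volumetry import rotation_angle_deg

H = 0.018


class TestReorient:
    def test_aligned_phantom_returns_identity(self, default_phantom):
        _, vol, _ = default_phantom
        out, R = reorient_to_axis(vol, 3500.0)
        assert rotation_angle_deg(R) < 1.0
        assert out.intensities is vol.intensities  # bit-exact skip path

    def test_known_rotation_recovered_within_2_degrees(self, small_phantom):
        spec, vol, _ = small_phantom
        rs = rotated_spec(spec, (1.0, 0.0, 0.0), 30.0)
        rvol, _ = make_phantom(rs, seed=0)
        _, R = reorient_to_axis(rvol, 3500.0)
        # recovered o applied should be the identity (up to roll about z,
        # which is zero for a rotation about x)
        residual = rotation_angle_deg(R @ rs.rotation.matrix)
        assert residual < 2.0

    def test_reorientation_preserves_bone_volume(self, small_phantom):
        spec, vol, _ = small_phantom
        bv0 = quantify(vol, VOISpec(n_slices=60)).bone_volume_mm3
        rs = rotated_spec(spec, (1.0, 0.0, 0.0), 30.0)
        rvol, _ = make_phantom(rs, seed=0)
        bv1 = quantify(rvol, VOISpec(n_slices=60)).bone_volume_mm3
        assert bv1 == pytest.approx(bv0, rel=0.03)

    def test_uniform_ball_is_ambiguous(self):
        spec = PhantomSpec(
            grid_shape=(40, 40, 40),
            spacing=(H, H, H),
            bones=(Ellipsoid((0.36,) * 3, (0.25,) * 3, 6700.0),),
            noise_sd=0.0,
        )
        vol, _ = make_phantom(spec, seed=0)
        with pytest.raises(AmbiguousAxisError):
            reorient_to_axis(vol, 3500.0)

    def test_too_little_foreground_is_degenerate(self):
        vol = VoxelVolume(np.full((10, 10, 10), -900.0), (H, H, H))
        with pytest.raises(DegenerateInputError):
            reorient_to_axis(vol, 3500.0)


class TestVOI:
    def test_100_slices_at_18um_is_1p8_mm(self, default_phantom):
        _, vol, truth = default_phantom
        slab = extract_voi(vol, VOISpec(start_slice=truth.landmark_slice, n_slices=100))
        assert slab.n_slices * slab.spacing[2] == pytest.approx(1.8, abs=1e-12)

    def test_full_extent_crop_is_identity(self, small_phantom):
        _, vol, _ = small_phantom
        slab = extract_voi(vol, VOISpec(start_slice=0, n_slices=vol.n_slices))
        np.testing.assert_array_equal(slab.intensities, vol.intensities)

    def test_crop_commutes_with_ground_truth_mask(self, small_phantom):
        _, vol, truth = small_phantom
        voi = VOISpec(start_slice=truth.landmark_slice, n_slices=30)
        slab = extract_voi(vol, voi)
        np.testing.assert_array_equal(
            segment_bone(slab, SegmentationParams()),
            truth.bone_mask[:, :, voi.start_slice : voi.start_slice + 30],
        )

    def test_out_of_bounds_voi_rejected(self, small_phantom):
        _, vol, _ = small_phantom
        with pytest.raises(RangeError):
            extract_voi(vol, VOISpec(start_slice=vol.n_slices - 5, n_slices=10))

    def test_landmark_detection_matches_generator_record(self, default_phantom):
        _, vol, truth = default_phantom
        assert find_voi_start(vol, 3500.0) == truth.landmark_slice

    def test_manual_override_wins(self, default_phantom):
        _, vol, _ = default_phantom
        assert find_voi_start(vol, 3500.0, override=55) == 55

    def test_all_air_volume_is_landmark_error(self):
        vol = VoxelVolume(np.full((8, 8, 20), -900.0), (H, H, H))
        with pytest.raises(LandmarkError):
            find_voi_start(vol, 3500.0)


class TestHistogramAndThreshold:
    def test_constant_volume_occupies_single_bin(self):
        vol = VoxelVolume(np.full((5, 5, 5), 300.0), (H, H, H))
        counts, _ = compute_histogram(vol, bins=16)
        assert (counts > 0).sum() == 1
        assert counts.sum() == 125

    def test_noiseless_phantom_has_three_intensity_levels(self, default_phantom):
        _, vol, _ = default_phantom
        assert set(np.unique(vol.intensities)) == {-900.0, 300.0, 6700.0}
        counts, _ = compute_histogram(vol, bins=64)
        assert counts.sum() == vol.intensities.size

    def test_two_value_histogram_splits_between(self):
        vals = np.array([300.0] * 50 + [5000.0] * 50).reshape(2, 5, 10)
        counts, edges = compute_histogram(VoxelVolume(vals, (H, H, H)), bins=32)
        t = suggest_threshold((counts, edges))
        assert 300.0 < t < 5000.0

    def test_noisy_phantom_threshold_separates_soft_from_bone(self, noisy_small_phantom):
        _, vol, truth = noisy_small_phantom
        hist = compute_histogram(vol, bins=256)
        t = suggest_threshold(hist)
        assert 1500.0 <= t <= 4000.0
        mask = vol.intensities > t
        disagree = np.count_nonzero(mask ^ truth.bone_mask)
        assert disagree < 0.01 * truth.bone_mask.sum()

    def test_degenerate_histogram_rejected(self):
        vol = VoxelVolume(np.full((4, 4, 4), 300.0), (H, H, H))
        with pytest.raises(ThresholdError):
            suggest_threshold(compute_histogram(vol, bins=8))


class TestSegmentation:
    def test_exactly_3500_is_not_bone(self):
        vol = VoxelVolume(np.full((4, 4, 4), 3500.0), (H, H, H))
        assert not segment_bone(vol, SegmentationParams()).any()

    def test_noiseless_phantom_bone_mask_matches_ground_truth(self, default_phantom):
        _, vol, truth = default_phantom
        np.testing.assert_array_equal(
            segment_bone(vol, SegmentationParams()), truth.bone_mask
        )

    def test_raised_threshold_empties_mask(self, default_phantom):
        _, vol, _ = default_phantom
        params = SegmentationParams(bone_threshold=6800.0)
        assert not segment_bone(vol, params).any()

    def test_uniform_soft_volume_fully_masked(self):
        vol = VoxelVolume(np.full((20, 20, 20), 300.0), (H, H, H))
        mask = segment_soft(vol, SegmentationParams(), np.zeros((20, 20, 20), bool))
        assert mask.all()

    def test_zero_smoothing_is_pure_range_threshold(self, noisy_small_phantom):
        _, vol, _ = noisy_small_phantom
        params = SegmentationParams(smoothing_sd=0.0, exclude_bone_from_soft=False)
        mask = segment_soft(vol, params, np.zeros(vol.shape, bool))
        expected = (vol.intensities >= -300.0) & (vol.intensities <= 1500.0)
        np.testing.assert_array_equal(mask, expected)

    def test_shape_mismatch_is_contract_error(self, small_phantom):
        _, vol, _ = small_phantom
        with pytest.raises(ContractError):
            segment_soft(vol, SegmentationParams(), np.zeros((2, 2, 2), bool))

    def test_soft_mask_close_to_truth_and_localized_at_interfaces(self, default_phantom):
        _, vol, truth = default_phantom
        res = quantify(vol)
        v = res.voi_used
        crop = np.s_[:, :, v.start_slice : v.start_slice + v.n_slices]
        gt_soft, gt_bone = truth.soft_mask[crop], truth.bone_mask[crop]
        diff = res.soft_mask ^ gt_soft
        assert diff.sum() <= 0.03 * gt_soft.sum()
        # disagreements confined to within 0.4 mm of a tissue interface
        air = ~(gt_soft | gt_bone)
        near_bone = ndimage.distance_transform_edt(~gt_bone, sampling=vol.spacing) <= 0.4
        near_air = ndimage.distance_transform_edt(~air, sampling=vol.spacing) <= 0.4
        assert not np.any(diff & ~(near_bone | near_air))

    def test_bone_and_soft_masks_disjoint(self, default_quantified):
        res = default_quantified
        assert not np.any(res.bone_mask & res.soft_mask)

    def test_invalid_params_rejected(self):
        with pytest.raises(RangeError):
            SegmentationParams(soft_low=2000.0)
        with pytest.raises(RangeError):
            SegmentationParams(smoothing_sd=-0.1)


class TestMaskVolume:
    def test_empty_mask_is_zero(self):
        assert mask_volume(np.zeros((5, 5, 5), bool), (H, H, H)) == 0.0

    def test_single_voxel_at_18um(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert mask_volume(m, (H, H, H)) == pytest.approx(5.832e-6)

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(11)
        mask = rng.random((12, 13, 14)) > 0.6
        count = 0
        for i in range(12):
            for j in range(13):
                for k in range(14):
                    if mask[i, j, k]:
                        count += 1
        assert mask_volume(mask, (H, H, H)) == count * H * H * H

    def test_non_boolean_mask_rejected(self):
        with pytest.raises(ContractError):
            mask_volume(np.zeros((2, 2, 2)), (H, H, H))


@given(
    seed=st.integers(0, 10_000),
    t1=st.floats(1600, 6600),
    t2=st.floats(1600, 6600),
)
def test_threshold_monotonicity(seed, t1, t2):
    """For t1 < t2 the bone mask at t2 is a subset of the mask at t1."""
    lo, hi = sorted((t1, t2))
    rng = np.random.default_rng(seed)
    vol = VoxelVolume(rng.normal(1000.0, 2500.0, (8, 8, 8)), (H, H, H))
    m_hi = segment_bone(vol, SegmentationParams(bone_threshold=hi))
    m_lo = segment_bone(vol, SegmentationParams(bone_threshold=lo))
    assert np.all(m_hi <= m_lo)
    assert mask_volume(m_hi, vol.spacing) <= mask_volume(m_lo, vol.spacing)


@pytest.mark.parametrize("shift", [(1, 0, 0), (0, 2, 0), (0, 0, 3), (2, 1, 3)])
def test_translation_equivariance(small_phantom, shift):
    """Whole-voxel shifts move the masks identically; volumes unchanged."""
    _, vol, _ = small_phantom
    params = SegmentationParams()
    base = segment_bone(vol, params)
    shifted = VoxelVolume(np.roll(vol.intensities, shift, axis=(0, 1, 2)), vol.spacing)
    moved = segment_bone(shifted, params)
    np.testing.assert_array_equal(moved, np.roll(base, shift, axis=(0, 1, 2)))
    assert mask_volume(moved, vol.spacing) == mask_volume(base, vol.spacing)


class TestQuantify:
    def test_noiseless_phantom_recovers_ground_truth(self, default_phantom, default_quantified):
        _, vol, truth = default_phantom
        res = default_quantified
        assert res.bone_volume_mm3 == truth.bone_volume_mm3  # exact
        v = res.voi_used
        crop = np.s_[:, :, v.start_slice : v.start_slice + v.n_slices]
        np.testing.assert_array_equal(res.bone_mask, truth.bone_mask[crop])
        gt_stv = mask_volume(truth.soft_mask[crop], vol.spacing)
        assert res.soft_volume_mm3 == pytest.approx(gt_stv, rel=0.03)

    def test_voi_used_spans_100_slices(self, default_quantified):
        assert default_quantified.voi_used.n_slices == 100

    def test_all_air_volume_is_landmark_error(self):
        vol = VoxelVolume(np.full((10, 10, 30), -900.0), (H, H, H))
        with pytest.raises(LandmarkError):
            quantify(vol)
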