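"""Profile extraction, length normalization, segments and subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatfront.dixon import FatFractionVolume, MuscleLabelMap, ValidationError
from fatfront.profiles import (
    classify_profile_shape,
    extract_profile,
    segment_means,
    select_slices,
    subsampled_ff,
    whole_muscle_ff,
)
from conftest import make_profile


def volume_with_muscle(per_slice_ff, first_slice=0, n_slices=None, width=3):
    """A volume with one square-cross-section muscle (label 1)."""
    span = len(per_slice_ff)
    n_slices = n_slices or first_slice + span + 2
    ff = np.zeros((8, 8, n_slices))
    labels = np.zeros((8, 8, n_slices), dtype=np.int16)
    for i, v in enumerate(per_slice_ff):
        ff[2:2 + width, 2:2 + width, first_slice + i] = v
        labels[2:2 + width, 2:2 + width, first_slice + i] = 1
    vol = FatFractionVolume(ff=ff)
    lmap = MuscleLabelMap(labels=labels, label_table={1: {"muscle": "m", "side": "L"}})
    return vol, lmap


class TestExtractProfile:
    def test_uniform_muscle(self):
        vol, lmap = volume_with_muscle([40.0] * 20)
        prof = extract_profile(vol, lmap, 1)
        assert prof.n_slices == 20
        np.testing.assert_allclose(prof.ff, 40.0)

    def test_relative_positions_formula(self):
        vol, lmap = volume_with_muscle(np.linspace(10, 50, 10), first_slice=10)
        prof = extract_profile(vol, lmap, 1)
        np.testing.assert_allclose(prof.relative_pos, 100.0 * np.arange(10) / 9)
        np.testing.assert_array_equal(prof.slice_indices, np.arange(10, 20))

    def test_single_slice_rejected(self):
        vol, lmap = volume_with_muscle([40.0])
        with pytest.raises(ValidationError, match="m"):
            extract_profile(vol, lmap, 1)

    def test_absent_muscle_rejected(self):
        vol, lmap = volume_with_muscle([40.0] * 5)
        with pytest.raises(ValidationError):
            extract_profile(vol, lmap, 7)

    def test_interior_hole_dropped_and_positions_kept(self):
        vol, lmap = volume_with_muscle([10.0, 20.0, 30.0, 40.0, 50.0])
        lab = lmap.labels.copy()
        lab[:, :, 2] = 0  # hole in the middle of the span
        lmap2 = MuscleLabelMap(labels=lab, label_table=lmap.label_table)
        prof = extract_profile(vol, lmap2, 1)
        assert prof.n_slices == 4
        np.testing.assert_allclose(prof.relative_pos, [0.0, 25.0, 75.0, 100.0])

    def test_missing_voxels_excluded_from_slice_mean(self):
        vol, lmap = volume_with_muscle([30.0, 30.0, 30.0])
        ff = vol.ff.copy()
        ff[2, 2, 0] = np.nan
        prof = extract_profile(FatFractionVolume(ff=ff), lmap, 1)
        assert prof.ff[0] == pytest.approx(30.0)
        assert prof.n_voxels[0] == prof.n_voxels[1] - 1


class TestWholeMuscleFF:
    def test_weighted_mean(self, profile_factory):
        prof = profile_factory([10.0, 30.0], n_voxels=[100, 300])
        assert whole_muscle_ff(prof) == pytest.approx(25.0)

    def test_constant_identity(self, profile_factory):
        prof = profile_factory([17.0] * 6)
        assert whole_muscle_ff(prof) == pytest.approx(17.0)

    def test_equals_voxelwise_mean_over_mask(self):
        """The weighted per-slice mean must reproduce the brute-force mean
        over every labeled voxel of the 3-D mask."""
        rng = np.random.default_rng(42)
        ff = np.zeros((8, 8, 12))
        labels = np.zeros((8, 8, 12), dtype=np.int16)
        vals = []
        for i in range(12):
            k = rng.integers(2, 9)  # varying cross-section
            block = rng.uniform(0, 100, (k, k))
            ff[:k, :k, i] = block
            labels[:k, :k, i] = 1
            vals.append(block.ravel())
        vol = FatFractionVolume(ff=ff)
        lmap = MuscleLabelMap(labels=labels, label_table={1: {"muscle": "m", "side": "L"}})
        prof = extract_profile(vol, lmap, 1)
        oracle = np.concatenate(vals).mean()
        assert whole_muscle_ff(prof) == pytest.approx(oracle, rel=1e-9)


class TestSegmentMeans:
    def test_hand_enumerated_bins(self, profile_factory):
        prof = profile_factory([50, 50, 40, 40, 30, 30, 20, 20, 10, 10])
        seg = segment_means(prof)
        np.testing.assert_allclose(seg.means, [50, 40, 30, 20, 10])

    def test_constant_profile(self, profile_factory):
        seg = segment_means(profile_factory([25.0] * 9))
        np.testing.assert_allclose(seg.means, 25.0)

    def test_five_slices_one_per_segment(self, profile_factory):
        # positions 0, 25, 50, 75, 100 fall in bins 1..5
        seg = segment_means(profile_factory([1.0, 2.0, 3.0, 4.0, 5.0]))
        np.testing.assert_allclose(seg.means, [1, 2, 3, 4, 5])
        np.testing.assert_array_equal(seg.n_slices, 1)

    def test_too_short_rejected(self, profile_factory):
        with pytest.raises(ValidationError):
            segment_means(profile_factory([1.0, 2.0, 3.0, 4.0]))

    def test_voxel_weighting_within_segment(self, profile_factory):
        # both slices in segment 1 (n=10 -> positions 0 and 11.1)
        prof = profile_factory(
            [10.0, 40.0] + [0.0] * 8, n_voxels=[300, 100] + [50] * 8
        )
        seg = segment_means(prof)
        assert seg.means[0] == pytest.approx((10 * 300 + 40 * 100) / 400)

    def test_matches_bruteforce_assignment_on_random_profiles(self, profile_factory):
        """Oracle: loop over slices, assign each to its half-open 20%-bin,
        accumulate voxel-weighted sums."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(5, 80))
            ff = rng.uniform(0, 100, n)
            nv = rng.integers(1, 500, n)
            prof = make_profile(ff, n_voxels=nv)
            acc = np.zeros(5)
            wsum = np.zeros(5)
            for i in range(n):
                pos = 100.0 * i / (n - 1)
                s = 4 if pos >= 100.0 else int(pos // 20)
                acc[s] += ff[i] * nv[i]
                wsum[s] += nv[i]
            np.testing.assert_allclose(segment_means(prof).means, acc / wsum)


class TestSelectSlices:
    @pytest.mark.parametrize("scheme,n,expected", [
        ("central5", 11, [3, 4, 5, 6, 7]),
        ("central5", 5, [0, 1, 2, 3, 4]),
        ("central5", 6, [0, 1, 2, 3, 4]),
        ("spread5", 21, [2, 6, 10, 14, 18]),
        ("spread5", 20, [2, 6, 10, 13, 17]),
        ("spread5", 6, [1, 2, 3, 4, 5]),  # 0.5,1.5,2.5,3.5,4.5 half-away
    ])
    def test_examples(self, scheme, n, expected):
        np.testing.assert_array_equal(select_slices(scheme, n), expected)

    def test_whole_scheme(self):
        np.testing.assert_array_equal(select_slices("whole", 7), np.arange(7))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            select_slices("central5", 4)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValidationError):
            select_slices("middle3", 10)

    @settings(max_examples=196, derandomize=True)
    @given(n=st.integers(5, 200))
    def test_spread5_indices_sorted_and_in_bounds(self, n):
        idx = select_slices("spread5", n)
        assert len(idx) == 5
        assert np.all(np.diff(idx) >= 0)
        assert idx[0] >= 0 and idx[-1] < n

    @settings(max_examples=100, derandomize=True)
    @given(n=st.integers(5, 200))
    def test_central5_is_contiguous_window(self, n):
        idx = select_slices("central5", n)
        assert np.all(np.diff(idx) == 1)
        assert idx[0] == (n - 5) // 2


class TestSubsampledFF:
    def test_constant_profile_all_schemes(self, profile_factory):
        prof = profile_factory([33.0] * 15)
        for scheme in ("central5", "spread5", "whole"):
            assert subsampled_ff(prof, scheme) == pytest.approx(33.0)

    def test_central5_on_linear_profile_hits_midpoint(self, profile_factory):
        ff = np.linspace(80, 0, 21)
        prof = profile_factory(ff)
        assert subsampled_ff(prof, "central5") == pytest.approx(ff[10])

    def test_spread5_on_step_profile(self, profile_factory):
        # distal half 80, proximal half 0, N=20: indices 2,6 high; 10,13,17 low
        prof = profile_factory([80.0] * 10 + [0.0] * 10)
        assert subsampled_ff(prof, "spread5") == pytest.approx(32.0)

    def test_unweighted_vs_voxel_weighted_whole(self, profile_factory):
        """subsampled_ff('whole') is the unweighted slice mean; it matches
        whole_muscle_ff only under equal voxel counts."""
        equal = profile_factory([10.0, 20.0, 60.0, 10.0, 20.0])
        assert subsampled_ff(equal, "whole") == pytest.approx(whole_muscle_ff(equal))
        skewed = profile_factory([10.0, 20.0, 60.0, 10.0, 20.0],
                                 n_voxels=[500, 10, 10, 10, 10])
        assert subsampled_ff(skewed, "whole") != pytest.approx(whole_muscle_ff(skewed))


class TestShapeClassification:
    @pytest.mark.parametrize("means,expected", [
        ([50, 40, 30, 20, 10], "decreasing"),
        ([10, 10, 10, 10, 10], "homogeneous"),
        ([40, 20, 10, 20, 40], "u_shape"),
        ([10, 20, 30, 40, 50], "reversed"),
        ([10, 40, 10, 40, 10], "other"),
    ])
    def test_rules(self, means, expected, profile_factory):
        seg = segment_means(make_profile(np.repeat(means, 2).astype(float)))
        np.testing.assert_allclose(seg.means, means)
        assert classify_profile_shape(seg) == expected

    def test_delta_threshold(self, profile_factory):
        seg = segment_means(make_profile(np.repeat([14.0, 12, 11, 10.5, 10], 2)))
        assert classify_profile_shape(seg, delta=5) == "homogeneous"
        assert classify_profile_shape(seg, delta=2) == "decreasing"
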