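import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import aligned_max_error, run_spine_chain
from spinemetrics import SpinePhantomSpec, make_spine_phantom
from spinemetrics import spine as sp
from spinemetrics.io import Volume
from spinemetrics.spine import (
    CalibrationError,
    DegenerateInputError,
    DensityCalibration,
    FitError,
    SparseVoxelCloud,
)


class TestDownsample:
    def test_factor_one_is_identity(self):
        vol = Volume(np.random.default_rng(0).random((6, 6, 6)), (1, 1, 1))
        out = sp.downsample(vol, 1.0)
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.voxel_size_um == vol.voxel_size_um

    def test_half_factor_halves_dims_doubles_voxel(self):
        vol = Volume(np.zeros((64, 64, 64)), (2.0, 2.0, 2.0))
        out = sp.downsample(vol, 0.5)
        assert out.shape == (32, 32, 32)
        assert out.voxel_size_um == (4.0, 4.0, 4.0)

    def test_constant_volume_is_mean_preserving(self):
        vol = Volume(np.full((10, 10, 10), 7.5), (1, 1, 1))
        out = sp.downsample(vol, 0.5)
        np.testing.assert_allclose(out.data, 7.5)

    def test_block_mean_values(self):
        data = np.arange(8, dtype=float).reshape(2, 2, 2)
        out = sp.downsample(Volume(data, (1, 1, 1)), 0.5)
        assert out.data.item() == data.mean()

    @pytest.mark.parametrize("factor", [0.0, -0.1, 1.5])
    def test_bad_factor(self, factor):
        with pytest.raises(ValueError):
            sp.downsample(Volume(np.zeros((4, 4, 4)), (1, 1, 1)), factor)


class TestThresholdToCloud:
    def test_published_fraction_keeps_7_of_1000(self):
        data = np.random.default_rng(1).random((10, 10, 10))
        cloud = sp.threshold_to_cloud(Volume(data, (1, 1, 1)), 0.007)
        assert len(cloud) == 7

    def test_two_valued_volume_keeps_exactly_the_ones(self):
        data = np.zeros((10, 10, 10))
        ones = np.random.default_rng(2).random((10, 10, 10)) < 0.5
        data[ones] = 1.0
        frac = ones.sum() / data.size
        cloud = sp.threshold_to_cloud(Volume(data, (1, 1, 1)), frac)
        assert len(cloud) == ones.sum()
        assert (cloud.intensity == 1.0).all()

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 50, size=(10, 10, 10)).astype(float)  # many ties
        vol = Volume(data, (1, 1, 1))
        frac = 0.1
        cloud = sp.threshold_to_cloud(vol, frac)
        # oracle: stable sort of (-intensity, raster index), take ceil(f*n)
        flat = data.ravel()
        k = int(np.ceil(frac * flat.size))
        oracle = np.sort(np.argsort(-flat, kind="stable")[:k])
        got = np.ravel_multi_index(cloud.indices.T, data.shape)
        np.testing.assert_array_equal(np.sort(got), oracle)

    def test_constant_volume_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sp.threshold_to_cloud(Volume(np.ones((5, 5, 5)), (1, 1, 1)), 0.1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**16), st.floats(0.01, 0.9))
    def test_retained_count_property(self, seed, frac):
        data = np.random.default_rng(seed).random((6, 6, 6))
        cloud = sp.threshold_to_cloud(Volume(data, (1, 1, 1)), frac)
        assert len(cloud) == int(np.ceil(frac * data.size))
        assert cloud.intensity.min() >= np.sort(data.ravel())[::-1][len(cloud) - 1]


class TestRemoveHead:
    def test_phantom_head_fully_removed_spine_kept(self, curved_phantom):
        ph = curved_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        out = sp.remove_head(cloud)
        truth = ph.truth_labels.data[tuple(cloud.indices.T)]
        kept = np.zeros(len(cloud), dtype=bool)
        kept_set = {tuple(i) for i in out.indices}
        for i, idx in enumerate(cloud.indices):
            kept[i] = tuple(idx) in kept_set
        assert (truth[kept] == -1).sum() == 0  # no head point survives
        spine_lost = ((truth > 0) & ~kept).sum() / (truth > 0).sum()
        assert spine_lost < 0.01

    def test_no_head_phantom_unchanged(self, straight_phantom):
        ph = straight_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        out = sp.remove_head(cloud)
        assert len(out) == len(cloud)

    def test_uniform_cloud_unchanged(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, size=(2000, 3))
        cloud = SparseVoxelCloud(coords, np.ones(2000), (1.0, 1.0, 1.0))
        assert len(sp.remove_head(cloud)) == 2000


class TestFitSpineAxis:
    def test_straight_cylinder_axis_is_straight(self, straight_phantom):
        ph = straight_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        axis = sp.fit_spine_axis(cloud)
        # transverse deviation from the generating straight line < 1 voxel
        dev = np.abs(axis.polyline[:, 1:] - ph.truth_axis[0, 1:]).max()
        assert dev < ph.volume.voxel_size_um[0]

    def test_sinusoidal_bend_recovered(self, curved_phantom):
        ph = curved_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        cloud = sp.remove_head(cloud)
        axis = sp.fit_spine_axis(cloud)
        # compare each polyline point to the generating curve at equal z
        truth_x = np.interp(axis.polyline[:, 0], ph.truth_axis[:, 0], ph.truth_axis[:, 2])
        truth_y = np.interp(axis.polyline[:, 0], ph.truth_axis[:, 0], ph.truth_axis[:, 1])
        dev = np.hypot(axis.polyline[:, 2] - truth_x, axis.polyline[:, 1] - truth_y)
        assert dev.max() < 2 * ph.volume.voxel_size_um[0]

    def test_doubling_smoothing_never_lengthens_curve(self, curved_phantom):
        ph = curved_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        cloud = sp.remove_head(cloud)
        lengths = []
        smoothing = 9.0
        for _ in range(5):
            lengths.append(sp.fit_spine_axis(cloud, smoothing=smoothing).arc_length_um)
            smoothing *= 2
        assert all(a >= b - 1e-6 for a, b in zip(lengths, lengths[1:]))

    def test_too_few_bins_raises(self):
        coords = np.random.default_rng(0).uniform(0, 10, size=(20, 3))
        cloud = SparseVoxelCloud(coords, np.ones(20), (1.0, 1.0, 1.0))
        with pytest.raises(FitError):
            sp.fit_spine_axis(cloud, bin_um=5.0)


class TestProjectProfile:
    def test_intensity_conservation_exact(self, curved_phantom):
        ph = curved_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        cloud = sp.remove_head(cloud)
        axis = sp.fit_spine_axis(cloud)
        profile = sp.project_profile(cloud, axis, 6.0)
        assert profile.density.sum() == pytest.approx(cloud.intensity.sum(), rel=0, abs=1e-6)

    def test_minima_at_truth_boundaries(self, straight_phantom):
        ph = straight_phantom
        _, _, _, profile, boundaries = run_spine_chain(ph, bin_um=6.0)
        assert len(boundaries) == 4
        assert aligned_max_error(boundaries, ph.truth_boundaries) <= 6.0

    def test_bad_bin_width(self, straight_phantom):
        ph = straight_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        axis = sp.fit_spine_axis(cloud)
        with pytest.raises(ValueError):
            sp.project_profile(cloud, axis, 0.0)


class TestFindSpacings:
    def _profile(self, density):
        density = np.asarray(density, dtype=float)
        s = (np.arange(len(density)) + 0.5) * 10.0
        return sp.AxialDensityProfile(s, density, 10.0)

    def test_monotone_profile_has_no_spacings(self):
        assert len(sp.find_spacings(self._profile(np.arange(20)))) == 0

    def test_constant_profile_has_no_spacings(self):
        assert len(sp.find_spacings(self._profile(np.ones(20)))) == 0

    def test_deep_gaps_found_waist_dips_rejected(self):
        # two hourglass centra: endplate peaks, mid waist at ~55%, true gap at 0
        centrum = [100, 55, 100]
        density = centrum + [0] + centrum
        out = sp.find_spacings(self._profile(density), prominence=0.1)
        assert len(out) == 1
        assert out[0] == pytest.approx(35.0)


class TestLabelCentra:
    def _chain(self, phantom):
        cloud = sp.threshold_to_cloud(phantom.volume, phantom.bone_fraction)
        axis = sp.fit_spine_axis(cloud)
        profile = sp.project_profile(cloud, axis, 6.0)
        boundaries = sp.find_spacings(profile, 0.1, 54.0)
        return cloud, axis, boundaries

    def test_full_core_fraction_means_seeding_is_output(self, straight_phantom):
        cloud, axis, boundaries = self._chain(straight_phantom)
        lab = sp.label_centra(cloud, axis, boundaries, core_fraction=1.0, k=12)
        s = axis.project(cloud.coords_um)
        expected = np.searchsorted(np.sort(boundaries), s) + 1
        np.testing.assert_array_equal(lab.labels, expected)

    def test_every_point_labeled_with_n_distinct_labels(self, straight_phantom):
        cloud, axis, boundaries = self._chain(straight_phantom)
        lab = sp.label_centra(cloud, axis, boundaries, core_fraction=0.5, k=12)
        assert (lab.labels > 0).all()
        assert len(np.unique(lab.labels)) == lab.n_centra == 5

    def test_accuracy_vs_truth_exceeds_99_percent(self, straight_phantom):
        ph = straight_phantom
        cloud, axis, boundaries = self._chain(ph)
        lab = sp.label_centra(cloud, axis, boundaries, core_fraction=0.5, k=12)
        truth = ph.truth_labels.data[tuple(cloud.indices.T)]
        assert (lab.labels == truth).mean() >= 0.99

    def test_repeat_runs_identical(self, straight_phantom):
        cloud, axis, boundaries = self._chain(straight_phantom)
        a = sp.label_centra(cloud, axis, boundaries, 0.5, 12)
        b = sp.label_centra(cloud, axis, boundaries, 0.5, 12)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_no_boundaries_gives_single_label(self):
        coords = np.random.default_rng(0).uniform(0, 50, (100, 3))
        cloud = SparseVoxelCloud(coords, np.ones(100), (1.0, 1.0, 1.0))
        axis = sp.fit_spine_axis(cloud, bin_um=2.0)
        lab = sp.label_centra(cloud, axis, [], 0.5, 12)
        assert (lab.labels == 1).all()


class TestCentrumStats:
    def test_identical_centra_have_zero_within_sample_sd(self, straight_phantom):
        cloud = sp.threshold_to_cloud(straight_phantom.volume,
                                      straight_phantom.bone_fraction)
        labels = np.repeat(np.arange(1, 6), len(cloud) // 5 + 1)[: len(cloud)]
        labeling = sp.CentrumLabeling(labels, np.array([1, 2, 3, 4.0]), 5)
        cloud.intensity[:] = 3.0
        stats = sp.centrum_stats(labeling, cloud)
        assert stats.within_sample_sd == 0.0

    def test_self_scaling_gives_unit_mean_relative_density(self, straight_phantom):
        ph = straight_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        axis = sp.fit_spine_axis(cloud)
        profile = sp.project_profile(cloud, axis, 6.0)
        boundaries = sp.find_spacings(profile, 0.1, 54.0)
        lab = sp.label_centra(cloud, axis, boundaries, 0.5, 12)
        stats = sp.centrum_stats(lab, cloud)
        assert stats.per_centrum["relative_density"].mean() == pytest.approx(1.0)

    def test_density_recovery_noise_free(self, straight_phantom):
        ph = straight_phantom
        cloud = sp.threshold_to_cloud(ph.volume, ph.bone_fraction)
        axis = sp.fit_spine_axis(cloud)
        profile = sp.project_profile(cloud, axis, 6.0)
        boundaries = sp.find_spacings(profile, 0.1, 54.0)
        lab = sp.label_centra(cloud, axis, boundaries, 0.5, 12)
        stats = sp.centrum_stats(lab, cloud)
        r = np.corrcoef(stats.per_centrum["mean_gray"], ph.truth_densities)[0, 1]
        assert r >= 0.99


class TestCalibration:
    def test_anchors_and_midpoint_exact(self):
        calib = DensityCalibration(gray_lo=100.0, gray_hi=300.0)
        assert sp.calibrate_tmd(100.0, calib) == 0.25
        assert sp.calibrate_tmd(300.0, calib) == 0.75
        assert sp.calibrate_tmd(200.0, calib) == 0.5

    def test_extrapolation_follows_affine_extension(self):
        calib = DensityCalibration(gray_lo=100.0, gray_hi=300.0)
        assert sp.calibrate_tmd(400.0, calib) == pytest.approx(1.0)

    def test_equal_phantom_grays_rejected(self):
        with pytest.raises(CalibrationError):
            DensityCalibration(gray_lo=200.0, gray_hi=200.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(1, 1000), st.floats(1.01, 10), st.floats(-2, 2))
    def test_affine_linearity(self, lo, ratio, t):
        hi = lo * ratio
        calib = DensityCalibration(gray_lo=lo, gray_hi=hi)
        gray = lo + t * (hi - lo)
        expected = 0.25 + t * 0.5
        assert sp.calibrate_tmd(gray, calib) == pytest.approx(expected, abs=1e-9)
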