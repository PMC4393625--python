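"""Volume I/O, subtraction, thresholding and the primitive searches."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seegseg import (
    ConvergenceError,
    CubicRegion,
    EmptyRegionError,
    FormatError,
    GridMismatchError,
    PhantomElectrode,
    PhantomSpec,
    ThresholdError,
    VoxelVolume,
    apply_threshold,
    auto_threshold,
    default_model,
    find_significant_voxel,
    load_volume,
    make_phantom,
    refine_centroid,
    subtract_volumes,
)

S = 1600.0


def anisotropic_volume(data):
    return VoxelVolume(data, np.diag([0.4, 0.4, 0.8, 1.0]))


class TestLoadVolume:
    def test_round_trip_preserves_data_and_spacing(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = anisotropic_volume(rng.uniform(0, 3000, size=(12, 10, 8)))
        path = tmp_path / "vol.nii.gz"
        vol.save(path)
        back = load_volume(path)
        np.testing.assert_allclose(back.data, vol.data, atol=0.5)  # float32 file
        np.testing.assert_allclose(back.spacing, [0.4, 0.4, 0.8], atol=1e-6)

    def test_missing_file_error_names_path(self, tmp_path):
        with pytest.raises(FormatError, match="nowhere.nii"):
            load_volume(tmp_path / "nowhere.nii")

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3), dtype=np.float32), np.eye(4))
        path = tmp_path / "vol4d.nii"
        img.to_filename(str(path))
        with pytest.raises(FormatError):
            load_volume(path)

    def test_degenerate_affine_rejected(self):
        with pytest.raises(FormatError):
            VoxelVolume(np.zeros((3, 3, 3)), np.zeros((4, 4)))


class TestSubtractVolumes:
    def test_self_subtraction_is_zero(self):
        vol = anisotropic_volume(np.full((5, 5, 5), 1200.0))
        out = subtract_volumes(vol, vol)
        assert np.all(out.data == 0.0)

    def test_bone_removal_leaves_only_electrode_voxels(self):
        """Post = bone + electrodes, pre = bone: the difference thresholds
        to exactly the electrode voxels even when bone intensity equals
        the contacts'."""
        model = default_model(8)
        entry = np.array([3.0, 12.0, 16.0])
        target = entry + (3 + 2 + 7 * 3.5) * np.array([1.0, 0.0, 0.0])
        spec = PhantomSpec(shape=(100, 60, 40),
                           electrodes=[PhantomElectrode("A", entry, target, model)],
                           seed=0, noise_level=0.0)
        electrode_vol, _ = make_phantom(spec)
        bone = np.zeros(spec.shape)
        bone[:, :8, :] = spec.contact_intensity  # a bone slab, metal-bright
        pre = VoxelVolume(bone, electrode_vol.affine)
        post = VoxelVolume(bone + electrode_vol.data, electrode_vol.affine)
        diff = apply_threshold(subtract_volumes(post, pre), S)
        expected = apply_threshold(electrode_vol, S)
        np.testing.assert_array_equal(diff.data > 0, expected.data > 0)

    def test_negatives_clamped(self):
        a = anisotropic_volume(np.full((3, 3, 3), 10.0))
        b = anisotropic_volume(np.full((3, 3, 3), 25.0))
        assert np.all(subtract_volumes(a, b).data == 0.0)

    def test_grid_mismatch_raises(self):
        a = anisotropic_volume(np.zeros((4, 4, 4)))
        b = anisotropic_volume(np.zeros((4, 4, 5)))
        with pytest.raises(GridMismatchError):
            subtract_volumes(a, b)
        c = VoxelVolume(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(GridMismatchError):
            subtract_volumes(a, c)


class TestAutoThreshold:
    def test_bimodal_histogram_threshold_in_valley(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(50, 400, size=(20, 20, 20))
        data.ravel()[rng.choice(data.size, 400, replace=False)] = \
            rng.uniform(2900, 3100, size=400)
        s = float(auto_threshold(anisotropic_volume(data)))
        assert 400 < s < 2900

    def test_phantom_auto_threshold_separates_metal_from_noise(self):
        model = default_model(8)
        entry = np.array([3.0, 12.0, 16.0])
        target = entry + (3 + 2 + 7 * 3.5) * np.array([1.0, 0.0, 0.0])
        spec = PhantomSpec(shape=(100, 60, 40),
                           electrodes=[PhantomElectrode("A", entry, target, model)],
                           seed=4)
        vol, _ = make_phantom(spec)
        s = float(auto_threshold(vol))
        assert spec.noise_level < s < spec.contact_intensity

    def test_constant_volume_raises(self):
        with pytest.raises(ThresholdError):
            auto_threshold(anisotropic_volume(np.full((5, 5, 5), 7.0)))

    def test_monotone_histogram_raises(self):
        counts = np.arange(256, 0, -1)
        values = np.repeat(np.linspace(1, 256, 256), counts)
        data = values.reshape(128, 257, 1)  # 32896 voxels, decreasing hist
        with pytest.raises(ThresholdError, match="manual"):
            auto_threshold(anisotropic_volume(data))


class TestApplyThreshold:
    @pytest.mark.parametrize("value,expected", [
        (1700.0, 1700.0),  # above: keeps its value
        (1599.0, 0.0),     # below: zeroed
        (1600.0, 0.0),     # exactly S: background (strict comparison)
    ])
    def test_boundary_cases(self, value, expected):
        vol = anisotropic_volume(np.full((2, 2, 2), value))
        assert apply_threshold(vol, S).data[0, 0, 0] == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 4000.0))
    def test_idempotent(self, seed, s):
        data = np.random.default_rng(seed).uniform(0, 4000, size=(6, 6, 6))
        vol = anisotropic_volume(data)
        once = apply_threshold(vol, s)
        twice = apply_threshold(once, s)
        np.testing.assert_array_equal(once.data, twice.data)


class TestFindSignificantVoxel:
    def setup_method(self):
        self.data = np.zeros((60, 60, 30))
        self.vol = anisotropic_volume(self.data)

    def test_found_inside_initial_region(self):
        self.data[27, 25, 12] = 2000.0  # (10.8, 10.0, 9.6): 1 mm off center
        found = find_significant_voxel(self.vol, (10.0, 10.0, 9.6), S)
        np.testing.assert_allclose(found, [10.8, 10.0, 9.6])

    def test_found_only_after_enlargement(self):
        # nearest hot voxel 4.8 mm along x: needs a cube of side >= 9.6 mm
        self.data[37, 25, 12] = 2000.0  # x = 14.8 vs center x = 10.0
        assert find_significant_voxel(self.vol, (10.0, 10.0, 9.6), S,
                                      l_init=3, l_max=9, l_step=1) is None
        found = find_significant_voxel(self.vol, (10.0, 10.0, 9.6), S,
                                       l_init=3, l_max=10, l_step=1)
        np.testing.assert_allclose(found, [14.8, 10.0, 9.6])

    def test_exhausted_returns_none(self):
        assert find_significant_voxel(self.vol, (10.0, 10.0, 9.6), S) is None

    def test_result_always_significant_and_inside_search_cube(self):
        rng = np.random.default_rng(9)
        data = rng.uniform(0, 2500, size=(40, 40, 20))
        vol = anisotropic_volume(data)
        for _ in range(25):
            center = rng.uniform([2, 2, 2], [14, 14, 14])
            found = find_significant_voxel(vol, center, S)
            if found is None:
                continue
            idx = tuple(np.round(vol.world_to_index(found)).astype(int))
            assert vol.data[idx] > S
            assert np.all(np.abs(found - center) <= 5.0 + 1e-9)

    def test_prefers_voxel_nearest_anchor(self):
        self.data[25, 25, 12] = 2000.0   # x = 10.0
        self.data[29, 25, 12] = 2000.0   # x = 11.6
        found = find_significant_voxel(self.vol, (10.8, 10.0, 9.6), S,
                                       prefer=(11.6, 10.0, 9.6))
        np.testing.assert_allclose(found, [11.6, 10.0, 9.6])


class TestRefineCentroid:
    def _cylinder_volume(self):
        model = default_model(8)
        entry = np.array([3.0, 12.0, 16.0])
        target = entry + (3 + 2 + 7 * 3.5) * np.array([1.0, 0.0, 0.0])
        spec = PhantomSpec(shape=(100, 60, 40),
                           electrodes=[PhantomElectrode("A", entry, target, model)],
                           seed=0, noise_level=0.0)
        vol, truth = make_phantom(spec)
        return vol, truth.contacts["A"]

    def test_fixed_point_at_symmetric_blob_centroid(self):
        data = np.zeros((21, 21, 11))
        data[9:12, 9:12, 4:7] = 2000.0
        vol = anisotropic_volume(data)
        center = vol.index_to_world([10, 10, 5])
        out = refine_centroid(vol, center, side=3.0, S=S)
        np.testing.assert_allclose(out, center, atol=1e-9)

    def test_converges_to_cylinder_centroid_from_offset_start(self):
        """From 1 mm off a rasterized contact, the iteration settles on the
        above-threshold mass centroid of its own converged region."""
        vol, contacts = self._cylinder_volume()
        true_c = contacts[3]
        start = true_c + np.array([0.7, 0.7, 0.14])  # ~1 mm offset
        out = refine_centroid(vol, start, side=3.0, S=S, eps=1e-4)
        # independent oracle: thresholded mass centroid of the final region
        values, coords = vol.region_voxels(CubicRegion(out, 3.0), above=S)
        oracle = coords.T @ values / values.sum()
        np.testing.assert_allclose(out, oracle, atol=2e-4)
        assert np.linalg.norm(out - true_c) < 0.3

    def test_basin_invariance_of_start_point(self):
        vol, contacts = self._cylinder_volume()
        true_c = contacts[5]
        rng = np.random.default_rng(2)
        results = []
        for _ in range(8):
            start = true_c + rng.uniform(-1, 1, size=3) * [1.0, 1.0, 0.5]
            results.append(refine_centroid(vol, start, side=3.0, S=S, eps=1e-4))
        results = np.array(results)
        assert np.linalg.norm(results - results[0], axis=1).max() < 5e-4

    def test_empty_start_raises(self):
        vol = anisotropic_volume(np.zeros((30, 30, 15)))
        with pytest.raises(EmptyRegionError):
            refine_centroid(vol, (6.0, 6.0, 6.0), side=3.0, S=S)

    def test_max_iter_exceeded_reports_last_iterate(self):
        vol, contacts = self._cylinder_volume()
        with pytest.raises(ConvergenceError) as excinfo:
            refine_centroid(vol, contacts[0], side=3.0, S=S, eps=0.0, max_iter=3)
        assert excinfo.value.last_point is not None
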