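import numpy as np
import nibabel as nib
import pytest

from caliper.errors import (
    ConstantImageError,
    NonVolumeError,
    ObliqueAffineError,
    VolumeError,
)
from caliper.volume_io import (
    VolumeGrid,
    load_volume,
    reorient_to_ras,
    resize_to_cube,
    save_volume,
    standardize_intensity,
)


def _write_nifti(path, data, affine):
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


class TestLoadVolume:
    def test_round_trip_identity(self, tmp_path, rng):
        data = rng.normal(size=(10, 12, 14))
        affine = np.diag([1.0, 1.0, 2.0, 1.0])
        affine[:3, 3] = (-5, 3, 7)
        p = tmp_path / "v.nii.gz"
        save_volume(VolumeGrid(data=data, affine=affine), p)
        v = load_volume(p)
        assert np.allclose(v.data, data, atol=1e-6)
        assert np.allclose(v.affine, affine)

    def test_missing_file(self, tmp_path):
        with pytest.raises(VolumeError, match="not found"):
            load_volume(tmp_path / "absent.nii")

    def test_4d_rejected(self, tmp_path, rng):
        _write_nifti(tmp_path / "v4.nii", rng.normal(size=(4, 4, 4, 3)), np.eye(4))
        with pytest.raises(NonVolumeError, match="non-3D"):
            load_volume(tmp_path / "v4.nii")

    def test_unreadable_header(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"this is not a nifti file at all" * 10)
        with pytest.raises(VolumeError):
            load_volume(bad)

    def test_anisotropic_header_spacing(self, tmp_path, rng):
        _write_nifti(tmp_path / "a.nii", rng.normal(size=(8, 8, 8)), np.diag([1.0, 1.0, 2.0, 1.0]))
        v = load_volume(tmp_path / "a.nii")
        assert np.allclose(v.spacing, [1.0, 1.0, 2.0])


class TestReorient:
    def test_already_ras_unchanged(self, rng):
        v = VolumeGrid(data=rng.normal(size=(5, 6, 7)), affine=np.eye(4))
        out = reorient_to_ras(v)
        assert np.array_equal(out.data, v.data)
        assert np.array_equal(out.affine, v.affine)

    def test_lps_flip_preserves_world_positions(self, rng):
        data = rng.normal(size=(6, 7, 8))
        affine = np.diag([-1.0, -1.0, 1.0, 1.0])
        affine[:3, 3] = (10.0, 20.0, -3.0)
        v = VolumeGrid(data=data, affine=affine)
        out = reorient_to_ras(v)
        assert out.axis_codes == ("R", "A", "S")
        # the world position of a marked voxel value is identical before/after
        idx = np.array([2, 3, 4])
        val = data[tuple(idx)]
        world = v.voxel_to_world(idx)
        inv = np.linalg.inv(out.affine)
        new_idx = np.round(inv[:3, :3] @ world + inv[:3, 3]).astype(int)
        assert out.data[tuple(new_idx)] == val

    def test_idempotent(self, rng):
        affine = np.diag([-1.0, 1.0, -1.0, 1.0])
        v = VolumeGrid(data=rng.normal(size=(5, 5, 5)), affine=affine)
        once = reorient_to_ras(v)
        twice = reorient_to_ras(once)
        assert np.array_equal(once.data, twice.data)
        assert np.array_equal(once.affine, twice.affine)

    def test_preserves_intensity_multiset(self, rng):
        affine = np.diag([1.0, -1.0, 1.0, 1.0])
        v = VolumeGrid(data=rng.normal(size=(4, 5, 6)), affine=affine)
        out = reorient_to_ras(v)
        assert np.array_equal(np.sort(out.data.ravel()), np.sort(v.data.ravel()))

    def test_oblique_rejected(self, rng):
        # first voxel axis points along the (1,1,1) diagonal: > 45 deg from
        # every canonical axis, so permutation/flip reorientation cannot apply
        u1 = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        u2 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        u3 = np.cross(u1, u2)
        affine = np.eye(4)
        affine[:3, :3] = np.stack([u1, u2, u3], axis=1)
        v = VolumeGrid(data=rng.normal(size=(4, 4, 4)), affine=affine)
        with pytest.raises(ObliqueAffineError):
            reorient_to_ras(v)


class TestResize:
    def test_identity_for_iso_cube(self, rng):
        v = VolumeGrid(data=rng.normal(size=(128, 128, 128)), affine=np.eye(4))
        p = resize_to_cube(v)
        assert p.scale_factor == 1.0
        assert tuple(p.pad_offsets) == (0, 0, 0)
        assert np.array_equal(p.data, v.data)

    def test_aspect_preserving_pads(self, rng):
        v = VolumeGrid(data=rng.normal(size=(100, 200, 100)), affine=np.eye(4))
        p = resize_to_cube(v)
        assert tuple(p.content_shape) == (64, 128, 64)
        assert tuple(p.pad_offsets) == (32, 0, 32)
        assert p.scale_factor == pytest.approx(200 / 128)

    def test_coordinate_round_trip(self, rng):
        affine = np.diag([0.9, 1.1, 1.3, 1.0])
        affine[:3, 3] = (4.0, -7.0, 2.0)
        v = VolumeGrid(data=rng.normal(size=(90, 110, 70)), affine=affine)
        p = resize_to_cube(v)
        src = np.array([[10.0, 20.0, 30.0], [45.0, 55.0, 35.0]])
        cube = p.source_voxel_to_cube(src)
        back = p.cube_to_source_voxel(cube)
        assert np.allclose(back, src, atol=1e-9)
        # world mapping agrees with the source affine directly
        world = p.cube_to_world(cube)
        expect = (affine[:3, :3] @ src.T).T + affine[:3, 3]
        assert np.allclose(world, expect, atol=1e-9)
        assert np.allclose(p.world_to_cube(world), cube, atol=1e-9)

    def test_aspect_ratio_within_one_percent(self, rng):
        v = VolumeGrid(
            data=rng.normal(size=(50, 80, 64)), affine=np.diag([1.5, 1.0, 1.2, 1.0])
        )
        p = resize_to_cube(v)
        phys = np.array([50 * 1.5, 80 * 1.0, 64 * 1.2])
        content = p.content_shape.astype(float)
        ratio = (content / content.max()) / (phys / phys.max())
        assert np.all(np.abs(ratio - 1) < 0.01)

    def test_degenerate_axis_rejected(self):
        # a zero-extent axis implies a singular affine, refused on construction
        with pytest.raises(VolumeError):
            VolumeGrid(data=np.ones((1, 10, 10)), affine=np.diag([0.0, 1, 1, 1]))


class TestStandardize:
    def _pre(self, data):
        return resize_to_cube(VolumeGrid(data=data, affine=np.eye(4)), edge=data.shape[0])

    def test_known_moments(self, rng):
        data = rng.normal(100.0, 20.0, size=(32, 32, 32))
        p = self._pre(data)
        out = standardize_intensity(p)
        region = out.data[out.content_slices]
        assert abs(region.mean()) < 1e-10
        assert abs(region.std() - 1) < 1e-10
        expect = (data - data.mean()) / data.std()
        assert np.allclose(out.data, expect, atol=1e-9)

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(16, 16, 16))
        a = standardize_intensity(self._pre(data))
        b = standardize_intensity(self._pre(3.5 * data + 42.0))
        assert np.allclose(a.data, b.data, atol=1e-9)

    def test_already_standardized_unchanged(self, rng):
        data = rng.normal(size=(16, 16, 16))
        data = (data - data.mean()) / data.std()
        out = standardize_intensity(self._pre(data))
        assert np.allclose(out.data, data, atol=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ConstantImageError):
            standardize_intensity(self._pre(np.full((8, 8, 8), 3.0)))
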