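"""NIfTI volume I/O and preprocessing.

Preprocessing mirrors the first stage of the measurement pipeline: reorient the
volume to RAS, resample it into an isotropic cube (default 128 voxels per edge)
that preserves the aspect ratio of the physical field of view, and standardize
intensities to zero mean / unit variance over the non-padded content region.

Coordinate conventions
----------------------
Voxel indices are 0-based and refer to voxel centers. World coordinates are in
millimetres, RAS+ (x right, y anterior, z superior). After resampling, one cube
voxel corresponds to ``scale_factor`` millimetres along every axis, and the
recorded pad offsets make the cube <-> source-world mapping exactly invertible.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    ConstantImageError,
    DegenerateAxisError,
    NonVolumeError,
    ObliqueAffineError,
    VolumeError,
)

__all__ = [
    "VolumeGrid",
    "PreprocessedVolume",
    "load_volume",
    "save_volume",
    "reorient_to_ras",
    "resize_to_cube",
    "standardize_intensity",
    "preprocess",
]


@dataclass
class VolumeGrid:
    """A 3D intensity array with a voxel->world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise NonVolumeError(f"non-3D volume: shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeError("affine is not invertible")

    @property
    def axis_codes(self) -> tuple[str, str, str]:
        return nib.aff2axcodes(self.affine)

    @property
    def is_ras(self) -> bool:
        return self.axis_codes == ("R", "A", "S")

    @property
    def spacing(self) -> np.ndarray:
        """Physical size of one voxel along each array axis (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        out = (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]
        return out[0] if out.shape[0] == 1 else out


@dataclass
class PreprocessedVolume:
    """An ``edge``-cubed resampled volume plus the transforms back to source.

    ``scale_factor`` is millimetres of source space per cube voxel;
    ``pad_offsets`` are the symmetric background pads added along each axis so
    the resampled content sits centered in the cube.
    """

    data: np.ndarray
    scale_factor: float
    pad_offsets: np.ndarray
    content_shape: np.ndarray
    source_affine: np.ndarray
    source_shape: tuple[int, int, int]
    edge: int = 128
    standardized: bool = False
    norm_mean: float | None = None
    norm_sd: float | None = None

    @property
    def content_slices(self) -> tuple[slice, slice, slice]:
        p, n = self.pad_offsets, self.content_shape
        return tuple(slice(int(p[i]), int(p[i] + n[i])) for i in range(3))

    @property
    def source_spacing(self) -> np.ndarray:
        return np.linalg.norm(self.source_affine[:3, :3], axis=0)

    def cube_to_source_voxel(self, cube_idx) -> np.ndarray:
        """Map cube voxel coordinates to source voxel coordinates."""
        c = np.atleast_2d(np.asarray(cube_idx, dtype=float))
        p = self.pad_offsets.astype(float)
        n = self.content_shape.astype(float)
        s_shape = np.asarray(self.source_shape, dtype=float)
        ratio = self.scale_factor / self.source_spacing
        s = (c - p - (n - 1) / 2.0) * ratio + (s_shape - 1) / 2.0
        return s[0] if s.shape[0] == 1 else s

    def source_voxel_to_cube(self, src_idx) -> np.ndarray:
        s = np.atleast_2d(np.asarray(src_idx, dtype=float))
        p = self.pad_offsets.astype(float)
        n = self.content_shape.astype(float)
        s_shape = np.asarray(self.source_shape, dtype=float)
        ratio = self.scale_factor / self.source_spacing
        c = (s - (s_shape - 1) / 2.0) / ratio + p + (n - 1) / 2.0
        return c[0] if c.shape[0] == 1 else c

    def cube_to_world(self, cube_idx) -> np.ndarray:
        s = np.atleast_2d(self.cube_to_source_voxel(cube_idx))
        w = (self.source_affine[:3, :3] @ s.T).T + self.source_affine[:3, 3]
        return w[0] if w.shape[0] == 1 else w

    def world_to_cube(self, world) -> np.ndarray:
        w = np.atleast_2d(np.asarray(world, dtype=float))
        inv = np.linalg.inv(self.source_affine)
        s = (inv[:3, :3] @ w.T).T + inv[:3, 3]
        c = self.source_voxel_to_cube(s)
        return c


def load_volume(path) -> VolumeGrid:
    """Read a NIfTI-1/NIfTI-2 file as a :class:`VolumeGrid` (no resampling)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeError(f"file not found: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except VolumeError:
        raise
    except Exception as exc:  # unreadable/corrupt header
        raise VolumeError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NonVolumeError(f"non-3D volume: shape {data.shape}")
    return VolumeGrid(data=data.astype(np.float64), affine=np.asarray(affine))


def save_volume(v: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine), os.fspath(path))


def _check_not_oblique(affine: np.ndarray) -> None:
    # Each voxel axis must lie within 45 degrees of a canonical world axis.
    rot = affine[:3, :3]
    for j in range(3):
        col = rot[:, j]
        if np.max(np.abs(col)) < np.cos(np.deg2rad(45.0)) * np.linalg.norm(col):
            raise ObliqueAffineError(
                "affine is oblique (no axis within 45 deg of canonical); "
                "resample explicitly before reorienting"
            )


def reorient_to_ras(v: VolumeGrid) -> VolumeGrid:
    """Permute/flip axes so axis codes become (R, A, S).

    World coordinates of every voxel are unchanged: the data are rearranged and
    the affine updated consistently. Already-RAS volumes are returned as-is.
    """
    if v.is_ras:
        return v
    _check_not_oblique(v.affine)
    ornt = nib.orientations.io_orientation(v.affine)
    data = nib.orientations.apply_orientation(v.data, ornt)
    affine = v.affine @ nib.orientations.inv_ornt_aff(ornt, v.data.shape)
    return VolumeGrid(data=np.ascontiguousarray(data), affine=affine)


def resize_to_cube(v: VolumeGrid, edge: int = 128) -> PreprocessedVolume:
    """Resample an RAS volume into an ``edge``-cubed isotropic grid.

    The largest physical extent maps onto ``edge`` voxels; the other axes are
    scaled by the same mm-per-voxel factor and padded symmetrically with the
    volume's minimum intensity so the aspect ratio is preserved.
    """
    spacing = v.spacing
    extents = np.asarray(v.data.shape) * spacing
    if np.any(extents <= 0):
        raise DegenerateAxisError(f"zero-extent axis: extents {extents}")
    scale = float(np.max(extents)) / edge  # mm per cube voxel
    content = np.minimum(np.round(extents / scale).astype(int), edge)
    content = np.maximum(content, 1)
    pads = (edge - content) // 2

    out = PreprocessedVolume(
        data=np.empty(0),
        scale_factor=scale,
        pad_offsets=pads,
        content_shape=content,
        source_affine=v.affine.copy(),
        source_shape=tuple(v.data.shape),
        edge=edge,
    )
    background = float(np.min(v.data))
    if tuple(content) == (edge,) * 3 and v.data.shape == (edge,) * 3 and np.allclose(
        spacing, spacing[0]
    ):
        # Source grid already coincides with the cube grid.
        out.data = np.asarray(v.data, dtype=np.float64).copy()
        return out
    cube_axes = [np.arange(edge, dtype=float)] * 3
    grid = np.stack(np.meshgrid(*cube_axes, indexing="ij"), axis=-1)
    src = out.cube_to_source_voxel(grid.reshape(-1, 3)).reshape(edge, edge, edge, 3)
    out.data = ndimage.map_coordinates(
        np.asarray(v.data, dtype=np.float64),
        [src[..., 0], src[..., 1], src[..., 2]],
        order=1,
        mode="constant",
        cval=background,
    )
    return out


def standardize_intensity(p: PreprocessedVolume) -> PreprocessedVolume:
    """Zero-mean / unit-variance rescaling over the non-padded content box.

    The same affine map is applied to the whole cube (padding included) so the
    output is a monotone affine function of the input everywhere.
    """
    region = p.data[p.content_slices]
    mean = float(np.mean(region))
    sd = float(np.std(region))
    if sd < 1e-12:
        raise ConstantImageError("constant image: intensity standardization undefined")
    out = dataclasses.replace(
        p,
        data=(p.data - mean) / sd,
        standardized=True,
        norm_mean=mean,
        norm_sd=sd,
    )
    return out


def preprocess(v: VolumeGrid, edge: int = 128) -> PreprocessedVolume:
    """Full preprocessing chain: reorient to RAS, resize to cube, standardize."""
    return standardize_intensity(resize_to_cube(reorient_to_ras(v), edge=edge))
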