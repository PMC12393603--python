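"""Oblique coronal plane construction, slice extraction, and perturbations.

The measurement plane is perpendicular to the AC-PC line at the level of PC.
Its in-plane frame is anchored to the subject's left-right axis so that image
columns run left to right and image rows run superior to inferior (row index
increases inferiorly, the usual image convention). All plane quantities are in
cube-voxel units of the preprocessed volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import GeometryError
from .landmarks import LandmarkSet
from .volume_io import PreprocessedVolume

__all__ = [
    "PlaneSpec",
    "Slice2D",
    "build_plane",
    "extract_slice",
    "perturb_plane",
    "save_slice_png",
    "save_slice_nifti",
]

_LR_AXIS = np.array([1.0, 0.0, 0.0])  # subject left -> right in RAS voxel space
_SUP_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class PlaneSpec:
    """Origin plus orthonormal frame of the oblique coronal plane.

    ``normal`` points from PC toward AC (anterior); ``u_axis`` spans image
    columns (subject left -> right); ``v_axis`` points superior. Pixel (i, j)
    of a ``size``-shaped slice samples::

        origin + (j - cx) * spacing * u_axis + (cy - i) * spacing * v_axis

    with (cx, cy) = (size[1] // 2, size[0] // 2), so rows increase inferiorly.
    """

    origin: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    size: tuple[int, int] = (224, 224)
    spacing: float = 1.0

    def __post_init__(self) -> None:
        for name in ("origin", "normal", "u_axis", "v_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if min(self.size) <= 0 or self.spacing <= 0:
            raise GeometryError("plane size and spacing must be positive")
        for name in ("normal", "u_axis", "v_axis"):
            if abs(np.linalg.norm(getattr(self, name)) - 1.0) > 1e-8:
                raise GeometryError(f"{name} must be unit length")

    @property
    def center_pixel(self) -> tuple[int, int]:
        return (self.size[0] // 2, self.size[1] // 2)

    def pixel_to_xyz(self, ij) -> np.ndarray:
        """Map (row, col) pixel coordinates to 3D cube-voxel coordinates."""
        ij = np.atleast_2d(np.asarray(ij, dtype=float))
        cy, cx = self.center_pixel
        off_u = (ij[:, 1] - cx) * self.spacing
        off_v = (cy - ij[:, 0]) * self.spacing
        pts = self.origin + off_u[:, None] * self.u_axis + off_v[:, None] * self.v_axis
        return pts[0] if pts.shape[0] == 1 else pts

    def grid_xyz(self) -> np.ndarray:
        """3D sample points for every pixel, shape ``size + (3,)``."""
        h, w = self.size
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        ij = np.stack([ii.ravel(), jj.ravel()], axis=1)
        return np.atleast_2d(self.pixel_to_xyz(ij)).reshape(h, w, 3)


@dataclass
class Slice2D:
    """A 2D slice (intensity or labels) with its generating plane."""

    data: np.ndarray
    plane: PlaneSpec
    mode: str = "intensity"  # intensity | label

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.plane.size):
            raise GeometryError(
                f"slice shape {self.data.shape} != plane size {self.plane.size}"
            )


def _orthonormalize(normal: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    normal = normal / np.linalg.norm(normal)
    u = u - np.dot(u, normal) * normal
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        raise GeometryError("u axis parallel to plane normal")
    u = u / nu
    v = np.cross(normal, u)
    v = v / np.linalg.norm(v)
    if np.dot(v, _SUP_AXIS) < 0:
        v = -v
    return normal, u, v


def build_plane(
    lm: LandmarkSet, size: tuple[int, int] = (224, 224), spacing: float = 1.0
) -> PlaneSpec:
    """Plane through PC, perpendicular to the AC-PC line.

    ``u_axis`` is the projection of the subject left->right axis onto the
    plane; ``v_axis`` completes the frame and points superior. Fails if the
    AC-PC line is (nearly) parallel to the left-right axis, where the in-plane
    roll would be undefined.
    """
    d = lm.ac - lm.pc
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise GeometryError("AC and PC coincide")
    normal = d / n
    if abs(np.dot(normal, _LR_AXIS)) > np.cos(np.deg2rad(5.0)):
        raise GeometryError("AC-PC line parallel to left-right axis: roll undefined")
    normal, u, v = _orthonormalize(normal, _LR_AXIS.copy())
    return PlaneSpec(
        origin=lm.pc.copy(), normal=normal, u_axis=u, v_axis=v,
        size=tuple(size), spacing=float(spacing),
    )


def extract_slice(
    volume: PreprocessedVolume | np.ndarray, plane: PlaneSpec, mode: str = "intensity"
) -> Slice2D:
    """Resample the volume on the plane's pixel grid.

    Trilinear interpolation for intensities, nearest neighbour for labels.
    Out-of-volume pixels take the background value (volume minimum for
    intensities, 0 for labels).
    """
    data = volume.data if isinstance(volume, PreprocessedVolume) else np.asarray(volume)
    if mode not in ("intensity", "label"):
        raise ValueError(f"unknown mode {mode!r}")
    pts = plane.grid_xyz()
    shape = np.asarray(data.shape, dtype=float)
    inside = np.all((pts > -0.5) & (pts < shape - 0.5), axis=-1)
    if not np.any(inside):
        raise GeometryError("plane does not intersect the volume")
    if mode == "label":
        order, cval = 0, 0.0
    else:
        order, cval = 1, float(np.min(data))
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=np.float64),
        [pts[..., 0], pts[..., 1], pts[..., 2]],
        order=order,
        mode="grid-constant" if order == 0 else "constant",
        cval=cval,
    )
    if mode == "label":
        out = np.round(out).astype(np.int64)
    return Slice2D(data=out, plane=plane, mode=mode)


def perturb_plane(
    plane: PlaneSpec,
    pc_shift: float = 0.0,
    sagittal_deg: float = 0.0,
    axial_deg: float = 0.0,
) -> PlaneSpec:
    """Apply the sensitivity-experiment perturbations to a plane.

    The origin is translated by ``pc_shift`` cube voxels along the (baseline)
    normal (positive = anterior); the frame is then rotated by ``sagittal_deg``
    about the u axis, followed by ``axial_deg`` about the (rotated) v axis, and
    re-orthonormalized.
    """
    if pc_shift == 0.0 and sagittal_deg == 0.0 and axial_deg == 0.0:
        return plane
    origin = plane.origin + pc_shift * plane.normal
    normal, u, v = plane.normal.copy(), plane.u_axis.copy(), plane.v_axis.copy()
    if sagittal_deg != 0.0:
        r = Rotation.from_rotvec(np.deg2rad(sagittal_deg) * u)
        normal, v = r.apply(normal), r.apply(v)
    if axial_deg != 0.0:
        r = Rotation.from_rotvec(np.deg2rad(axial_deg) * v)
        normal, u = r.apply(normal), r.apply(u)
    normal, u, v = _orthonormalize(normal, u)
    return replace(plane, origin=origin, normal=normal, u_axis=u, v_axis=v)


def save_slice_png(s: Slice2D, path) -> None:
    """8-bit PNG export: min-max scaled intensities, or raw label indices."""
    if s.mode == "label":
        iio.imwrite(path, s.data.astype(np.uint8))
        return
    lo, hi = float(np.min(s.data)), float(np.max(s.data))
    scaled = np.zeros_like(s.data, dtype=float) if hi == lo else (s.data - lo) / (hi - lo)
    iio.imwrite(path, np.round(scaled * 255).astype(np.uint8))


def save_slice_nifti(s: Slice2D, path) -> None:
    """Single-slice NIfTI preserving the plane geometry in the affine."""
    p = s.plane
    # Array axes: (row, col, slice) -> world directions (-v, u, normal).
    affine = np.eye(4)
    affine[:3, 0] = -p.v_axis * p.spacing
    affine[:3, 1] = p.u_axis * p.spacing
    affine[:3, 2] = p.normal
    affine[:3, 3] = p.pixel_to_xyz([0, 0])
    nib.save(nib.Nifti1Image(np.asarray(s.data, dtype=np.float32)[..., None], affine), path)
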