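"""Synthetic wedge phantoms with analytically known callosal angle.

The phantom emulates the geometry the angle measurement depends on: two
wedge-shaped "lateral ventricles" whose medial walls descend from near a
midline apex at half the apex angle from vertical, separated by a small gap.
The ground-truth callosal angle at the posterior-commissure plane equals the
apex angle exactly, and the analytic wall lines are returned alongside every
phantom.

In 3D the wedge is extruded along the anterior-posterior axis with two slow
anatomical-variation terms: the apex angle drifts linearly with the anterior
coordinate, and the two walls acquire a small antisymmetric "twist" with it.
These make the measured angle genuinely sensitive to slice position and plane
orientation (a perfectly uniform extrusion would be blind to posterior
commissure shifts and to axial rotations by symmetry). AC and PC are placed on
the anterior-posterior axis a realistic commissural distance apart, and an
optional global tilt rotates volume and landmarks jointly.

All phantom randomness (intensity noise) sits behind a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .ca_core import WallLine
from .errors import CaliperError
from .landmarks import LandmarkSet
from .plane_geometry import PlaneSpec, Slice2D
from .ventricle_masks import LEFT_LABEL, RIGHT_LABEL, VentricleMask
from .volume_io import PreprocessedVolume, VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "make_wedge_slice",
    "make_phantom_volume",
    "PhantomSegmenter",
    "PhantomLandmarkProvider",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the wedge phantom (pixel units = cube voxels = mm).

    ``apex_position`` is in image coordinates of the 224x224 coronal slice
    centered on PC; ``angle_slope`` and ``wall_twist`` are the degrees of
    apex-angle drift and of antisymmetric wall twist per voxel of anterior
    offset from the PC plane.
    """

    apex_angle_deg: float = 100.0
    apex_position: tuple[float, float] = (112.0, 67.0)
    wall_length: float = 45.0
    ventricle_width: float = 15.0
    gap: float = 6.0
    noise_sd: float = 0.05
    tilt_sagittal_deg: float = 0.0
    tilt_axial_deg: float = 0.0
    seed: int = 0
    angle_slope_deg_per_voxel: float = 2.0
    wall_twist_deg_per_voxel: float = 0.7
    ac_pc_distance: float = 26.0
    pc_y: float = 50.0
    extrusion_half_depth: float = 30.0
    roof_slope_deg: float = 15.0
    floor_slope_deg: float = 15.0
    tip_cap_px: float = 3.0

    def __post_init__(self) -> None:
        if not (20.0 < self.apex_angle_deg < 170.0):
            raise CaliperError("apex angle must be in (20, 170) degrees")
        if self.gap < 0 or self.wall_length < 20:
            raise CaliperError("need gap >= 0 and wall_length >= 20 px")

    def half_angles_deg(self, dy) -> tuple[np.ndarray, np.ndarray]:
        """Left/right wall angles from vertical at anterior offset ``dy``.

        The apex-angle drift and the antisymmetric wall twist are linear in
        the anterior offset near the PC plane; each wall angle saturates at
        [12, 78] degrees from vertical so the geometry stays valid over the
        whole extrusion (anatomical variation is bounded).
        """
        dy = np.asarray(dy, dtype=float)
        theta = self.apex_angle_deg + self.angle_slope_deg_per_voxel * dy
        twist = self.wall_twist_deg_per_voxel * dy
        a_l = np.clip(theta / 2.0 + twist, 12.0, 78.0)
        a_r = np.clip(theta / 2.0 - twist, 12.0, 78.0)
        return a_l, a_r

    def truth_wall_lines(self) -> tuple[WallLine, WallLine]:
        """Analytic wall lines at the PC plane, in slice image coordinates."""
        a = np.deg2rad(self.apex_angle_deg / 2.0)
        xa, ya = self.apex_position
        left = WallLine(
            base_point=np.array([xa - self.gap / 2.0, ya]),
            direction=np.array([-np.sin(a), np.cos(a)]),
            inlier_count=0,
            inlier_rms=0.0,
        )
        right = WallLine(
            base_point=np.array([xa + self.gap / 2.0, ya]),
            direction=np.array([np.sin(a), np.cos(a)]),
            inlier_count=0,
            inlier_rms=0.0,
        )
        return left, right


def _wedge_labels(spec: PhantomSpec, x_img, y_img, dy) -> np.ndarray:
    """Multiclass membership of slice-image points at anterior offset dy."""
    x_img = np.asarray(x_img, dtype=float)
    y_img = np.asarray(y_img, dtype=float)
    dy = np.broadcast_to(np.asarray(dy, dtype=float), x_img.shape)
    a_l, a_r = spec.half_angles_deg(dy)
    valid = np.abs(dy) <= spec.extrusion_half_depth
    xa, ya = spec.apex_position
    d = y_img - ya
    out = np.zeros(x_img.shape, dtype=np.int64)
    tan_roof = np.tan(np.deg2rad(spec.roof_slope_deg))
    tan_floor = np.tan(np.deg2rad(spec.floor_slope_deg))
    for label, sign, half in ((LEFT_LABEL, -1.0, a_l), (RIGHT_LABEL, 1.0, a_r)):
        rad = np.deg2rad(half)
        x_med = xa + sign * (spec.gap / 2.0 + d * np.tan(rad))
        lateral = sign * (x_img - x_med)
        # the superomedial corner is blunt (a short flat cap, as real ventricle
        # corners are) and the roof then slopes down laterally (as the
        # ventricle roofs under the corpus callosum do), so the corner is the
        # most superior region and rasterizes stably; the floor rises
        # laterally from the medial wall's bottom corner (trigone-like
        # outline), so neither roof nor floor can shadow the medial wall from
        # the midline
        in_depth = (d >= np.maximum(lateral - spec.tip_cap_px, 0.0) * tan_roof) & (
            d <= spec.wall_length * np.cos(rad) - lateral * tan_floor
        )
        inside = valid & in_depth & (lateral >= 0) & (lateral <= spec.ventricle_width)
        out[inside] = label
    return out


def _baseline_plane(spec: PhantomSpec, shape=(128, 128, 128), size=(224, 224)) -> PlaneSpec:
    cx, cz = (shape[0] // 2), (shape[2] // 2)
    return PlaneSpec(
        origin=np.array([cx, spec.pc_y, cz], dtype=float),
        normal=np.array([0.0, 1.0, 0.0]),
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 0.0, 1.0]),
        size=tuple(size),
        spacing=1.0,
    )


def make_wedge_slice(
    spec: PhantomSpec, size: tuple[int, int] = (224, 224)
) -> tuple[Slice2D, VentricleMask, tuple[WallLine, WallLine]]:
    """2D wedge phantom: intensity slice, truth mask, analytic wall lines."""
    h, w = size
    ii, jj = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    labels = _wedge_labels(spec, jj, ii, 0.0)
    _check_extent(spec, size)
    rng = np.random.default_rng(spec.seed)
    intensity = gaussian_filter((labels > 0).astype(float), sigma=1.5)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=labels.shape)
    plane = _baseline_plane(spec, size=size)
    return (
        Slice2D(data=intensity, plane=plane, mode="intensity"),
        VentricleMask(labels=labels, spacing=1.0),
        spec.truth_wall_lines(),
    )


def _check_extent(spec: PhantomSpec, size, lateral_limit: float | None = None) -> None:
    """Raise if the walls exit the image/volume anywhere along the extrusion."""
    xa, ya = spec.apex_position
    dys = np.array([-spec.extrusion_half_depth, 0.0, spec.extrusion_half_depth])
    a_l, a_r = spec.half_angles_deg(dys)
    a_max = np.deg2rad(np.max(np.concatenate([a_l, a_r])))
    reach = spec.wall_length * np.sin(a_max) + spec.ventricle_width + spec.gap / 2.0
    depth = spec.wall_length  # cos <= 1
    h, w = size
    half = lateral_limit if lateral_limit is not None else min(xa, w - 1 - xa)
    if reach > half or ya + depth > h - 1:
        raise CaliperError(
            f"walls exit the image: lateral reach {reach:.1f} px exceeds {half:.1f}"
        )


@dataclass
class PhantomVolume:
    """A 3D phantom: intensity volume, label volume, landmarks, analytics."""

    volume: VolumeGrid
    labels: np.ndarray
    landmarks: LandmarkSet
    spec: PhantomSpec
    rotation: np.ndarray
    center: np.ndarray

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Analytic multiclass membership at arbitrary 3D voxel coordinates."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        p0 = (p - self.center) @ self.rotation + self.center  # inverse tilt
        shape = self.volume.data.shape
        cx, cz = shape[0] // 2, shape[2] // 2
        x_img = p0[:, 0] - cx + 112.0
        y_img = 112.0 - (p0[:, 2] - cz)
        dy = p0[:, 1] - self.spec.pc_y
        return _wedge_labels(self.spec, x_img, y_img, dy)

    def baseline_plane(self, size=(224, 224)) -> PlaneSpec:
        """The true measurement plane (tilt applied), for reference."""
        p = _baseline_plane(self.spec, self.volume.data.shape, size)
        r = self.rotation
        rot = lambda v: r @ v  # forward tilt
        origin = rot(p.origin - self.center) + self.center
        from dataclasses import replace

        return replace(
            p, origin=origin, normal=rot(p.normal), u_axis=rot(p.u_axis), v_axis=rot(p.v_axis)
        )

    @property
    def truth_angle_deg(self) -> float:
        return self.spec.apex_angle_deg


def make_phantom_volume(
    spec: PhantomSpec, shape: tuple[int, int, int] = (128, 128, 128)
) -> PhantomVolume:
    """Build the 3D phantom volume, label volume, and true landmarks.

    The tilt angles rotate the phantom geometry and the landmarks jointly about
    the volume center (sagittal tilt about the left-right axis, then axial tilt
    about the superior axis). The labels are rasterized analytically on the
    rotated grid, so no resampling artifacts are introduced by tilting.
    """
    _check_extent(spec, (224, 224), lateral_limit=min(shape[0] // 2, shape[2] // 2) - 1)
    rot = (
        Rotation.from_euler(
            "zx", [spec.tilt_axial_deg, spec.tilt_sagittal_deg], degrees=True
        ).as_matrix()
    )
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    ph = PhantomVolume(
        volume=VolumeGrid(data=np.zeros(shape), affine=np.eye(4)),
        labels=np.empty(0),
        landmarks=_make_landmarks(spec, shape, rot, center),
        spec=spec,
        rotation=rot,
        center=center,
    )
    labels = np.zeros(shape, dtype=np.int64)
    lo, hi = _wedge_bbox(spec, shape, rot, center)
    axes = [np.arange(lo[i], hi[i], dtype=float) for i in range(3)]
    bb = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    labels[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] = ph.label_at(
        bb.reshape(-1, 3)
    ).reshape(bb.shape[:3])
    rng = np.random.default_rng(spec.seed)
    intensity = gaussian_filter((labels > 0).astype(float), sigma=1.5)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape)
    ph.volume = VolumeGrid(data=intensity, affine=np.eye(4))
    ph.labels = labels
    return ph


def _wedge_bbox(spec: PhantomSpec, shape, rot, center) -> tuple[np.ndarray, np.ndarray]:
    """Voxel bounding box (lo inclusive, hi exclusive) containing the wedge."""
    cx, cz = shape[0] // 2, shape[2] // 2
    xa3 = cx + (spec.apex_position[0] - 112.0)
    z_apex = cz + (112.0 - spec.apex_position[1])
    reach = spec.wall_length + spec.ventricle_width + spec.gap / 2.0
    xs = (xa3 - reach, xa3 + reach)
    ys = (spec.pc_y - spec.extrusion_half_depth, spec.pc_y + spec.extrusion_half_depth)
    zs = (z_apex - spec.wall_length, z_apex)
    corners = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    world = (corners - center) @ rot.T + center
    lo = np.clip(np.floor(world.min(axis=0)) - 1, 0, np.asarray(shape)).astype(int)
    hi = np.clip(np.ceil(world.max(axis=0)) + 2, 0, np.asarray(shape)).astype(int)
    return lo, hi


def _make_landmarks(spec, shape, rot, center) -> LandmarkSet:
    cx, cz = shape[0] // 2, shape[2] // 2
    pc0 = np.array([cx, spec.pc_y, cz], dtype=float)
    ac0 = pc0 + np.array([0.0, spec.ac_pc_distance, 0.0])
    pc = rot @ (pc0 - center) + center
    ac = rot @ (ac0 - center) + center
    return LandmarkSet(ac=ac, pc=pc, world_ac=ac, world_pc=pc, source="phantom")


@dataclass
class PhantomSegmenter:
    """Perfect segmenter: analytic ventricle mask of any requested plane.

    When the slice plane lives in preprocessed-cube coordinates that differ
    from the phantom's source grid, pass the PreprocessedVolume so sample
    points are mapped back to the source frame first.
    """

    phantom: PhantomVolume
    preprocessed: PreprocessedVolume | None = None

    def __call__(self, s: Slice2D) -> VentricleMask:
        pts = s.plane.grid_xyz().reshape(-1, 3)
        if self.preprocessed is not None:
            pts = np.atleast_2d(self.preprocessed.cube_to_source_voxel(pts))
        labels = self.phantom.label_at(pts).reshape(s.plane.size)
        return VentricleMask(labels=labels, spacing=s.plane.spacing)


@dataclass
class PhantomLandmarkProvider:
    """Ground-truth landmark provider for a phantom volume."""

    phantom: PhantomVolume
    preprocessed: PreprocessedVolume | None = None

    def __call__(self, volume: PreprocessedVolume | None = None) -> LandmarkSet:
        vol = volume or self.preprocessed
        lm = self.phantom.landmarks
        if vol is None:
            return lm
        ac = np.atleast_1d(vol.source_voxel_to_cube(lm.ac))
        pc = np.atleast_1d(vol.source_voxel_to_cube(lm.pc))
        out = LandmarkSet(ac=ac, pc=pc, source="phantom")
        return out.with_world_from(vol)
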