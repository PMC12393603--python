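"""Callosal-angle geometry: separator, medial walls, wall lines, angle.

Given the two lateral-ventricle contours on the coronal measurement plane, the
callosal angle is computed in four geometric stages:

1. A maximum-margin line separating the two contours. For separable contours
   this is solved exactly as the perpendicular bisector of the shortest segment
   between their convex hulls (identical to the hard-margin SVM solution, but
   deterministic and exactly symmetric under mirroring); a soft-margin linear
   SVM is used only as a fallback for slightly overlapping contours.
2. Rays cast perpendicular to the separating line; the first collision with
   each ventricle's contour yields that side's medial-wall point set.
3. Base points: among each contour's points lying close to the other contour,
   the most superior one.
4. For each side, the line through the base point crossing the most medial-wall
   points (within a tolerance band), ties broken by minimal inlier RMS; the
   angle between the two inferior-oriented wall directions is the callosal
   angle. Angles below the 90 degree threshold are classified "narrow".

All 2D coordinates are (x, y) pixels with y increasing inferiorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint
from shapely.ops import nearest_points

from .errors import (
    GeometryError,
    MedialWallError,
    PipelineStageError,
    SeparationError,
    WallFitError,
)
from .plane_geometry import Slice2D
from .ventricle_masks import Contour, VentricleMask, extract_contours

__all__ = [
    "CAConfig",
    "SeparatingLine",
    "MedialWall",
    "WallLine",
    "CAResult",
    "fit_separating_line",
    "cast_medial_rays",
    "find_base_points",
    "fit_wall_line",
    "angle_between_walls",
    "measure_ca",
]


@dataclass(frozen=True)
class CAConfig:
    """Tunables of the angle-measurement geometry (pixel units, degrees)."""

    ray_step: float = 1.0
    wall_tol: float = 1.5
    angular_step: float = 0.25
    base_threshold: float = 5.0
    classification_threshold: float = 90.0
    min_component_px: int = 5

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SeparatingLine:
    point: np.ndarray
    direction: np.ndarray
    margin: float
    soft: bool = False

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)

    def side_values(self, pts: np.ndarray) -> np.ndarray:
        """Signed perpendicular coordinate of points relative to the line."""
        rel = np.atleast_2d(pts) - self.point
        d = self.direction
        return d[0] * rel[:, 1] - d[1] * rel[:, 0]


@dataclass
class MedialWall:
    points: np.ndarray
    side: str  # left | right
    ray_indices: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.ray_indices = np.asarray(self.ray_indices, dtype=int)


@dataclass
class WallLine:
    base_point: np.ndarray
    direction: np.ndarray  # unit, oriented inferiorly (positive y)
    inlier_count: int
    inlier_rms: float

    def __post_init__(self) -> None:
        self.base_point = np.asarray(self.base_point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def angle_from_vertical_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.direction[0], self.direction[1])))


def _points_of(obj) -> np.ndarray:
    if isinstance(obj, Contour):
        return obj.points
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise GeometryError("expected a nonempty (n, 2) point set")
    return pts


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    d = d / np.linalg.norm(d)
    if d[1] < 0 or (d[1] == 0 and d[0] < 0):
        d = -d
    return d


def fit_separating_line(left, right) -> SeparatingLine:
    """Maximum-margin line between the two contours.

    Exact hard-margin solution via the shortest segment between convex hulls
    when the contours are disjoint; soft-margin linear SVM fallback when they
    touch or overlap slightly. Overlap beyond 20% of the smaller hull area is
    an error ("ventricles not separable").
    """
    lp, rp = _points_of(left), _points_of(right)
    hull_l = MultiPoint(lp).convex_hull
    hull_r = MultiPoint(rp).convex_hull
    dist = hull_l.distance(hull_r)
    if dist > 0:
        a, b = nearest_points(hull_l, hull_r)
        pa = np.array([a.x, a.y])
        pb = np.array([b.x, b.y])
        w = pb - pa
        direction = _canonical_direction(np.array([-w[1], w[0]]))
        return SeparatingLine(point=(pa + pb) / 2, direction=direction, margin=dist / 2)
    inter = hull_l.intersection(hull_r).area
    smaller = min(hull_l.area, hull_r.area)
    if smaller > 0 and inter > 0.20 * smaller:
        raise SeparationError("ventricles not separable (contours overlap > 20%)")
    from sklearn.svm import SVC

    x = np.vstack([lp, rp])
    y = np.concatenate([np.zeros(len(lp)), np.ones(len(rp))])
    clf = SVC(kernel="linear", C=10.0, tol=1e-8, random_state=0).fit(x, y)
    w = clf.coef_[0]
    b = float(clf.intercept_[0])
    norm_w = np.linalg.norm(w)
    q = x.mean(axis=0)
    q = q - (np.dot(w, q) + b) / norm_w**2 * w
    direction = _canonical_direction(np.array([-w[1], w[0]]))
    s = (x @ w + b) / norm_w
    sign_l = -1.0 if np.mean(s[: len(lp)]) < 0 else 1.0
    margin = float(min(np.min(sign_l * s[: len(lp)]), np.min(-sign_l * s[len(lp):])))
    return SeparatingLine(point=q, direction=direction, margin=max(0.0, margin), soft=True)


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _first_hits(
    origins: np.ndarray,
    ray_dir: np.ndarray,
    poly: np.ndarray,
    min_incidence_deg: float = 6.0,
):
    """First intersection of each ray with a closed polygon (vectorized).

    Hits where the ray meets the contour at grazing incidence (angle between
    ray and the local contour tangent below ``min_incidence_deg``) are
    discarded: a tangential first collision is numerically unstable and does
    not sample the medial wall, only corner arcs and roof/floor edges running
    parallel to the rays. Returns (t_hit, hit_points); t_hit is NaN where a
    ray has no stable hit.
    """
    a = poly
    e = np.roll(poly, -1, axis=0) - poly  # edge vectors
    denom = _cross2(ray_dir[None, :], e)  # (J,)
    rel = a[None, :, :] - origins[:, None, :]  # (K, J, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = _cross2(rel, e[None, :, :]) / denom[None, :]
        s = _cross2(rel, np.broadcast_to(ray_dir, e.shape)[None, :, :]) / denom[None, :]
    # local tangent from a +/-2 vertex chord: single marching-squares segments
    # wiggle with the pixel staircase, the windowed chord tracks the true
    # boundary direction
    chord = np.roll(poly, -3, axis=0) - np.roll(poly, 2, axis=0)
    chord_norm = np.linalg.norm(chord, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_incidence = np.abs(_cross2(ray_dir[None, :], chord)) / np.where(
            chord_norm > 0, chord_norm, np.inf
        )
    intersects = (
        (np.abs(denom)[None, :] > 1e-12)
        & (t >= 1e-9)
        & (s >= -1e-9)
        & (s <= 1 + 1e-9)
    )
    t = np.where(intersects, t, np.inf)
    first = t.argmin(axis=1)
    t_hit = t[np.arange(len(origins)), first]
    graze = sin_incidence[first] < np.sin(np.deg2rad(min_incidence_deg))
    # a tangential first collision invalidates the ray; do not fall through
    # to whatever surface lies behind it
    t_hit = np.where(np.isfinite(t_hit) & ~graze, t_hit, np.nan)
    pts = origins + t_hit[:, None] * ray_dir
    return t_hit, pts


def cast_medial_rays(
    line: SeparatingLine, left, right, step: float = 1.0
) -> tuple[MedialWall, MedialWall]:
    """Perpendicular rays from the separating line; first hit per side.

    Ray origins are spaced ``step`` pixels apart along the line, centered on
    the midpoint of the contours' projected extent (which makes the ray set
    exactly mirror-symmetric for mirror-symmetric inputs).
    """
    lp, rp = _points_of(left), _points_of(right)
    d = line.direction / np.linalg.norm(line.direction)
    q = line.point
    t_all = (np.vstack([lp, rp]) - q) @ d
    t_mid = (t_all.min() + t_all.max()) / 2
    k = int(np.floor((t_all.max() - t_all.min()) / (2 * step)))
    ts = t_mid + np.arange(-k, k + 1) * step
    origins = q + ts[:, None] * d

    perp = np.array([-d[1], d[0]])
    sign_left = 1.0 if np.dot(perp, lp.mean(axis=0) - q) >= 0 else -1.0
    walls = []
    for side, pts, normal in (
        ("left", lp, sign_left * perp),
        ("right", rp, -sign_left * perp),
    ):
        t_hit, hit_pts = _first_hits(origins, normal, pts)
        ok = np.isfinite(t_hit)
        if ok.sum() < 3:
            raise MedialWallError(f"medial wall too short on {side} side")
        walls.append(
            MedialWall(points=hit_pts[ok], side=side, ray_indices=np.nonzero(ok)[0])
        )
    return walls[0], walls[1]


def _densify_closed_polyline(pts: np.ndarray, step: float = 0.2) -> np.ndarray:
    """Subdivide each segment of a closed polyline into ~``step``-px pieces.

    Subdivision is per segment (no running arc-length phase), so mirroring the
    polyline mirrors the resampled point set exactly.
    """
    nxt = np.roll(pts, -1, axis=0)
    seg = nxt - pts
    lengths = np.linalg.norm(seg, axis=1)
    n_sub = np.maximum(np.ceil(lengths / step).astype(int), 1)
    out = []
    for a, d, n in zip(pts, seg, n_sub):
        fracs = np.arange(n) / n
        out.append(a + fracs[:, None] * d)
    return np.concatenate(out, axis=0)


def find_base_points(
    left, right, threshold: float = 5.0, superior_tol: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Most superior near-contact point of each ventricle.

    Candidates are contour points within ``max(threshold, d_min + 1)`` pixels
    of the other contour, where d_min is the minimal inter-contour distance
    (the guard guarantees a nonempty candidate set). The most superior
    candidate is each side's base point; superiority is resolved with a
    ``superior_tol`` pixel tolerance, inside which the candidate closest to
    the other contour wins (the base point is a point of near-contact, and on
    discretized contours the literal y-minimum can sit a pixel away from the
    true contact corner along the ventricle roof).
    """
    lp = _densify_closed_polyline(_points_of(left))
    rp = _densify_closed_polyline(_points_of(right))
    d = cdist(lp, rp)
    thr = max(float(threshold), float(d.min()) + 1.0)
    bases = []
    for pts, dist in ((lp, d.min(axis=1)), (rp, d.min(axis=0))):
        sel = dist <= thr
        cand, cd = pts[sel], dist[sel]
        near_top = cand[:, 1] <= cand[:, 1].min() + superior_tol
        cand, cd = cand[near_top], cd[near_top]
        order = np.lexsort((cand[:, 0], cand[:, 1], cd))
        bases.append(cand[order[0]].copy())
    return bases[0], bases[1]


def _wrap_half(phi: np.ndarray) -> np.ndarray:
    """Wrap direction angles (degrees from vertical) into [-90, 90)."""
    return (np.asarray(phi, dtype=float) + 90.0) % 180.0 - 90.0


def fit_wall_line(
    base, wall: MedialWall | np.ndarray, tol: float = 1.5, angular_step: float = 0.25
) -> WallLine:
    """Line through the base point crossing the most medial-wall points.

    The direction search combines a coarse sweep at ``angular_step`` with the
    exact critical angles at which each wall point enters or leaves the
    ``tol``-pixel band, so the maximal inlier count is found exactly. Ties are
    broken by minimal RMS distance of the inliers (with a least-squares
    refinement of the direction over each winning inlier set), then by the
    smaller angle from vertical. The returned direction points inferiorly.
    """
    base = np.asarray(base, dtype=float)
    pts = wall.points if isinstance(wall, MedialWall) else np.asarray(wall, dtype=float)
    if len(pts) < 3:
        raise WallFitError("need >= 3 wall points")
    r = pts - base
    rho = np.linalg.norm(r, axis=1)
    alpha = np.degrees(np.arctan2(r[:, 0], r[:, 1]))  # angle from inferior axis

    far = rho > tol
    cand = [np.arange(-90.0, 90.0, angular_step)]
    if far.any():
        delta = np.degrees(np.arcsin(np.clip(tol / rho[far], -1.0, 1.0)))
        edges = np.concatenate([alpha[far] - delta, alpha[far] + delta])
        cand.append(_wrap_half(edges))
    phi = np.unique(np.concatenate(cand))

    def distances(phi_arr: np.ndarray) -> np.ndarray:
        # (C, N) distance of each point from the line at each candidate angle
        dphi = np.deg2rad(phi_arr[:, None] - alpha[None, :])
        return np.abs(np.sin(dphi)) * rho[None, :]

    def evaluate(phi_arr: np.ndarray):
        dmat = distances(phi_arr)
        inl = dmat <= tol + 1e-9
        counts = inl.sum(axis=1)
        return dmat, inl, counts

    dmat, inliers, counts = evaluate(phi)
    best = int(counts.max())
    if best < 3:
        raise WallFitError("no linear wall (best inlier count < 3)")

    # Least-squares refinement of direction over each winning inlier set.
    top = np.nonzero(counts == best)[0]
    refined = []
    seen = set()
    for idx in top:
        key = inliers[idx].tobytes()
        if key in seen:
            continue
        seen.add(key)
        ri = r[inliers[idx]]
        m = ri.T @ ri
        _, vecs = np.linalg.eigh(m)
        d_ls = vecs[:, -1]
        refined.append(float(_wrap_half(np.degrees(np.arctan2(d_ls[0], d_ls[1])))))
    if refined:
        phi2 = np.unique(np.concatenate([phi, np.asarray(refined)]))
        dmat, inliers, counts = evaluate(phi2)
        best = int(counts.max())
        phi = phi2

    top = np.nonzero(counts == best)[0]
    rms = np.sqrt(
        np.sum(np.where(inliers[top], dmat[top] ** 2, 0.0), axis=1) / best
    )
    order = np.lexsort((np.abs(phi[top]), rms))
    pick = top[order[0]]
    phi_best = float(phi[pick])
    direction = np.array([np.sin(np.deg2rad(phi_best)), np.cos(np.deg2rad(phi_best))])
    if direction[1] < 0 or (direction[1] == 0 and direction[0] < 0):
        direction = -direction
    return WallLine(
        base_point=base,
        direction=direction,
        inlier_count=best,
        inlier_rms=float(rms[order[0]]),
    )


def angle_between_walls(left: WallLine, right: WallLine) -> float:
    """Opening angle (degrees) between two inferior-oriented wall directions."""
    out = []
    for w in (left, right):
        n = np.linalg.norm(w.direction)
        if n < 1e-12:
            raise GeometryError("zero wall direction")
        out.append(w.direction / n)
    dot = float(np.dot(out[0], out[1]))
    return float(np.degrees(np.arccos(np.clip(dot, -1.0, 1.0))))


@dataclass
class CAResult:
    """Measured callosal angle with all intermediate geometry for audit."""

    angle_deg: float
    classification: str
    left_wall: WallLine
    right_wall: WallLine
    separating_line: SeparatingLine
    medial_walls: tuple[MedialWall, MedialWall]
    base_points: tuple[np.ndarray, np.ndarray]
    diagnostics: list = field(default_factory=list)
    config: CAConfig = field(default_factory=CAConfig)

    def __post_init__(self) -> None:
        expected = angle_between_walls(self.left_wall, self.right_wall)
        if abs(expected - self.angle_deg) > 1e-9:
            raise GeometryError("angle inconsistent with wall directions")

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "classification": self.classification,
            "left_wall": {
                "base_point": self.left_wall.base_point.tolist(),
                "direction": self.left_wall.direction.tolist(),
                "inlier_count": self.left_wall.inlier_count,
                "inlier_rms": self.left_wall.inlier_rms,
            },
            "right_wall": {
                "base_point": self.right_wall.base_point.tolist(),
                "direction": self.right_wall.direction.tolist(),
                "inlier_count": self.right_wall.inlier_count,
                "inlier_rms": self.right_wall.inlier_rms,
            },
            "separating_line": {
                "point": self.separating_line.point.tolist(),
                "direction": self.separating_line.direction.tolist(),
                "margin": self.separating_line.margin,
                "soft": self.separating_line.soft,
            },
            "base_points": [p.tolist() for p in self.base_points],
            "diagnostics": list(self.diagnostics),
            "config": self.config.to_dict(),
        }


def classify_angle(angle_deg: float, threshold: float = 90.0) -> str:
    """"narrow" iff strictly below the threshold, else "wide" (90 -> wide)."""
    return "narrow" if angle_deg < threshold else "wide"


def measure_ca(
    slice2d: Slice2D | None, mask: VentricleMask, config: CAConfig | None = None
) -> CAResult:
    """Run contouring through angle calculation on one coronal mask.

    ``slice2d`` is carried for provenance/plotting only; the geometry depends
    on the mask alone. Stage failures are re-raised as
    :class:`PipelineStageError` naming the stage.
    """
    cfg = config or CAConfig()
    diagnostics: list[str] = []

    def run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    left_c, right_c = run("contours", extract_contours, mask, min_area=cfg.min_component_px)
    sep = run("separating_line", fit_separating_line, left_c, right_c)
    if sep.soft:
        diagnostics.append("soft-margin separator fallback (contours touch/overlap)")
    wall_l, wall_r = run("medial_rays", cast_medial_rays, sep, left_c, right_c, step=cfg.ray_step)
    base_l, base_r = run("base_points", find_base_points, left_c, right_c, threshold=cfg.base_threshold)
    line_l = run("wall_fit_left", fit_wall_line, base_l, wall_l, tol=cfg.wall_tol, angular_step=cfg.angular_step)
    line_r = run("wall_fit_right", fit_wall_line, base_r, wall_r, tol=cfg.wall_tol, angular_step=cfg.angular_step)
    angle = run("angle", angle_between_walls, line_l, line_r)
    return CAResult(
        angle_deg=angle,
        classification=classify_angle(angle, cfg.classification_threshold),
        left_wall=line_l,
        right_wall=line_r,
        separating_line=sep,
        medial_walls=(wall_l, wall_r),
        base_points=(base_l, base_r),
        diagnostics=diagnostics,
        config=cfg,
    )
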