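"""AC/PC landmark containers, providers, and localization metrics.

The anterior and posterior commissures (AC, PC) define the AC-PC line used to
orient the coronal measurement plane. Landmarks can come from a JSON file (e.g.
exported from a manual annotation tool or an external detector) or from the
synthetic phantom, both behind the same provider contract. Metrics follow
standard keypoint-evaluation practice: per-landmark Euclidean error, PCK@10
(correct if the error is below 10% of the AC-PC distance), and the undirected
pitch angle between two AC-PC lines.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .errors import FrameMismatchError, LandmarkError
from .volume_io import PreprocessedVolume

__all__ = [
    "LandmarkSet",
    "LandmarkProvider",
    "FileLandmarkProvider",
    "load_landmarks",
    "save_landmarks",
    "landmark_error",
    "pck_at_10",
    "pck_fraction",
    "pitch_angle_between",
]


@dataclass
class LandmarkSet:
    """AC and PC positions in cube-voxel coordinates, optionally world mm."""

    ac: np.ndarray
    pc: np.ndarray
    world_ac: np.ndarray | None = None
    world_pc: np.ndarray | None = None
    source: str = "annotated"  # annotated | predicted | phantom

    def __post_init__(self) -> None:
        self.ac = np.asarray(self.ac, dtype=float)
        self.pc = np.asarray(self.pc, dtype=float)
        for name in ("ac", "pc"):
            arr = getattr(self, name)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise LandmarkError(f"{name} must be a finite 3-vector")
        if np.allclose(self.ac, self.pc):
            raise LandmarkError("AC and PC coincide")
        if self.world_ac is not None:
            self.world_ac = np.asarray(self.world_ac, dtype=float)
        if self.world_pc is not None:
            self.world_pc = np.asarray(self.world_pc, dtype=float)

    @property
    def has_world(self) -> bool:
        return self.world_ac is not None and self.world_pc is not None

    def ac_pc_distance(self, frame: str = "cube") -> float:
        a, p = self._frame_coords(frame)
        return float(np.linalg.norm(a - p))

    def _frame_coords(self, frame: str) -> tuple[np.ndarray, np.ndarray]:
        if frame == "cube":
            return self.ac, self.pc
        if frame == "world":
            if not self.has_world:
                raise FrameMismatchError("world coordinates not available")
            return self.world_ac, self.world_pc
        raise ValueError(f"unknown frame {frame!r}")

    def with_world_from(self, p: PreprocessedVolume) -> "LandmarkSet":
        """Attach world (mm) coordinates via the preprocessed-volume transform."""
        return LandmarkSet(
            ac=self.ac,
            pc=self.pc,
            world_ac=p.cube_to_world(self.ac),
            world_pc=p.cube_to_world(self.pc),
            source=self.source,
        )


class LandmarkProvider(Protocol):
    """Anything that yields a LandmarkSet for a preprocessed volume.

    Implementations must be deterministic for a fixed input. A trained
    landmark-detection network is one possible provider; this package ships a
    file-based provider and the phantom's ground-truth provider.
    """

    def __call__(self, volume: PreprocessedVolume) -> LandmarkSet: ...


@dataclass
class FileLandmarkProvider:
    """Reads landmarks from a JSON file, converting world -> cube if needed."""

    path: str
    source: str = "annotated"

    def __call__(self, volume: PreprocessedVolume | None = None) -> LandmarkSet:
        return load_landmarks(self.path, volume=volume, source=self.source)


def load_landmarks(
    path, volume: PreprocessedVolume | None = None, source: str = "annotated"
) -> LandmarkSet:
    """Read ``{"ac": [x,y,z], "pc": [x,y,z], "space": "voxel"|"world"}`` JSON."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise LandmarkError(f"landmark file not found: {path}")
    with open(path) as fh:
        obj = json.load(fh)
    try:
        ac = np.asarray(obj["ac"], dtype=float)
        pc = np.asarray(obj["pc"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise LandmarkError(f"malformed landmark file {path}: {exc}") from exc
    space = obj.get("space", "voxel")
    if space == "world":
        if volume is None:
            raise LandmarkError("world-space landmarks require a preprocessed volume")
        lm = LandmarkSet(
            ac=volume.world_to_cube(ac), pc=volume.world_to_cube(pc),
            world_ac=ac, world_pc=pc, source=source,
        )
    elif space == "voxel":
        lm = LandmarkSet(ac=ac, pc=pc, source=source)
        if volume is not None:
            lm = lm.with_world_from(volume)
    else:
        raise LandmarkError(f"unknown landmark space {space!r}")
    return lm


def save_landmarks(lm: LandmarkSet, path, space: str = "voxel") -> None:
    if space == "voxel":
        obj = {"ac": list(lm.ac), "pc": list(lm.pc), "space": "voxel"}
    elif space == "world":
        if not lm.has_world:
            raise FrameMismatchError("world coordinates not available")
        obj = {"ac": list(lm.world_ac), "pc": list(lm.world_pc), "space": "world"}
    else:
        raise ValueError(f"unknown space {space!r}")
    with open(os.fspath(path), "w") as fh:
        json.dump(obj, fh, indent=2)


def landmark_error(
    pred: LandmarkSet, truth: LandmarkSet, frame: str = "world"
) -> dict[str, float]:
    """Per-landmark 3D Euclidean distance between prediction and truth.

    Distances are in the units of ``frame`` (mm for "world", cube voxels for
    "cube"). Both sets must carry the requested frame.
    """
    pa, pp = pred._frame_coords(frame)
    ta, tp = truth._frame_coords(frame)
    return {
        "ac": float(np.linalg.norm(pa - ta)),
        "pc": float(np.linalg.norm(pp - tp)),
    }


def pck_at_10(
    pred: LandmarkSet, truth: LandmarkSet, frame: str = "cube"
) -> dict[str, bool]:
    """Correctness at the PCK@10 threshold.

    A landmark is correct iff its Euclidean error is strictly below 10% of the
    ground-truth AC-PC distance. Scale-invariant by construction.
    """
    ref = truth.ac_pc_distance(frame)
    if ref <= 0:
        raise LandmarkError("zero AC-PC distance in ground truth")
    err = landmark_error(pred, truth, frame=frame)
    thr = 0.10 * ref
    return {"ac": err["ac"] < thr, "pc": err["pc"] < thr}


def pck_fraction(
    pairs: list[tuple[LandmarkSet, LandmarkSet]], frame: str = "cube"
) -> float:
    """Aggregate PCK@10 over a cohort: fraction of correct landmarks."""
    flags: list[bool] = []
    for pred, truth in pairs:
        d = pck_at_10(pred, truth, frame=frame)
        flags.extend([d["ac"], d["pc"]])
    return float(np.mean(flags)) if flags else float("nan")


def pitch_angle_between(l1: LandmarkSet, l2: LandmarkSet, frame: str = "cube") -> float:
    """Undirected 3D angle in degrees between the two AC-PC lines, in [0, 90]."""
    angles = []
    for lm in (l1, l2):
        a, p = lm._frame_coords(frame)
        d = a - p
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise LandmarkError("degenerate AC-PC line")
        angles.append(d / n)
    dot = abs(float(np.dot(angles[0], angles[1])))
    return float(np.degrees(np.arccos(np.clip(dot, -1.0, 1.0))))
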