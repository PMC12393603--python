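"""Sensitivity of the callosal angle to plane placement errors.

The experiment perturbs one degree of freedom at a time — posterior-commissure
position along the AC-PC line (cube voxels, 1 voxel = scale_factor mm), plane
rotation about the in-plane left-right axis (sagittal, degrees), and about the
in-plane superior axis (axial, degrees) — re-extracts the slice, re-runs the
segmenter, re-measures the angle, and tabulates the deviation from the
unperturbed baseline. Paired t-tests compare each nonzero offset against
baseline across cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ca_core import CAConfig, measure_ca
from .errors import CaliperError
from .landmarks import LandmarkSet
from .plane_geometry import PlaneSpec, build_plane, extract_slice, perturb_plane
from .volume_io import PreprocessedVolume

__all__ = [
    "PerturbationGrid",
    "run_perturbation_grid",
    "paired_t_test",
    "summarize_sensitivity",
]

AXES = ("pc_shift", "sagittal", "axial")


@dataclass(frozen=True)
class PerturbationGrid:
    """Offsets per perturbation axis; 0 must be present as the baseline anchor."""

    pc_shifts: tuple = tuple(range(-10, 11))
    sagittal_degs: tuple = tuple(range(-10, 11))
    axial_degs: tuple = tuple(range(-10, 11))

    def __post_init__(self) -> None:
        for name in ("pc_shifts", "sagittal_degs", "axial_degs"):
            vals = tuple(float(v) for v in getattr(self, name))
            object.__setattr__(self, name, vals)
            if 0.0 not in vals:
                raise CaliperError(f"{name} must contain 0 (baseline anchor)")

    def offsets(self, axis: str) -> tuple:
        return {
            "pc_shift": self.pc_shifts,
            "sagittal": self.sagittal_degs,
            "axial": self.axial_degs,
        }[axis]


def run_perturbation_grid(
    volume: PreprocessedVolume,
    landmarks: LandmarkSet,
    segmenter,
    grid: PerturbationGrid | None = None,
    config: CAConfig | None = None,
    case_id: str = "case0",
    size: tuple[int, int] = (224, 224),
    extract_intensity: bool = False,
) -> pd.DataFrame:
    """One measured angle per (axis, offset), compared to the shared baseline.

    Each axis is perturbed independently with the others at zero. Per-offset
    failures are recorded as missing (NaN) rather than aborting the grid; the
    baseline itself must succeed. Columns: case, axis, offset, ca_deg,
    abs_err_deg.
    """
    grid = grid or PerturbationGrid()
    cfg = config or CAConfig()
    base_plane = build_plane(landmarks, size=size)

    def measure_at(plane: PlaneSpec) -> float:
        mask = segmenter(_plane_slice(volume, plane, extract_intensity))
        return measure_ca(None, mask, cfg).angle_deg

    baseline = measure_at(base_plane)
    rows = []
    for axis in AXES:
        for off in grid.offsets(axis):
            if off == 0.0:
                ca = baseline
            else:
                kwargs = {
                    "pc_shift": off if axis == "pc_shift" else 0.0,
                    "sagittal_deg": off if axis == "sagittal" else 0.0,
                    "axial_deg": off if axis == "axial" else 0.0,
                }
                try:
                    ca = measure_at(perturb_plane(base_plane, **kwargs))
                except CaliperError:
                    ca = float("nan")
            rows.append(
                {
                    "case": case_id,
                    "axis": axis,
                    "offset": off,
                    "ca_deg": ca,
                    "abs_err_deg": abs(ca - baseline) if np.isfinite(ca) else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def _plane_slice(volume: PreprocessedVolume, plane: PlaneSpec, extract_intensity: bool):
    if extract_intensity:
        return extract_slice(volume, plane, mode="intensity")
    # Segmenters only need the plane geometry; skip the interpolation cost.
    from .plane_geometry import Slice2D

    return Slice2D(data=np.zeros(plane.size), plane=plane, mode="intensity")


def paired_t_test(baseline, perturbed) -> tuple[float, float]:
    """Classic paired t on the differences; returns (t, two-sided p)."""
    b = np.asarray(baseline, dtype=float)
    p = np.asarray(perturbed, dtype=float)
    if b.shape != p.shape or b.ndim != 1 or b.size < 3:
        raise CaliperError("paired t-test needs equal-length 1D samples, n >= 3")
    d = p - b
    if np.allclose(d, d[0]):
        if abs(d[0]) < 1e-300:
            return 0.0, 1.0
        raise CaliperError("zero-variance differences: t statistic undefined")
    t, pv = stats.ttest_rel(p, b)
    return float(t), float(pv)


def summarize_sensitivity(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of |delta CA| per (axis, offset), with paired t vs baseline.

    Expects the concatenated per-case tables from :func:`run_perturbation_grid`.
    """
    out = []
    for axis in table["axis"].unique():
        sub = table[table["axis"] == axis]
        base = sub[sub["offset"] == 0.0].set_index("case")["ca_deg"]
        for off in sorted(sub["offset"].unique()):
            s = sub[sub["offset"] == off].set_index("case")
            common = base.index.intersection(s.index)
            pert = s.loc[common, "ca_deg"]
            ok = np.isfinite(pert.to_numpy())
            abs_err = s.loc[common, "abs_err_deg"].to_numpy()[ok]
            row = {
                "axis": axis,
                "offset": off,
                "n": int(ok.sum()),
                "mean_abs_err_deg": float(np.mean(abs_err)) if ok.any() else float("nan"),
                "sd_abs_err_deg": (
                    float(np.std(abs_err, ddof=1)) if ok.sum() > 1 else float("nan")
                ),
            }
            if off == 0.0:
                row["t"], row["p"] = float("nan"), float("nan")
            else:
                try:
                    row["t"], row["p"] = paired_t_test(
                        base.loc[common].to_numpy()[ok], pert.to_numpy()[ok]
                    )
                except CaliperError:
                    row["t"], row["p"] = float("nan"), float("nan")
            out.append(row)
    return pd.DataFrame(out)
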