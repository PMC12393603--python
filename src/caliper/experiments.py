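"""Reusable phantom experiments: recovery grids, cohorts, sensitivity runs.

These functions drive the full pipeline (volume -> preprocess -> landmarks ->
plane -> segment -> measure) over seeded phantom cohorts. They back the
`caliper perturb` CLI command, the acceptance checks, and the reproducibility
script; all randomness flows from explicit seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ca_core import CAConfig, CAResult, measure_ca
from .errors import CaliperError
from .landmarks import LandmarkSet
from .perturbation import PerturbationGrid, run_perturbation_grid
from .phantom import (
    PhantomSegmenter,
    PhantomSpec,
    PhantomVolume,
    make_phantom_volume,
)
from .plane_geometry import Slice2D, build_plane, extract_slice
from .volume_io import PreprocessedVolume, preprocess

__all__ = [
    "random_spec",
    "measure_phantom",
    "end_to_end_angle",
    "recovery_grid",
    "agreement_cohort",
    "perturbation_cohort",
]


def random_spec(
    rng: np.random.Generator,
    apex_angle_deg: float | None = None,
    noise_sd: float = 0.05,
    tilt_sagittal_deg: float = 0.0,
    tilt_axial_deg: float = 0.0,
) -> PhantomSpec:
    """Draw a phantom with plausible anatomical variation, fitting the volume."""
    apex = float(rng.uniform(60.0, 140.0)) if apex_angle_deg is None else apex_angle_deg
    return PhantomSpec(
        apex_angle_deg=apex,
        apex_position=(112.0 + float(rng.uniform(-5, 5)), 67.0),
        wall_length=float(rng.uniform(38.0, 44.0)),
        ventricle_width=float(rng.uniform(12.0, 15.0)),
        gap=float(rng.uniform(4.0, 8.0)),
        noise_sd=noise_sd,
        tilt_sagittal_deg=tilt_sagittal_deg,
        tilt_axial_deg=tilt_axial_deg,
        seed=int(rng.integers(0, 2**31 - 1)),
        angle_slope_deg_per_voxel=float(rng.uniform(1.5, 2.5)),
        wall_twist_deg_per_voxel=float(rng.uniform(0.5, 0.9)),
    )


def _prepare(ph: PhantomVolume) -> tuple[PreprocessedVolume, LandmarkSet]:
    pre = preprocess(ph.volume)
    from .phantom import PhantomLandmarkProvider

    lm = PhantomLandmarkProvider(ph)(pre)
    return pre, lm


def measure_phantom(
    ph: PhantomVolume,
    config: CAConfig | None = None,
    size: tuple[int, int] = (224, 224),
    extract_intensity: bool = True,
) -> CAResult:
    """Run the measurement pipeline on a phantom with its true landmarks."""
    pre, lm = _prepare(ph)
    plane = build_plane(lm, size=size)
    if extract_intensity:
        sl = extract_slice(pre, plane, mode="intensity")
    else:
        sl = Slice2D(data=np.zeros(plane.size), plane=plane, mode="intensity")
    mask = PhantomSegmenter(ph, preprocessed=pre)(sl)
    return measure_ca(sl, mask, config)


def end_to_end_angle(spec: PhantomSpec, config: CAConfig | None = None) -> float:
    """Measured angle of a freshly built phantom volume."""
    ph = make_phantom_volume(spec)
    return measure_phantom(ph, config=config, extract_intensity=True).angle_deg


def recovery_grid(
    apex_angles=(60.0, 80.0, 100.0, 120.0, 140.0),
    tilts=(0.0, 5.0, 10.0),
    noise_sds=(0.0, 0.05, 0.1),
    n_seeds: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end angle recovery over apex x tilt x noise conditions.

    Each (angle, tilt, noise) cell is run ``n_seeds`` times with freshly drawn
    phantom geometry. Tilts are applied as sagittal rotation of volume and
    landmarks jointly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for apex in apex_angles:
        for tilt in tilts:
            for noise in noise_sds:
                for k in range(n_seeds):
                    spec = random_spec(
                        rng,
                        apex_angle_deg=apex,
                        noise_sd=noise,
                        tilt_sagittal_deg=tilt,
                    )
                    try:
                        ca = end_to_end_angle(spec)
                        err = abs(ca - apex)
                    except CaliperError:
                        ca, err = float("nan"), float("inf")
                    rows.append(
                        {
                            "apex_deg": apex,
                            "tilt_deg": tilt,
                            "noise_sd": noise,
                            "replicate": k,
                            "ca_deg": ca,
                            "abs_err_deg": err,
                        }
                    )
    return pd.DataFrame(rows)


def agreement_cohort(
    n_cases: int = 30, seed: int = 0, noise_sd: float = 0.05
) -> pd.DataFrame:
    """Measured vs ground-truth angles over a random phantom cohort."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cases):
        spec = random_spec(rng, noise_sd=noise_sd)
        ca = end_to_end_angle(spec)
        rows.append({"case": f"case{i:03d}", "truth_deg": spec.apex_angle_deg, "ca_deg": ca})
    return pd.DataFrame(rows)


def perturbation_cohort(
    n_cases: int = 20,
    seed: int = 0,
    max_offset: int = 10,
    config: CAConfig | None = None,
) -> pd.DataFrame:
    """Per-case sensitivity tables over a phantom cohort (concatenated)."""
    rng = np.random.default_rng(seed)
    offsets = tuple(float(v) for v in range(-max_offset, max_offset + 1))
    grid = PerturbationGrid(pc_shifts=offsets, sagittal_degs=offsets, axial_degs=offsets)
    tables = []
    for i in range(n_cases):
        spec = random_spec(rng)
        ph = make_phantom_volume(spec)
        pre, lm = _prepare(ph)
        seg = PhantomSegmenter(ph, preprocessed=pre)
        tables.append(
            run_perturbation_grid(
                pre, lm, seg, grid=grid, config=config, case_id=f"case{i:03d}"
            )
        )
    return pd.concat(tables, ignore_index=True)
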