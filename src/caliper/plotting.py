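"""Overlay and agreement plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement_stats import BlandAltman
from .ca_core import CAResult
from .plane_geometry import Slice2D
from .ventricle_masks import VentricleMask

__all__ = ["render_overlay", "plot_bland_altman", "plot_correlation"]


def _draw_line(ax, point, direction, length, **kw):
    p = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    seg = np.stack([p - length * d, p + length * d])
    ax.plot(seg[:, 0], seg[:, 1], **kw)


def render_overlay(
    slice2d: Slice2D | None, mask: VentricleMask, result: CAResult, path=None
):
    """Render contours, separating line, wall points, base points, wall lines."""
    fig, ax = plt.subplots(figsize=(6, 6))
    if slice2d is not None:
        ax.imshow(slice2d.data, cmap="gray", interpolation="nearest")
    else:
        ax.imshow(mask.labels, cmap="gray", interpolation="nearest")
    for wall, color in zip(result.medial_walls, ("tab:cyan", "tab:orange")):
        ax.plot(wall.points[:, 0], wall.points[:, 1], ".", ms=2, color=color)
    sep = result.separating_line
    _draw_line(ax, sep.point, sep.direction, 100, color="yellow", lw=0.8, ls="--")
    for wl, color in ((result.left_wall, "tab:cyan"), (result.right_wall, "tab:orange")):
        _draw_line(ax, wl.base_point, wl.direction, 60, color=color, lw=1.2)
    bp = np.stack(result.base_points)
    ax.plot(bp[:, 0], bp[:, 1], "r+", ms=10)
    ax.set_title(
        f"CA = {result.angle_deg:.1f} deg ({result.classification})", fontsize=10
    )
    ax.set_xlim(0, mask.labels.shape[1])
    ax.set_ylim(mask.labels.shape[0], 0)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_bland_altman(ba: BlandAltman, path=None, label: str = "CA (deg)"):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ba.means, ba.diffs, "o", ms=4, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=0.8)
    ax.set_xlabel(f"mean of methods, {label}")
    ax.set_ylabel(f"difference (pred - manual), {label}")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_correlation(pred, truth, path=None, label: str = "CA (deg)"):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(truth, pred, "o", ms=4, alpha=0.7)
    lo = min(truth.min(), pred.min())
    hi = max(truth.max(), pred.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.set_xlabel(f"manual {label}")
    ax.set_ylabel(f"predicted {label}")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
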