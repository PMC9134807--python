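"""Visualisation: ternary S/P/X trajectories, kymograph images, C-factor strips.

The S/P/X fractions of a conformation live on the 2-simplex; the standard
planar embedding puts the pure-S composition at the origin, pure P at (1, 0)
and pure X at the apex (1/2, sqrt(3)/2):

    x = f_P + f_X / 2,      y = f_X * sqrt(3) / 2

All plotting is headless-safe (Agg backend) and optional: every figure
function returns the matplotlib Figure and writes files only when asked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .circuit_topology import TopologyFractions
from .dynamic_ct import CFactorProfile, Kymograph

__all__ = [
    "TernaryPoint",
    "to_ternary",
    "from_ternary",
    "ternary_plot",
    "kymograph_figure",
    "c_factor_figure",
]

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class TernaryPoint:
    """A composition (f_S, f_P, f_X) and its planar 2-simplex coordinates."""

    f_S: float
    f_P: float
    f_X: float
    x: float
    y: float


def to_ternary(fractions: TopologyFractions | tuple[float, float, float]) -> TernaryPoint:
    """Map S/P/X fractions to planar simplex coordinates (S at the origin).

    Raises ``ValueError`` when the fractions are undefined (fewer than two
    contacts in the census).
    """
    if isinstance(fractions, TopologyFractions):
        if fractions.n_pairs == 0:
            raise ValueError("fractions undefined for fewer than two contacts")
        f_s, f_p, f_x = fractions.f_S, fractions.f_P, fractions.f_X
    else:
        f_s, f_p, f_x = fractions
    total = f_s + f_p + f_x
    if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {total}")
    return TernaryPoint(f_s, f_p, f_x, x=f_p + f_x / 2.0, y=f_x * _SQRT3_2)


def from_ternary(x: float, y: float) -> tuple[float, float, float]:
    """Invert the planar embedding back to (f_S, f_P, f_X)."""
    f_x = y / _SQRT3_2
    f_p = x - f_x / 2.0
    return (1.0 - f_p - f_x, f_p, f_x)


def _simplex_axes(ax):
    tri_x = [0.0, 1.0, 0.5, 0.0]
    tri_y = [0.0, 0.0, _SQRT3_2, 0.0]
    ax.plot(tri_x, tri_y, color="black", lw=1)
    ax.text(-0.03, -0.03, "S", ha="right", va="top")
    ax.text(1.03, -0.03, "P", ha="left", va="top")
    ax.text(0.5, _SQRT3_2 + 0.03, "X", ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def ternary_plot(
    fractions: Sequence[TopologyFractions],
    *,
    path=None,
    color_by_time: bool = True,
    title: str | None = None,
):
    """Scatter a topology trajectory on the S/P/X simplex.

    Frames with undefined fractions (m < 2) are skipped.  When ``path`` is
    given the figure is saved there (and as .png alongside an .svg path).
    """
    pts = []
    for f in fractions:
        if f.n_pairs > 0:
            p = to_ternary(f)
            pts.append((p.x, p.y))
    fig, ax = plt.subplots(figsize=(4.5, 4.2))
    _simplex_axes(ax)
    if pts:
        xs, ys = zip(*pts)
        c = np.arange(len(pts)) if color_by_time else None
        sc = ax.scatter(xs, ys, c=c, cmap="viridis", s=12, alpha=0.85)
        if color_by_time:
            fig.colorbar(sc, ax=ax, shrink=0.7, label="frame")
    if title:
        ax.set_title(title)
    if path is not None:
        _save_dual(fig, path)
    return fig


def kymograph_figure(kymo: Kymograph, *, path=None, max_rows: int | None = None):
    """Contact-presence kymograph as an image (rows = pairs, columns = frames)."""
    mat = kymo.presence if max_rows is None else kymo.presence[:max_rows]
    fig, ax = plt.subplots(figsize=(6, 4))
    if mat.size:
        ax.imshow(mat, aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xlabel(f"frame (Δt = {kymo.delta_t} ns)")
    ax.set_ylabel("contact pair")
    if path is not None:
        _save_dual(fig, path)
    return fig


def c_factor_figure(profile: CFactorProfile, *, path=None):
    """Per-residue C-factor heat strip (NaN = residue without contacts)."""
    fig, ax = plt.subplots(figsize=(7, 1.6))
    values = profile.values[None, :]
    im = ax.imshow(values, aspect="auto", cmap="magma", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="C-factor (ns)")
    ax.set_yticks([])
    ax.set_xlabel("residue")
    if path is not None:
        _save_dual(fig, path)
    return fig


def _save_dual(fig, path) -> None:
    """Save a figure as both the given path and its .svg/.png sibling."""
    from pathlib import Path

    p = Path(path)
    fig.savefig(p, dpi=150, bbox_inches="tight")
    sibling = p.with_suffix(".png" if p.suffix == ".svg" else ".svg")
    fig.savefig(sibling, dpi=150, bbox_inches="tight")
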