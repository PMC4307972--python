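"""Presentation-layer figures; all numbers come from the upstream modules."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .localization import LocalizationCurve
from .model import adsorption, mean_cluster_size

__all__ = ["plot_isotherms", "plot_localization", "plot_curves"]


def plot_isotherms(
    e_r_values: Sequence[float],
    C_s_grid: Sequence[float],
    path,
    with_cluster_inset: bool = True,
):
    """Adsorption vs concentration, one curve per repulsion strength.

    Lower e_r gives the upper curve (weaker repulsion, stronger
    cooperativity); the inset shows the number-weighted mean cluster size.
    """
    e_r_values = list(e_r_values)
    C_s_grid = np.asarray(list(C_s_grid), dtype=float)
    if not e_r_values or C_s_grid.size == 0:
        warnings.warn("empty isotherm request; no figure written", stacklevel=2)
        return None
    fig, ax = plt.subplots(figsize=(5.2, 4.0))
    inset = fig.add_axes([0.22, 0.55, 0.30, 0.28]) if with_cluster_inset else None
    for e_r in sorted(e_r_values):
        cv = [adsorption(c, e_r) for c in C_s_grid]
        ax.plot(C_s_grid, cv, label=f"$e_r={e_r:g}$")
        if inset is not None:
            ks = [mean_cluster_size(c, e_r) for c in C_s_grid]
            inset.plot(C_s_grid, ks)
    ax.set_xlabel("normalised solution concentration $C_s$")
    ax.set_ylabel("normalised adsorption $C_v$")
    ax.legend(loc="lower right", fontsize=8)
    if inset is not None:
        inset.set_ylabel("mean size", fontsize=7)
        inset.tick_params(labelsize=7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_localization(curve: LocalizationCurve | None, path):
    """Fraction in the high-curvature region vs total adsorption."""
    if curve is None or curve.C_s.size == 0:
        warnings.warn("empty localization curve; no figure written", stacklevel=2)
        return None
    fig, ax = plt.subplots(figsize=(5.2, 4.0))
    ax.semilogx(curve.total_adsorption, curve.fraction_1, "k-")
    ax.set_xlabel("total adsorption")
    ax.set_ylabel("fraction in high-curvature region")
    ax.set_ylim(0.45, 1.02)
    inset = fig.add_axes([0.60, 0.25, 0.28, 0.28])
    inset.loglog(curve.total_adsorption, curve.mean_size_1, "k-")
    inset.loglog(curve.total_adsorption, curve.mean_size_2, "k--")
    inset.set_ylabel("mean size", fontsize=7)
    inset.tick_params(labelsize=7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_curves(results, style: str, path):
    """Dispatch on figure style: 'isotherm' or 'localization'."""
    if style == "isotherm":
        return plot_isotherms(results.get("e_r_values", []), results.get("C_s_grid", []), path)
    if style == "localization":
        return plot_localization(results.get("curve"), path)
    raise ValueError(f"unknown figure style {style!r}")
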