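"""Triangle scatter and likelihood-surface plots."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .estimation import LikelihoodSurface

__all__ = ["triangle_plot", "surface_plot"]


def _triangle_boundary(ax):
    ax.plot([0, 0.5, 1, 0], [0, 1, 0, 0], color="black", linewidth=1)
    ax.set_xlabel("S (fraction of population-2 ancestry)")
    ax.set_ylabel("interclass heterozygosity $H_I$")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.05)


def triangle_plot(S, H_I, ax=None, **scatter_kwargs):
    """Scatter of per-individual (S, H_I) estimates inside the triangular
    sample space."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(np.asarray(S), np.asarray(H_I), **{"s": 18, "alpha": 0.7, **scatter_kwargs})
    _triangle_boundary(ax)
    return ax


def surface_plot(surface: LikelihoodSurface, ax=None, shade_step: float = 2.0,
                 n_levels: int = 8):
    """Shaded log-likelihood surface; each shading level spans
    ``shade_step`` log-likelihood units below the maximum, so the darkest
    band is the 2-unit support region."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    pts = surface.points
    top = surface.max_loglik
    levels = top - shade_step * np.arange(n_levels, -1, -1, dtype=float)
    vals = np.maximum(pts["loglik"], levels[0])
    ax.tricontourf(pts["S"], pts["H_I"], vals, levels=levels, cmap="Greys")
    _triangle_boundary(ax)
    return ax
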