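"""Minimal plotting helpers (requires matplotlib, an optional dependency)."""

from __future__ import annotations

import numpy as np

from .equilibria import find_equilibria, parabola
from .params import StoichParams

_STYLE = {"stable": dict(marker="o", color="k"),
          "unstable": dict(marker="o", mfc="w", color="k"),
          "saddle": dict(marker="s", mfc="w", color="k"),
          "marginal": dict(marker="x", color="k")}


def phase_portrait(params: StoichParams, ax=None, separatrix=None, cycle=None):
    """Nullclines, equilibria, and optionally separatrix/limit cycle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = np.linspace(1e-4, params.K, 400)
    ax.plot(xs, parabola(xs, params), "b-", lw=1, label="producer nullcline")
    x_star = params.x_star
    ax.plot([x_star, x_star], [0, params.p - x_star], "r-", lw=1,
            label="grazer nullcline")
    x2 = np.linspace(x_star, min(params.K, params.c * params.e * params.p / params.d - params.a), 100)
    ax.plot(x2, params.p - params.d * (params.a + x2) / (params.c * params.e), "r-", lw=1)
    ax.plot(xs, params.p - xs, "c--", lw=0.8, label="branch line x+y=p")
    for eq in find_equilibria(params):
        ax.plot([eq.x], [eq.y], ls="", **_STYLE.get(eq.stability, {}))
    if separatrix is not None:
        ax.plot(*separatrix.points.T, "m-.", lw=1, label="separatrix")
    if cycle is not None:
        ax.plot(*cycle.samples.T, "g-", lw=1.2, label="limit cycle")
    ax.set_xlabel("producer x (mg C/l)")
    ax.set_ylabel("grazer y (mg C/l)")
    ax.set_xlim(0, params.K * 1.05)
    ax.set_ylim(0, params.p * 1.05)
    ax.legend(fontsize=7)
    return ax


def plot_confidence(region, ax=None, **kwargs):
    """Draw a confidence ellipse boundary or band boundaries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if hasattr(region, "boundary"):
        pts = np.vstack([region.boundary, region.boundary[:1]])
        ax.plot(*pts.T, **{"lw": 1, **kwargs})
    else:
        for g in (region.gamma1, region.gamma2):
            ax.plot(*np.vstack([g, g[:1]]).T, **{"lw": 1, **kwargs})
    return ax
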