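"""Small matplotlib helpers: fit overlays and MAPE-vs-noise panels."""

from __future__ import annotations

import numpy as np

from .evaluate import MapeGrid
from .forward import RecoveryCurve


def plot_recovery_fit(curve: RecoveryCurve, fits: dict[str, RecoveryCurve],
                      path: str | None = None):
    """Overlay an observed recovery curve with one or more model fits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.times, curve.values, "k.", ms=4, label="data")
    for name, fit in fits.items():
        ax.plot(fit.times, fit.values, lw=1.5, label=name)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean ROI intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_mape_vs_noise(grid: MapeGrid, param: str = "d",
                       path: str | None = None):
    """One panel per (D, alpha) cell: MAPE as a function of the noise
    variance a, one line per estimator."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grids = {"d": grid.mape_d, "c0": grid.mape_c0,
             "alpha": grid.mape_alpha}[param]
    n_d = len(grid.spec.d_si)
    n_al = len(grid.spec.alpha)
    fig, axes = plt.subplots(n_d, n_al, figsize=(3 * n_al, 2.5 * n_d),
                             sharex=True, squeeze=False)
    for i, d_si in enumerate(grid.spec.d_si):
        for j, alpha in enumerate(grid.spec.alpha):
            ax = axes[i][j]
            for name, vals in grids.items():
                ax.loglog(grid.spec.a, vals[i, j, :], "o-", ms=3, label=name)
            ax.set_title(f"D={d_si:.2g} m$^2$/s, $\\alpha$={alpha:g}",
                         fontsize=8)
            if i == n_d - 1:
                ax.set_xlabel("noise variance a")
            if j == 0:
                ax.set_ylabel("MAPE (%)")
    axes[0][0].legend(frameon=False, fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
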