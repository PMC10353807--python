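"""Small plotting helpers: density/hazard curves and study heatmaps."""

from __future__ import annotations

import numpy as np

from .distribution import UELParams, hazard, pdf


def plot_density_hazard(params_list, labels=None, path=None, grid_size: int = 400):
    """Density and hazard curves for one or more parameter triples.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(params_list, UELParams):
        params_list = [params_list]
    y = np.linspace(1e-4, 1 - 1e-4, grid_size)
    fig, (ax_f, ax_h) = plt.subplots(1, 2, figsize=(9, 3.6))
    for i, p in enumerate(params_list):
        lab = labels[i] if labels else f"({p.delta:g}, {p.lam:g}, {p.theta:g})"
        ax_f.plot(y, pdf(y, p), label=lab)
        ax_h.plot(y, hazard(y, p), label=lab)
    ax_f.set_xlabel("y")
    ax_f.set_ylabel("density")
    ax_h.set_xlabel("y")
    ax_h.set_ylabel("hazard")
    ax_f.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
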