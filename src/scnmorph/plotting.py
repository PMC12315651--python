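"""Basic metric-curve plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .permutation import GroupCurves


def plot_metric_curves(curves: GroupCurves, path: str | Path) -> None:
    """One panel per metric: both groups' metric-vs-density curves."""
    metric_names = list(next(iter(curves.curves.values())).keys())
    n = len(metric_names)
    ncols = min(n, 4)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
    for ax, m in zip(axes.ravel(), metric_names):
        for group, style in (("A", "-o"), ("B", "-s")):
            c = curves.curves[group][m]
            ax.plot(c.densities, c.values, style, ms=2.5, label=f"{group} (AUC={c.auc:.3f})")
        ax.set_title(m)
        ax.set_xlabel("density")
        ax.legend(fontsize=6)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
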