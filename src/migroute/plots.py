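"""Minimal diagnostic plots (trace plots and posterior-predictive bars)."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def trace_plot(draws, names: Optional[Sequence[str]] = None, path=None):
    """Per-chain trace plots for a few parameters of a PosteriorDraws."""
    import matplotlib.pyplot as plt

    all_names = draws.layout.constrained_names
    names = list(names or all_names[:4])
    arr = draws.constrained_chains()
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)),
                             squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        k = all_names.index(name)
        for chain in range(arr.shape[0]):
            ax.plot(arr[chain, :, k], lw=0.5)
        ax.set_ylabel(name, fontsize=8)
    axes[-1, 0].set_xlabel("iteration")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def ppc_plot(table, path=None):
    """Observed counts against replicate intervals from a PPC table."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.4 * len(table) + 1.5))
    y = np.arange(len(table))
    ax.hlines(y, table["rep_lo"], table["rep_hi"], color="0.6", lw=4,
              label="central 95% of replicates")
    ax.plot(table["rep_mean"], y, "|", color="0.3", ms=10)
    ax.plot(table["observed"], y, "o", color="crimson", ms=5, label="observed")
    ax.set_yticks(y, table["statistic"], fontsize=7)
    ax.set_xlabel("count")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
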