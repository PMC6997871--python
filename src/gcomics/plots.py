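"""Plot helpers: volcano and VIP V-plots.

Minimal matplotlib figures for the two plots practitioners ask for first.
Both accept an optional Axes and return it, so they compose with larger
figures.
"""

from __future__ import annotations

import numpy as np


def volcano_plot(diff_table, fc_thr: float = 2.0, q_thr: float = 0.05, ax=None):
    """Volcano plot of a two-group differential table (log2FC vs -log10 q)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = diff_table["log2FC"]
    y = -np.log10(np.clip(diff_table["q"], 1e-300, None))
    sig = diff_table["significant"]
    ax.scatter(x[~sig], y[~sig], s=6, c="0.6", label="n.s.")
    ax.scatter(x[sig], y[sig], s=8, c="crimson", label="significant")
    ax.axvline(np.log2(fc_thr), ls="--", c="0.3", lw=0.8)
    ax.axvline(-np.log2(fc_thr), ls="--", c="0.3", lw=0.8)
    ax.axhline(-np.log10(q_thr), ls="--", c="0.3", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 q")
    ax.legend(frameon=False, fontsize=8)
    return ax


def vip_vplot(pls_results, trend_table, vip_thr: float = 2.0, ax=None):
    """V-plot: VIP score against the stage-trend Pearson r per feature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    shared = pls_results.vip.index.intersection(trend_table.index)
    r = trend_table.loc[shared, "r"]
    v = pls_results.vip.loc[shared]
    hot = v > vip_thr
    ax.scatter(r[~hot], v[~hot], s=6, c="0.6")
    ax.scatter(r[hot], v[hot], s=8, c="crimson")
    ax.axhline(vip_thr, ls="--", c="0.3", lw=0.8)
    ax.set_xlabel("Pearson r with stage")
    ax.set_ylabel("VIP")
    return ax
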