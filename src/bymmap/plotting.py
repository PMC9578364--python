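"""Minimal plotting helpers: a forest plot of rate ratios and trace plots."""

from __future__ import annotations

import numpy as np


def forest_plot(results, ax=None, title=None):
    """Forest plot of RRs with 95% CrIs from a long-format results table.

    ``results`` needs columns method, covariate, rr, lo, hi (one row per
    model cell); intervals excluding 1 are drawn filled.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(results) + 1))
    labels, y = [], 0
    for _, row in results.iterrows():
        filled = not (row["lo"] <= 1.0 <= row["hi"])
        ax.plot([row["lo"], row["hi"]], [y, y], color="k", lw=1)
        ax.plot(row["rr"], y, "o", color="k",
                markerfacecolor="k" if filled else "w")
        labels.append(f"{row['method']}: {row['covariate']}")
        y += 1
    ax.axvline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_yticks(np.arange(len(labels)))
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("rate ratio per 1 SD (95% CrI)")
    if title:
        ax.set_title(title)
    ax.invert_yaxis()
    return ax


def trace_plot(samples, names=None, axes=None):
    """Per-chain trace plots of monitored scalars (graphical history check)."""
    import matplotlib.pyplot as plt

    draws = samples.scalar_draws()
    names = names or list(draws)
    if axes is None:
        _, axes = plt.subplots(len(names), 1, figsize=(6, 1.6 * len(names)),
                               squeeze=False)
        axes = axes[:, 0]
    for ax, name in zip(axes, names):
        for c in range(draws[name].shape[0]):
            ax.plot(draws[name][c], lw=0.5)
        ax.set_ylabel(name, fontsize=8)
    return axes
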