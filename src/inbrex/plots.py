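"""Diagnostic figures for the two standard views of a panel.

Both functions take stage outputs (axes table, per-line intercepts) and
return the matplotlib Figure; pass a path to save instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_fitness_correlation(axes_table: pd.DataFrame, path=None):
    """Standardized male vs female fitness with the rotated axes overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    x, y = axes_table["male_std"], axes_table["female_std"]
    ax.scatter(x, y, s=25, color="0.2", zorder=3)
    lim = 1.1 * max(np.abs(np.concatenate([x, y])))
    for slope, label in ((-1, "antagonism"), (1, "concordance")):
        ax.plot([-lim, lim], [-slope * lim, slope * lim],
                lw=1, ls="--", color="0.6")
        ax.annotate(label, xy=(0.82 * lim, 0.82 * slope * lim), fontsize=9,
                    color="0.4", ha="center")
    r = np.corrcoef(x, y)[0, 1]
    ax.set_xlabel("male fitness (standardized log)")
    ax.set_ylabel("female fitness (standardized log)")
    ax.set_title(f"intersexual correlation r = {r:.2f}")
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, lw=0.5, color="0.8")
    ax.axvline(0, lw=0.5, color="0.8")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_extinction_risk(axes_table: pd.DataFrame, intercepts: pd.Series,
                         path=None):
    """Per-line random-intercept extinction risk against both derived axes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = axes_table.set_index("line_id")
    b = intercepts.reindex(df.index)
    fig, axs = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, col in zip(axs, ("antagonism", "concordance")):
        x = df[col]
        ax.scatter(x, b, s=25, color="0.2")
        slope, icpt = np.polyfit(x, b, 1)
        xs = np.linspace(x.min(), x.max(), 2)
        ax.plot(xs, slope * xs + icpt, lw=1, color="0.5")
        ax.set_xlabel(col)
    axs[0].set_ylabel("extinction risk (random intercept)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
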