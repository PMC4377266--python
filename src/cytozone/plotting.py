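"""Optional figure exports: PCA biplot with group ellipses, the
cross-scale null-distribution histogram, and stacked posterior bars.

matplotlib is imported lazily so the core pipeline has no plotting
dependency; every function writes to ``path`` and returns it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def pca_biplot(pca, groups: pd.Series, path, components=(0, 1)) -> Path:
    """Score scatter with per-group SD ellipses (centroid ± score SD) and
    loading arrows inside the unit circle."""
    plt = _plt()
    i, j = components
    ci, cj = pca.scores.columns[i], pca.scores.columns[j]
    fig, ax = plt.subplots(figsize=(6, 6))
    groups = groups.loc[pca.scores.index]
    for k, lvl in enumerate(sorted(groups.unique())):
        pts = pca.scores.loc[(groups == lvl).to_numpy(), [ci, cj]]
        color = f"C{k}"
        ax.scatter(pts[ci], pts[cj], s=10, alpha=0.5, color=color, label=str(lvl))
        cx, cy = pts[ci].mean(), pts[cj].mean()
        sx, sy = pts[ci].std(ddof=1), pts[cj].std(ddof=1)
        theta = np.linspace(0, 2 * np.pi, 200)
        ax.plot(cx + sx * np.cos(theta), cy + sy * np.sin(theta), color=color)
        ax.annotate(str(lvl), (cx, cy), fontsize=11, fontweight="bold")
    scale = np.abs(pca.scores[[ci, cj]].to_numpy()).max()
    for var in pca.loadings.index:
        lx, ly = pca.loadings.loc[var, ci], pca.loadings.loc[var, cj]
        ax.annotate(
            "", xy=(lx * scale, ly * scale), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="grey"),
        )
        ax.annotate(var, (lx * scale, ly * scale), color="grey")
    ax.set_xlabel(f"{ci} ({100 * pca.explained[i]:.0f}%)")
    ax.set_ylabel(f"{cj} ({100 * pca.explained[j]:.0f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def scale_test_histogram(result, path, bins=40) -> Path:
    """Null F distribution with the empirical contact-zone F as a dashed
    line, in the style of a Monte Carlo randomization summary."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.null_F, bins=bins, color="lightsteelblue", edgecolor="white")
    ax.axvline(result.empirical_F, color="black", linestyle="--",
               label=f"empirical F (p = {result.p:.4g})")
    ax.set_xlabel("MANOVA F of range-wide subsamples")
    ax.set_ylabel("frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def posterior_stacked_bars(posterior, path, cytotypes: pd.Series | None = None) -> Path:
    """One stacked bar of class posterior probabilities per individual,
    optionally ordered and delimited by cytotype."""
    plt = _plt()
    probs = posterior.probs
    if cytotypes is not None:
        order = cytotypes.loc[probs.index].sort_values(kind="stable").index
        probs = probs.loc[order]
    fig, ax = plt.subplots(figsize=(max(6, len(probs) * 0.06), 4))
    bottom = np.zeros(len(probs))
    x = np.arange(len(probs))
    for k, cls in enumerate(probs.columns):
        vals = probs[cls].to_numpy()
        ax.bar(x, vals, bottom=bottom, width=1.0, color=f"C{k}", label=cls)
        bottom += vals
    ax.set_xlim(-0.5, len(probs) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("posterior probability")
    ax.set_xlabel("individuals")
    ax.legend(frameon=False, ncol=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
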