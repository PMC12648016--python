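"""Figure helpers: turnover curves, offset maps and group violins."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .gforest import TurnoverModel  # noqa: E402

__all__ = ["plot_turnover", "plot_offset_map", "plot_group_violins"]


def plot_turnover(model: TurnoverModel, predictor: str, ax=None,
                  highlight_snps=None):
    """Cumulative-importance curve for one predictor; optionally overlay
    per-SNP curves for ``highlight_snps``."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    edges = model.bin_edges[predictor]
    ax.step(edges, model.cum_importance[predictor], where="post",
            color="k", lw=1.5, label="aggregate")
    for snp in highlight_snps or []:
        imp = model.per_snp_importance.get(snp)
        if imp is None:
            continue
        ax.step(edges, np.concatenate([[0.0], np.cumsum(imp[predictor])]),
                where="post", lw=0.6, alpha=0.6)
    ax.set_xlabel(predictor)
    ax.set_ylabel("cumulative importance")
    return ax


def plot_offset_map(grid, stack, ax=None, label="offset"):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, extent=(stack.lon[0], stack.lon[-1],
                                 stack.lat[-1], stack.lat[0]))
    plt.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax


def plot_group_violins(offset, regions, ax=None):
    """Violin plot of per-cell offsets by group region."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    groups = [g for g in np.unique(regions[regions != None])]  # noqa: E711
    data = []
    for g in groups:
        v = np.asarray(offset[regions == g], dtype=float)
        data.append(v[np.isfinite(v)])
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(np.arange(1, len(groups) + 1), groups)
    ax.set_ylabel("local offset")
    return ax
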