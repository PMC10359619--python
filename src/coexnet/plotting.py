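"""Static plot helpers for module summaries and comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_eigengene_by_category(summary: pd.DataFrame, module_label: int, ax=None):
    """Bar-plus-points plot of one module's eigengene by category level.

    ``summary`` is the long table from
    :func:`coexnet.module_stats.summarize_eigengene_by_category`.
    """
    sub = summary[summary["module_label"] == module_label]
    if sub.empty:
        raise ValueError(f"module {module_label} not present in summary")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    levels = sub.drop_duplicates("level")
    x = np.arange(len(levels))
    ax.bar(x, levels["level_mean"], yerr=levels["level_sd"], color="lightsteelblue",
           edgecolor="black", capsize=3, zorder=1)
    for xi, (_, row) in zip(x, levels.iterrows()):
        pts = sub[sub["level"] == row["level"]]["eigengene"]
        ax.scatter(np.full(len(pts), xi) + np.random.default_rng(0).uniform(-0.15, 0.15, len(pts)),
                   pts, s=12, color="black", zorder=2)
    ax.set_xticks(x, levels["level"])
    ax.set_ylabel("module eigengene")
    ax.set_title(f"module {module_label}")
    return ax


def plot_module_trait_heatmap(table: pd.DataFrame, ax=None):
    """Heatmap of module-trait correlations annotated with adjusted p.

    ``table`` is the long table from
    :func:`coexnet.module_stats.module_trait_correlation`.
    """
    r = table.pivot(index="module_label", columns="trait", values="r")
    p = table.pivot(index="module_label", columns="trait", values="p_adjusted")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + r.shape[1], 1 + 0.5 * r.shape[0]))
    im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(r.shape[0]), [f"module {m}" for m in r.index])
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            if np.isfinite(r.iat[i, j]):
                ax.text(j, i, f"{r.iat[i, j]:.2f}\n({p.iat[i, j]:.2g})",
                        ha="center", va="center", fontsize=7)
    plt.colorbar(im, ax=ax, label="correlation")
    return ax


def plot_comparison_bubbles(result: pd.DataFrame, ax=None):
    """Bubble plot of module overlaps: size = shared fraction of A,
    color = -log10 adjusted Fisher p (grey where not significant)."""
    mods_a = sorted(result["module_a"].unique())
    mods_b = sorted(result["module_b"].unique())
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.5 * len(mods_b), 1 + 0.5 * len(mods_a)))
    xi = {m: i for i, m in enumerate(mods_b)}
    yi = {m: i for i, m in enumerate(mods_a)}
    with np.errstate(divide="ignore"):
        logp = -np.log10(np.maximum(result["fisher_p_adjusted"].to_numpy(), 1e-300))
    sig = result["fisher_p_adjusted"].to_numpy() <= 0.05
    colors = np.where(sig, logp, np.nan)
    sc = ax.scatter(
        [xi[m] for m in result["module_b"]],
        [yi[m] for m in result["module_a"]],
        s=20 + 300 * result["fraction_of_a"].to_numpy(),
        c=np.nan_to_num(colors), cmap="viridis",
        edgecolors=np.where(sig, "black", "lightgrey"),
    )
    ax.set_xticks(range(len(mods_b)), mods_b, rotation=45, ha="right")
    ax.set_yticks(range(len(mods_a)), mods_a)
    plt.colorbar(sc, ax=ax, label="-log10 adjusted p (significant pairs)")
    return ax
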