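"""Diagnostic plots for the region-stratified benchmark.

Thin matplotlib helpers over :class:`idrbench.vep.VepBenchmarkResults`:
per-region AUROC dot plots, sensitivity-vs-specificity scatters at global or
region-specific thresholds, and group-agreement bar charts with SEM error
bars.  Intended for quick inspection, not publication styling.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .structure import REGION_LABELS

_REGION_COLORS = {"disordered": "#d95f02", "intermediate": "#7570b3", "ordered": "#1b9e77"}


def plot_auroc_by_region(results, ax=None):
    """Dot plot of per-VEP AUROC in each structural region."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * results.metrics["vep"].nunique() + 1.5))
    table = results.auroc_table()
    for region in REGION_LABELS:
        if region in table.columns:
            ax.scatter(table[region], range(len(table)), label=region,
                       color=_REGION_COLORS[region], zorder=3)
    ax.set_yticks(range(len(table)), table.index)
    ax.set_xlabel("AUROC")
    ax.set_xlim(0.5, 1.0)
    ax.grid(axis="x", alpha=0.3)
    ax.legend(title="region", fontsize=8)
    return ax


def plot_sens_spec(results, threshold_scope: str = "global", ax=None):
    """Sensitivity vs specificity per region, at the global threshold
    (``threshold_scope='global'``) or at each region's own threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    m = results.metrics
    for region in REGION_LABELS:
        sub = m.loc[m["scope"] == region]
        if sub.empty:
            continue
        if threshold_scope == "global":
            x, y = sub["sensitivity_at_global"], sub["specificity_at_global"]
        else:
            x, y = sub["sensitivity"], sub["specificity"]
        ax.scatter(x, y, label=region, color=_REGION_COLORS[region], alpha=0.8)
    ax.set_xlabel("sensitivity")
    ax.set_ylabel("specificity")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(title="region", fontsize=8)
    ax.set_title(f"{threshold_scope} threshold")
    return ax


def plot_group_agreement(results, ax=None):
    """Mean pairwise Cohen's kappa per group pair and region, with SEM bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    agg = results.agreement
    pairs = sorted(agg["group_pair"].unique())
    width = 0.8 / len(REGION_LABELS)
    for j, region in enumerate(REGION_LABELS):
        sub = agg.loc[agg["scope"] == region].set_index("group_pair")
        xs, ys, errs = [], [], []
        for i, pair in enumerate(pairs):
            if pair in sub.index:
                xs.append(i + j * width)
                ys.append(sub.loc[pair, "mean_kappa"])
                errs.append(sub.loc[pair, "sem"] or 0.0)
        ax.bar(xs, ys, width=width, yerr=errs, capsize=2,
               label=region, color=_REGION_COLORS[region])
    ax.set_xticks([i + width for i in range(len(pairs))], pairs,
                  rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("mean Cohen's kappa")
    ax.legend(title="region", fontsize=8)
    return ax
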