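"""Vector-graphics summaries: null-distribution histograms, reaction-norm
curves, and stacked repeatability partitions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .brn import FitResult, RepeatabilityEstimate, predict_reaction_norms
from .nullmodels import NullDistribution

__all__ = ["plot_null", "plot_reaction_norms", "plot_repeatability_partition"]


def plot_null(nd: NullDistribution, path=None, ax=None):
    """Histogram of permuted values with the observed value (solid line)
    and the 2.5/97.5% quantiles (dashed)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.hist(nd.permuted, bins=30, color="0.7", edgecolor="0.4")
    ax.axvline(nd.observed, color="k", lw=2, label="observed")
    ax.axvline(nd.ci_low, color="k", ls="--", lw=1)
    ax.axvline(nd.ci_high, color="k", ls="--", lw=1)
    ax.set_xlabel(nd.statistic_name)
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_reaction_norms(fit: FitResult, density_grid, path=None, ax=None):
    """Per-individual predicted curves (thin) over the population mean
    curve (thick black) across the density gradient."""
    preds = predict_reaction_norms(fit, density_grid)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for ind, grp in preds.groupby("individual"):
        if ind == "population":
            continue
        ax.plot(grp["density"], grp["predicted"], lw=0.8, alpha=0.7)
    pop = preds[preds["individual"] == "population"]
    ax.plot(pop["density"], pop["predicted"], color="k", lw=2.5)
    ax.set_xlabel("density (elk/ha)")
    ax.set_ylabel("predicted metric")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_repeatability_partition(estimates: dict[str, RepeatabilityEstimate],
                                 path=None, ax=None):
    """Stacked bars: each metric's r split into the design-averaged diagonal
    contributions of the random effects (scaled to total bar length r)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels, bottoms = [], []
    rows = []
    for name, est in estimates.items():
        if not est.defined:
            continue
        total_var = est.s2_among + est.s2_within
        parts = {t: v / total_var for t, v in est.partition.items()}
        rows.append((name, est, parts))
    shades = {"intercept": "0.85", "density": "0.45", "density2": "0.65"}
    for k, (name, est, parts) in enumerate(rows):
        bottom = 0.0
        for term, frac in parts.items():
            ax.barh(k, frac, left=bottom, color=shades.get(term, "0.5"),
                    edgecolor="k", label=term if k == 0 else None)
            bottom += frac
        ax.plot([est.ci_low, est.ci_high], [k, k], color="k", lw=1)
        labels.append(name)
    ax.set_yticks(range(len(rows)), labels)
    ax.set_xlabel("repeatability r")
    ax.legend(frameon=False, fontsize=8)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
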