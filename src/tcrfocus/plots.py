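"""Cohort report figures (SVG, deterministic output for fixed inputs)."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

matplotlib.rcParams["svg.hashsalt"] = "tcrfocus"

_SAVE_KW = {"format": "svg", "metadata": {"Date": None}}

_TIMEPOINT_COLORS = {"BL": "#4878a8", "postASCT": "#c44e52", "other": "#777777"}


def _save(fig, outdir, name: str) -> None:
    fig.savefig(os.path.join(outdir, name), **_SAVE_KW)
    plt.close(fig)


def plot_cohort(report, outdir) -> None:
    """Write the standard figure set for a cohort report."""
    os.makedirs(outdir, exist_ok=True)
    plot_paired_richness(report.richness, outdir)
    plot_renyi_profiles(report.renyi, outdir)
    plot_threshold_curves(report.threshold_curves, outdir)
    plot_expansion(report.expansion, outdir)
    plot_clusters(report.clusters, outdir)


def plot_paired_richness(richness, outdir) -> None:
    """Paired before/after dot plot of full-sample richness per chain."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for patient, group in richness.groupby("patient_id"):
        group = group.sort_values("timepoint")
        bl = group[group["timepoint"] == "BL"]["richness"]
        post = group[group["timepoint"] == "postASCT"]["richness"]
        if len(bl) and len(post):
            ax.plot([0, 1], [bl.iloc[0], post.iloc[0]], "o-", color="#555555", alpha=0.8)
    ax.set_xticks([0, 1], ["BL", "post-ASCT"])
    ax.set_ylabel("unique TCR sequences (richness)")
    ax.set_xlim(-0.3, 1.3)
    fig.tight_layout()
    _save(fig, outdir, "fig_richness.svg")


def plot_renyi_profiles(renyi, outdir) -> None:
    """Rényi spectra per sample; infinite order drawn at the right edge."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    orders = sorted(
        {float("inf") if o == "inf" else float(o) for o in renyi["order"]}
    )
    finite = [o for o in orders if np.isfinite(o)]
    xmax = (max(finite) * 2) if finite else 1.0
    xpos = {o: (xmax if np.isinf(o) else o) for o in orders}
    for (sample, timepoint), group in renyi.groupby(["sample_id", "timepoint"]):
        qs = [float("inf") if o == "inf" else float(o) for o in group["order"]]
        xs = [xpos[q] for q in qs]
        idx = np.argsort(xs)
        ax.plot(
            np.array(xs)[idx],
            group["entropy_median"].to_numpy()[idx],
            "-o",
            markersize=3,
            label=sample,
            color=_TIMEPOINT_COLORS.get(timepoint, "#777777"),
            alpha=0.8,
        )
    ax.set_xscale("symlog", linthresh=1)
    ax.set_xlabel("Rényi order q (rightmost point: q = ∞)")
    ax.set_ylabel("Rényi entropy (nats)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    _save(fig, outdir, "fig_renyi.svg")


def plot_threshold_curves(curves, outdir) -> None:
    """Clone counts above frequency thresholds, median with min–max band."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for (sample, timepoint), group in curves.groupby(["sample_id", "timepoint"]):
        group = group.sort_values("threshold")
        color = _TIMEPOINT_COLORS.get(timepoint, "#777777")
        ax.plot(group["threshold"], group["count_median"], "-o", markersize=3,
                label=sample, color=color, alpha=0.8)
        ax.fill_between(group["threshold"], group["count_min"], group["count_max"],
                        color=color, alpha=0.15, linewidth=0)
    ax.set_xscale("log")
    ax.set_yscale("symlog", linthresh=1)
    ax.set_xlabel("frequency threshold")
    ax.set_ylabel("clones above threshold")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    _save(fig, outdir, "fig_threshold_curves.svg")


def plot_expansion(expansion, outdir) -> None:
    """Expanded-clonotype proportion per sample, grouped by timepoint."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    table = expansion.sort_values(["timepoint", "sample_id"])
    colors = [_TIMEPOINT_COLORS.get(t, "#777777") for t in table["timepoint"]]
    ax.bar(range(len(table)), table["proportion_expanded"], color=colors)
    ax.set_xticks(range(len(table)), table["sample_id"], rotation=60, fontsize=6, ha="right")
    ax.set_ylabel("proportion expanded (> threshold)")
    fig.tight_layout()
    _save(fig, outdir, "fig_expansion.svg")


def plot_clusters(clusters, outdir) -> None:
    """Cluster counts from the top expanded CDR3s per sample."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    table = clusters.sort_values(["timepoint", "sample_id"])
    colors = [_TIMEPOINT_COLORS.get(t, "#777777") for t in table["timepoint"]]
    ax.bar(range(len(table)), table["n_clusters"], color=colors)
    ax.set_xticks(range(len(table)), table["sample_id"], rotation=60, fontsize=6, ha="right")
    ax.set_ylabel("CDR3 similarity clusters")
    fig.tight_layout()
    _save(fig, outdir, "fig_clusters.svg")
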