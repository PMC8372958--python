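"""Diagnostic plots (PDF) for each pipeline stage."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .cell_gating import GateResult, log_scatter
from .fcs import EventTable
from .gmm import MixtureModel
from .singlet_gating import SingletGateResult, _features


def _sigma_ellipses(ax, model: MixtureModel, colors=None) -> None:
    """1/2/3-sigma contours for every mixture component."""
    for j, comp in enumerate(model.components):
        vals, vecs = np.linalg.eigh(comp.covariance)
        angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
        color = None if colors is None else colors[j % len(colors)]
        for nsig in (1, 2, 3):
            w, h = 2 * nsig * np.sqrt(vals)
            ax.add_patch(
                Ellipse(
                    comp.mean, w, h, angle=angle,
                    fill=False, lw=0.8, color=color or f"C{j}",
                )
            )


def _hist2d(ax, X: np.ndarray, title: str) -> None:
    if X.shape[0]:
        ax.hist2d(X[:, 0], X[:, 1], bins=100, cmap="viridis", cmin=1)
    ax.set_title(title, fontsize=8)


def cell_gating_report(
    plot_dir: Path,
    tables: dict[str, EventTable],
    results: list[GateResult],
    model: MixtureModel,
) -> Path:
    plot_dir.mkdir(parents=True, exist_ok=True)
    out = plot_dir / "cell_gating.pdf"
    n = len(results)
    fig, axes = plt.subplots(n, 3, figsize=(10, 3 * n), squeeze=False)
    for row, res in enumerate(results):
        table = tables[res.sample_id]
        X, valid = log_scatter(table)
        _hist2d(axes[row][0], X, f"{res.sample_id}: all events")
        kept = X[res.keep_mask[valid]]
        _hist2d(axes[row][1], kept, f"{res.sample_id}: after gating")
        ax = axes[row][2]
        idx = res.component_index[valid]
        sub = slice(None, None, max(1, X.shape[0] // 5000))
        ax.scatter(X[sub, 0], X[sub, 1], c=idx[sub] % 10, s=2, cmap="tab10")
        _sigma_ellipses(ax, model)
        ax.set_title("cluster assignments", fontsize=8)
        for a in axes[row]:
            a.set_xlabel("log10 FSC-H", fontsize=7)
            a.set_ylabel("log10 SSC-H", fontsize=7)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return out


def singlet_gating_report(
    plot_dir: Path,
    tables: dict[str, EventTable],
    results: dict[str, SingletGateResult],
) -> Path:
    plot_dir.mkdir(parents=True, exist_ok=True)
    variant = next(iter(results.values())).variant
    out = plot_dir / f"singlet_gating_{variant}.pdf"
    n = len(results)
    fig, axes = plt.subplots(n, 2, figsize=(7, 3 * n), squeeze=False)
    ylabel = "log10(H/A)" if variant == "ratio" else "log10 SSC-W"
    for row, (sid, res) in enumerate(results.items()):
        X, valid = _features(tables[sid], variant)
        _hist2d(axes[row][0], X, f"{sid}: before")
        _hist2d(axes[row][1], X[res.keep_mask[valid]], f"{sid}: singlets")
        for a in axes[row]:
            a.set_xlabel("log10 SSC-H", fontsize=7)
            a.set_ylabel(ylabel, fontsize=7)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return out


def bead_report(
    plot_dir: Path,
    gated: EventTable,
    clusters,
    assignments: np.ndarray,
    calibrations: dict,
    channels,
) -> Path:
    plot_dir.mkdir(parents=True, exist_ok=True)
    out = plot_dir / "bead_calibration.pdf"
    fig, axes = plt.subplots(1, 1 + len(calibrations), figsize=(11, 3.5))
    ax = axes[0]
    logX = clusters.log_values
    outlier = assignments == -1
    ax.scatter(logX[~outlier, 0], logX[~outlier, 1],
               c=assignments[~outlier] % 10, s=2, cmap="tab10")
    ax.scatter(logX[outlier, 0], logX[outlier, 1],
               marker="x", s=8, color="red")
    _sigma_ellipses(ax, clusters.model)
    ax.set_xlabel(f"log10 {channels[0]}", fontsize=7)
    ax.set_ylabel(f"log10 {channels[1]}", fontsize=7)
    ax.set_title("bead clusters (outliers: red x)", fontsize=8)
    for i, (ch, cal) in enumerate(calibrations.items(), start=1):
        ax = axes[i]
        ax.plot(cal.mef_levels_used, cal.cluster_means, "o")
        grid = np.linspace(0, cal.mef_levels_used.max(), 50)
        ax.plot(grid, cal.intercept + cal.slope * grid, "-")
        ax.set_xlabel(f"MEF ({ch})", fontsize=7)
        ax.set_ylabel("measured intensity", fontsize=7)
        ax.set_title(f"{ch}: r^2 = {cal.r_squared:.5f}", fontsize=8)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return out
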