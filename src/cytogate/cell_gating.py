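"""Cell vs. background gating by blank-referenced constrained mixture fits.

The gate is built in two fits.  First a Gaussian mixture is fitted to the
log10 forward/side-scatter heights of a buffer blank, characterising the
background (debris/noise) distribution at the instrument threshold.  Then a
combined mixture — the background components held frozen, plus free "cell"
components — is fitted to the pooled scatter data of every cell sample in
the batch.  Events assigned to free components are kept as cells; the same
fitted gate is applied to every sample in the batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, SchemaError
from .fcs import BatchManifest, EventTable, read_fcs
from .gmm import (
    FitConfig,
    GaussianComponent,
    MixtureModel,
    assign,
    fit_constrained_gmm,
    fit_gmm,
    select_k_by_bic,
)
from .memory import AnalysisMemory

SCATTER = ("FSC-H", "SSC-H")

#: cap on pooled events entering EM; assignment always uses all events
POOL_SUBSAMPLE = 200_000


@dataclass
class GateResult:
    """Per-sample outcome of a gating stage."""

    sample_id: str
    keep_mask: np.ndarray  # boolean per event (False for dropped/non-positive)
    component_index: np.ndarray  # -1 for events excluded before the fit
    component_labels: list[str]
    model_ref: MixtureModel
    n_kept: int
    n_total: int

    def __post_init__(self) -> None:
        assert self.n_kept == int(np.sum(self.keep_mask)) <= self.n_total


def log_scatter(table: EventTable, channels=SCATTER) -> tuple[np.ndarray, np.ndarray]:
    """log10 of the scatter heights for events with both heights positive.

    Returns (n_valid x 2 matrix, boolean validity mask over all events).
    """
    for ch in channels:
        if ch not in table.channels:
            raise SchemaError(f"required channel {ch!r} missing from event table")
    raw = table.data[list(channels)].to_numpy(dtype=np.float64)
    valid = np.all(raw > 0, axis=1)
    return np.log10(raw[valid]), valid


def fit_background(
    blank_table: EventTable,
    num_back_clusters: int | None = None,
    config: FitConfig | None = None,
    k_range: tuple[int, int] = (1, 12),
) -> MixtureModel:
    """Fit the background mixture to a buffer blank.

    When the cluster count is not given it is selected by BIC over
    ``k_range``.  All returned components are marked frozen, ready to be
    carried into the constrained combined fit.
    """
    if config is None:
        config = FitConfig()
    X, valid = log_scatter(blank_table)
    if X.shape[0] < 100:
        raise DataError(
            f"blank has only {X.shape[0]} events with positive scatter; "
            "at least 100 are required"
        )
    if num_back_clusters is None:
        num_back_clusters = select_k_by_bic(X, k_range, config)
    model = fit_gmm(X, num_back_clusters, config)
    for c in model.components:
        c.frozen = True
    return model


def _pool(tables: dict[str, EventTable], config: FitConfig) -> np.ndarray:
    # canonical sample order: the fitted gate must not depend on the order
    # samples were listed in
    chunks = []
    for sample_id in sorted(tables):
        X, _ = log_scatter(tables[sample_id])
        chunks.append(X)
    pooled = np.concatenate(chunks, axis=0) if chunks else np.empty((0, 2))
    if pooled.shape[0] == 0:
        raise DataError("no positive-scatter events in any batch sample")
    if pooled.shape[0] > POOL_SUBSAMPLE:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x706F6F6C]))
        idx = rng.choice(pooled.shape[0], POOL_SUBSAMPLE, replace=False)
        pooled = pooled[np.sort(idx)]
    return pooled


def gate_with_model(
    table: EventTable, model: MixtureModel, sample_id: str
) -> GateResult:
    """Apply a fitted combined model to one sample (frozen => background,
    free => cell; non-positive-scatter events are dropped outright)."""
    X, valid = log_scatter(table)
    comp_idx = np.full(table.n_events, -1, dtype=int)
    comp_idx[valid] = assign(model, X)
    labels = ["background" if c.frozen else "cell" for c in model.components]
    cell_comps = np.array([lab == "cell" for lab in labels])
    keep = np.zeros(table.n_events, dtype=bool)
    keep[valid] = cell_comps[comp_idx[valid]]
    return GateResult(
        sample_id=sample_id,
        keep_mask=keep,
        component_index=comp_idx,
        component_labels=labels,
        model_ref=model,
        n_kept=int(keep.sum()),
        n_total=table.n_events,
    )


def gate_tables(
    blank_table: EventTable,
    sample_tables: dict[str, EventTable],
    num_back_clusters: int | None = None,
    num_cell_clusters: int = 3,
    config: FitConfig | None = None,
    cell_type: str = "default",
    memory: AnalysisMemory | None = None,
) -> tuple[list[GateResult], MixtureModel]:
    """Core batch gate on already-loaded event tables.

    Fits the blank, then the constrained combined model on the pooled batch
    scatter data (random initializations plus warm starts retrieved from
    the analysis memory), stores the winning model back into memory, and
    applies it identically to every sample.
    """
    if config is None:
        config = FitConfig()
    background = fit_background(blank_table, num_back_clusters, config)
    frozen = [
        GaussianComponent(c.mean, c.covariance, c.weight, frozen=True)
        for c in background.components
    ]
    # keep the blank-fit arrays bit-identical through the constrained fit
    for f, c in zip(frozen, background.components):
        f.mean = c.mean
        f.covariance = c.covariance

    pooled = _pool(sample_tables, config)
    inits = None
    if memory is not None and config.n_memory_inits > 0:
        inits = memory.retrieve(cell_type, "cell_gating", config.n_memory_inits)
    combined = fit_constrained_gmm(
        pooled, frozen, num_cell_clusters, config, inits=inits
    )
    if memory is not None and combined.converged:
        memory.append(combined, cell_type, "cell_gating")
    results = [
        gate_with_model(table, combined, sample_id)
        for sample_id, table in sample_tables.items()
    ]
    return results, combined


def background_subtract_gating(
    manifest: BatchManifest,
    num_back_clusters: int | None = None,
    num_cell_clusters: int = 3,
    config: FitConfig | None = None,
    cell_type: str = "default",
    samples: list[str] | None = None,
    memory: AnalysisMemory | None = None,
    plot_dir: str | Path | None = None,
) -> list[GateResult]:
    """Batch cell gating straight from a batch manifest of FCS files."""
    blank_table, _ = read_fcs(manifest.blank_file)
    sample_files = manifest.sample_files
    if samples is not None:
        sample_files = [p for p in sample_files if any(s in p.name for s in samples)]
    if not sample_files:
        raise DataError("no sample files selected for gating")
    tables = {p.stem: read_fcs(p)[0] for p in sample_files}
    results, combined = gate_tables(
        blank_table,
        tables,
        num_back_clusters=num_back_clusters,
        num_cell_clusters=num_cell_clusters,
        config=config,
        cell_type=cell_type,
        memory=memory,
    )
    if plot_dir is not None:
        from . import plots

        plots.cell_gating_report(Path(plot_dir), tables, results, combined)
    return results
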