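"""Batch orchestration: compose the gating and calibration stages over a
batch directory, write result CSVs, diagnostic plots and a run log."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .beads import BeadSetSpec, apply_calibration, fit_bead_data
from .cell_gating import GateResult, gate_tables
from .errors import ConfigurationError, DataError
from .fcs import EventTable, classify_batch, read_fcs
from .gmm import FitConfig
from .memory import AnalysisMemory, default_memory_root
from .singlet_gating import (
    SingletGateResult,
    apply_singlet_gate,
    singlet_gating,
    singlet_gating_width,
)

GATED_DIR = "gated"


def _write_run_log(out_dir: Path, payload: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    name = f"run_log_{payload['stage']}.json"
    (out_dir / name).write_text(json.dumps(payload, indent=1, default=str))


def run_gate_pipeline(
    data_directory: str | Path,
    blank_file: str | Path | None = None,
    samples: list[str] | None = None,
    num_back_clusters: int | None = None,
    num_cell_clusters: int = 3,
    singlet_variant: str = "ratio",
    singlet_n_clusters: int = 4,
    singlet_mean_center: float = 0.0,
    singlet_width_cutoff: float | None = None,
    cell_type: str = "default",
    config: FitConfig | None = None,
    memory_root: str | Path | None = None,
    output_dir: str | Path | None = None,
    make_plots: bool = True,
) -> dict[str, dict]:
    """Cell gating then singlet gating over one batch.

    The singlet gate, like the cell gate, is fitted once on the pooled
    cell events of the batch and applied identically to every sample.
    Returns per-sample ``{"cell": GateResult, "singlet": SingletGateResult}``
    and writes per-sample gating CSVs plus singlet-cell event exports.
    """
    if singlet_variant not in ("ratio", "width"):
        raise ConfigurationError(f"unknown singlet variant {singlet_variant!r}")
    if config is None:
        config = FitConfig()
    data_directory = Path(data_directory)
    out_dir = Path(output_dir) if output_dir else data_directory / GATED_DIR
    manifest = classify_batch(data_directory, blank_file, samples)
    memory = AnalysisMemory(
        Path(memory_root) if memory_root else default_memory_root(data_directory)
    )

    blank_table, _ = read_fcs(manifest.blank_file)
    tables = {p.stem: read_fcs(p)[0] for p in manifest.sample_files}
    cell_results, cell_model = gate_tables(
        blank_table,
        tables,
        num_back_clusters=num_back_clusters,
        num_cell_clusters=num_cell_clusters,
        config=config,
        cell_type=cell_type,
        memory=memory,
    )
    cell_by_id = {r.sample_id: r for r in cell_results}

    # pool the gated cell events of the batch for the singlet fit
    pooled_frames = [
        tables[sid].data.loc[cell_by_id[sid].keep_mask]
        for sid in sorted(cell_by_id)
        if cell_by_id[sid].n_kept
    ]
    if not pooled_frames:
        raise DataError("cell gating kept no events in any sample")
    pooled = EventTable(pd.concat(pooled_frames, ignore_index=True))

    stage = f"singlet_{singlet_variant}"
    inits = memory.retrieve(cell_type, stage, config.n_memory_inits)
    if singlet_variant == "ratio":
        pooled_res = singlet_gating(
            pooled,
            n_clusters=singlet_n_clusters,
            singlet_mean_center=singlet_mean_center,
            config=config,
            inits=inits or None,
        )
    else:
        pooled_res = singlet_gating_width(
            pooled,
            n_clusters=singlet_n_clusters,
            singlet_width_cutoff=singlet_width_cutoff,
            config=config,
            inits=inits or None,
        )
    if pooled_res.model_ref.converged:
        memory.append(pooled_res.model_ref, cell_type, stage)

    results: dict[str, dict] = {}
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for sid, table in tables.items():
        cell_res = cell_by_id[sid]
        cell_events = EventTable(
            table.data.loc[cell_res.keep_mask].reset_index(drop=True)
        )
        singlet_res = apply_singlet_gate(
            cell_events,
            pooled_res.model_ref,
            pooled_res.component_labels,
            singlet_variant,
        )
        results[sid] = {"cell": cell_res, "singlet": singlet_res}

        # per-event gate decisions for the whole sample
        singlet_keep = np.zeros(table.n_events, dtype=bool)
        singlet_comp = np.full(table.n_events, -1, dtype=int)
        rows = np.flatnonzero(cell_res.keep_mask)
        singlet_keep[rows] = singlet_res.keep_mask
        singlet_comp[rows] = singlet_res.component_index
        pd.DataFrame(
            {
                "cell_keep": cell_res.keep_mask.astype(int),
                "cell_component": cell_res.component_index,
                "singlet_keep": singlet_keep.astype(int),
                "singlet_component": singlet_comp,
            }
        ).to_csv(out_dir / f"{sid}.gating.csv", index=False)
        table.data.loc[singlet_keep].reset_index(drop=True).to_csv(
            out_dir / f"{sid}.singlet_cells.csv", index=False
        )
        counts[sid] = {
            "total": cell_res.n_total,
            "cells": cell_res.n_kept,
            "singlet_cells": int(singlet_keep.sum()),
        }

    if make_plots:
        from . import plots

        plots.cell_gating_report(out_dir / "plots", tables, cell_results, cell_model)
        plots.singlet_gating_report(
            out_dir / "plots",
            {sid: EventTable(tables[sid].data.loc[cell_by_id[sid].keep_mask]
                             .reset_index(drop=True))
             for sid in results},
            {sid: results[sid]["singlet"] for sid in results},
        )

    _write_run_log(
        out_dir,
        {
            "stage": "gate",
            "data_directory": str(data_directory),
            "blank_file": str(manifest.blank_file),
            "seed": config.seed,
            "config": asdict(config),
            "num_back_clusters": num_back_clusters,
            "num_cell_clusters": num_cell_clusters,
            "singlet_variant": singlet_variant,
            "cell_type": cell_type,
            "event_counts": counts,
        },
    )
    return results


def run_bead_pipeline(
    data_directory: str | Path,
    bead_spec: BeadSetSpec,
    channels=("BL1-A", "YL1-A"),
    config: FitConfig | None = None,
    output_dir: str | Path | None = None,
    make_plots: bool = True,
) -> dict:
    """Bead calibration over every bead file of a batch; calibrated MEF
    columns are appended to any singlet-cell CSVs already exported."""
    if config is None:
        config = FitConfig()
    data_directory = Path(data_directory)
    out_dir = Path(output_dir) if output_dir else data_directory / GATED_DIR
    manifest = classify_batch(data_directory)
    if not manifest.bead_files:
        raise ConfigurationError(f"no bead .fcs files found in {data_directory}")
    out_dir.mkdir(parents=True, exist_ok=True)
    all_cals = {}
    for bead_file in manifest.bead_files:
        bead_table, _ = read_fcs(bead_file)
        cals = fit_bead_data(
            bead_table,
            bead_spec,
            channels=channels,
            config=config,
            plot_dir=(out_dir / "plots") if make_plots else None,
        )
        all_cals[bead_file.stem] = cals
        (out_dir / f"{bead_file.stem}.calibration.json").write_text(
            json.dumps({ch: c.to_dict() for ch, c in cals.items()}, indent=1)
        )

    # append MEF columns to previously exported singlet-cell events
    first = next(iter(all_cals.values()))
    for csv in sorted(out_dir.glob("*.singlet_cells.csv")):
        df = pd.read_csv(csv)
        changed = False
        for ch, cal in first.items():
            if ch in df.columns:
                df[f"{ch}_MEF"] = apply_calibration(df[ch].to_numpy(), cal)
                changed = True
        if changed:
            df.to_csv(csv, index=False)

    _write_run_log(
        out_dir,
        {
            "stage": "beads",
            "data_directory": str(data_directory),
            "bead_set": bead_spec.name,
            "seed": config.seed,
            "config": asdict(config),
            "calibrations": {
                stem: {ch: c.to_dict() for ch, c in cals.items()}
                for stem, cals in all_cals.items()
            },
        },
    )
    return all_cals
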