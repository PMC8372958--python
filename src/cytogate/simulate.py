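"""Synthetic flow-cytometry data with known ground truth.

Generates buffer-blank, cell-sample and calibration-bead event tables that
mimic the structure of small-particle (bacterial) cytometry data from an
acoustic-focusing instrument:

* background (debris/noise) events form a multi-modal cloud truncated from
  below at the instrument trigger threshold;
* cell populations are roughly log-normal clusters in scatter space, well
  above the background;
* singlet events have pulse area ~ height (the instrument calibrates the
  two to agree) and a narrow pulse width; doublets carry ~2x the area,
  mildly inflated height, and a wider pulse;
* rainbow beads come in eight sub-populations whose measured fluorescence
  is linear in their vendor-assigned molecules-of-equivalent-fluorophore
  (MEF) values on each of two channels.

Every generator is driven by one global integer seed through named RNG
streams, so adding a sample to a batch never perturbs the draws of earlier
samples, and the same seed reproduces bit-identical tables.
"""

from __future__ import annotations

import datetime as _dt
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, InvalidInputError
from .fcs import EventTable, write_fcs

SCATTER_CHANNELS = ["FSC-H", "SSC-H", "FSC-A", "SSC-A", "SSC-W"]
FLUOR_CHANNELS = ["BL1-A", "YL1-A"]
ALL_CHANNELS = SCATTER_CHANNELS + FLUOR_CHANNELS + ["Time"]

#: pulse-geometry defaults (log10 units)
SINGLET_RATIO_SIGMA = 0.015  # spread of log10(area/height) for singlets
SINGLET_WIDTH_CENTER = 1.78  # log10 pulse width of singlets
SINGLET_WIDTH_SIGMA = 0.05
DOUBLET_WIDTH_SHIFT = np.log10(1.6)
DOUBLET_HEIGHT_RANGE = (1.0, 1.4)  # multiplicative height inflation

_REJECTION_ROUNDS = 200


@dataclass
class ComponentSpec:
    """Generative counterpart of one Gaussian mixture component
    (log10 scatter space)."""

    mean: np.ndarray  # 2-vector: (log10 FSC-H, log10 SSC-H)
    covariance: np.ndarray
    weight: float
    label: str = "background"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(2)
        self.covariance = np.asarray(self.covariance, dtype=np.float64).reshape(2, 2)
        if not np.allclose(self.covariance, self.covariance.T):
            raise InvalidInputError("component covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise InvalidInputError("component covariance must be positive-definite")
        if not (0 <= self.weight <= 1):
            raise InvalidInputError("component weight must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Per-event ground truth emitted next to every synthetic table."""

    component_index: np.ndarray  # index into the combined component list
    multiplet_order: np.ndarray  # 1 = singlet, 2 = doublet, ...
    component_labels: list[str]  # per-component label
    true_mef: pd.DataFrame | None  # per-event true MEF per fluor channel
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.multiplet_order < 1):
            raise InvalidInputError("multiplet order must be >= 1")
        if np.any(self.component_index < 0) or np.any(
            self.component_index >= len(self.component_labels)
        ):
            raise InvalidInputError("component index out of range")

    @property
    def is_cell(self) -> np.ndarray:
        labels = np.array(self.component_labels)
        return labels[self.component_index] != "background"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "component_index": self.component_index,
                "component_label": np.array(self.component_labels)[
                    self.component_index
                ],
                "multiplet_order": self.multiplet_order,
            }
        )
        if self.true_mef is not None:
            for col in self.true_mef.columns:
                df[f"mef_{col}"] = self.true_mef[col].to_numpy()
        return df


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG stream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _check_components(components: list[ComponentSpec]) -> np.ndarray:
    w = np.array([c.weight for c in components])
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise InvalidInputError(f"component weights must sum to 1 (got {w.sum():.6g})")
    return w


def _draw_truncated_scatter(
    rng: np.random.Generator,
    components: list[ComponentSpec],
    n: int,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (log10 FSC-H, log10 SSC-H) from the mixture, rejecting events
    whose linear height falls below the trigger threshold on either channel."""
    weights = _check_components(components)
    comp_idx = rng.choice(len(components), size=n, p=weights)
    out = np.empty((n, 2))
    pending = np.arange(n)
    log_thr = -np.inf if threshold <= 0 else np.log10(threshold)
    for _ in range(_REJECTION_ROUNDS):
        if pending.size == 0:
            break
        for j, comp in enumerate(components):
            rows = pending[comp_idx[pending] == j]
            if rows.size:
                out[rows] = rng.multivariate_normal(
                    comp.mean, comp.covariance, size=rows.size
                )
        ok = np.all(out[pending] >= log_thr, axis=1)
        pending = pending[~ok]
    else:
        if pending.size:
            raise DataError(
                f"threshold {threshold} rejects essentially all draws "
                f"({pending.size} events unresolved after {_REJECTION_ROUNDS} rounds)"
            )
    return out, comp_idx


def _pulse_geometry(
    rng: np.random.Generator,
    log_heights: np.ndarray,
    doublet: np.ndarray,
) -> dict[str, np.ndarray]:
    """Turn base log10 heights into H/A/W channels with singlet/doublet
    pulse geometry.  ``doublet`` is a boolean mask."""
    n = log_heights.shape[0]
    eps_f = rng.normal(0.0, SINGLET_RATIO_SIGMA, size=n)
    eps_s = rng.normal(0.0, SINGLET_RATIO_SIGMA, size=n)
    u = rng.uniform(*DOUBLET_HEIGHT_RANGE, size=n)
    log_u = np.where(doublet, np.log10(u), 0.0)
    log_area_boost = np.where(doublet, np.log10(2.0), 0.0)

    log_fsc_h = log_heights[:, 0] + log_u
    log_ssc_h = log_heights[:, 1] + log_u
    log_fsc_a = log_heights[:, 0] + log_area_boost + eps_f
    log_ssc_a = log_heights[:, 1] + log_area_boost + eps_s
    log_w = rng.normal(SINGLET_WIDTH_CENTER, SINGLET_WIDTH_SIGMA, size=n)
    log_w = log_w + np.where(
        doublet, DOUBLET_WIDTH_SHIFT + rng.normal(0.0, 0.05, size=n), 0.0
    )
    return {
        "FSC-H": 10.0**log_fsc_h,
        "SSC-H": 10.0**log_ssc_h,
        "FSC-A": 10.0**log_fsc_a,
        "SSC-A": 10.0**log_ssc_a,
        "SSC-W": 10.0**log_w,
    }


def _assemble(
    cols: dict[str, np.ndarray], rng: np.random.Generator, n: int
) -> EventTable:
    cols = dict(cols)
    for ch in FLUOR_CHANNELS:
        cols.setdefault(ch, 10.0 ** rng.normal(1.2, 0.25, size=n))
    cols["Time"] = np.cumsum(rng.exponential(1.0, size=n))
    data = pd.DataFrame({ch: cols[ch] for ch in ALL_CHANNELS})
    return EventTable(data.astype(np.float64))


def simulate_blank(
    n: int,
    components: list[ComponentSpec],
    threshold: float = 10.0,
    seed: int = 0,
    stream: str = "blank",
) -> tuple[EventTable, SimulationTruth]:
    """Buffer-blank sample: threshold-truncated background mixture only."""
    if n <= 0:
        raise InvalidInputError("n must be > 0")
    for c in components:
        if c.label != "background":
            raise InvalidInputError("blank components must be labelled background")
    rng = stream_rng(seed, stream)
    logh, comp_idx = _draw_truncated_scatter(rng, components, n, threshold)
    cols = _pulse_geometry(rng, logh, np.zeros(n, dtype=bool))
    table = _assemble(cols, rng, n)
    truth = SimulationTruth(
        component_index=comp_idx,
        multiplet_order=np.ones(n, dtype=int),
        component_labels=[c.label for c in components],
        true_mef=None,
        seed=seed,
    )
    return table, truth


def _lognormal(
    rng: np.random.Generator, mean: np.ndarray, cv: float | np.ndarray
) -> np.ndarray:
    """Draws with the requested arithmetic mean and coefficient of variation."""
    cv = np.asarray(cv, dtype=np.float64)
    sigma2 = np.log1p(cv**2)
    mu = np.log(np.maximum(mean, 1e-300)) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2)))


@dataclass
class FluorModel:
    """Per-cell-component fluorescence: arithmetic mean and CV per channel."""

    means: dict[str, list[float]]  # channel -> per-cell-component mean MEF
    cvs: dict[str, list[float]]


def simulate_cells(
    n: int,
    cell_components: list[ComponentSpec],
    background_components: list[ComponentSpec],
    background_fraction: float = 0.3,
    doublet_fraction: float = 0.2,
    fluor_model: FluorModel | None = None,
    threshold: float = 10.0,
    seed: int = 0,
    stream: str = "cells",
) -> tuple[EventTable, SimulationTruth]:
    """Cell sample: background + cell mixture with singlet/doublet geometry.

    ``doublet_fraction`` applies to cell events only (multiplets are
    coincidences of cells in the detection volume).  The combined component
    list in the truth record is background components first, then cell
    components.
    """
    if n <= 0:
        raise InvalidInputError("n must be > 0")
    if not (0 <= background_fraction <= 1 and 0 <= doublet_fraction <= 1):
        raise InvalidInputError("fractions must lie in [0, 1]")
    rng = stream_rng(seed, stream)
    n_bg_comp = len(background_components)

    is_bg = rng.random(n) < background_fraction
    n_bg = int(is_bg.sum())
    n_cell = n - n_bg

    comp_idx = np.zeros(n, dtype=int)
    logh = np.zeros((n, 2))
    if n_bg:
        bg_logh, bg_idx = _draw_truncated_scatter(
            rng, background_components, n_bg, threshold
        )
        logh[is_bg] = bg_logh
        comp_idx[is_bg] = bg_idx
    if n_cell:
        cell_logh, cell_idx = _draw_truncated_scatter(
            rng, cell_components, n_cell, threshold
        )
        logh[~is_bg] = cell_logh
        comp_idx[~is_bg] = n_bg_comp + cell_idx

    doublet = np.zeros(n, dtype=bool)
    if n_cell:
        doublet[~is_bg] = rng.random(n_cell) < doublet_fraction
    cols = _pulse_geometry(rng, logh, doublet)

    true_mef = None
    if fluor_model is not None:
        mef_cols = {}
        for ch in FLUOR_CHANNELS:
            vals = 10.0 ** rng.normal(1.2, 0.25, size=n)  # background noise
            mefs = np.zeros(n)
            if ch in fluor_model.means:
                means = np.asarray(fluor_model.means[ch], dtype=np.float64)
                cvs = np.asarray(fluor_model.cvs[ch], dtype=np.float64)
                cell_rows = np.flatnonzero(~is_bg)
                ci = comp_idx[cell_rows] - n_bg_comp
                draw = _lognormal(rng, means[ci], cvs[ci])
                # a doublet carries the summed signal of two cells
                second = _lognormal(rng, means[ci], cvs[ci])
                draw = np.where(doublet[cell_rows], draw + second, draw)
                mefs[cell_rows] = draw
                vals[cell_rows] = draw
            cols[ch] = vals
            mef_cols[ch] = mefs
        true_mef = pd.DataFrame(mef_cols)

    table = _assemble(cols, rng, n)
    truth = SimulationTruth(
        component_index=comp_idx,
        multiplet_order=np.where(doublet, 2, 1).astype(int),
        component_labels=[c.label for c in background_components]
        + [c.label for c in cell_components],
        true_mef=true_mef,
        seed=seed,
    )
    return table, truth


def simulate_beads(
    n: int,
    mef_values: dict[str, list[float]],
    slope: float | dict[str, float] = 1.0,
    intercept: float | dict[str, float] = 0.0,
    cv: float = 0.05,
    doublet_fraction: float = 0.0,
    seed: int = 0,
    stream: str = "beads",
) -> tuple[EventTable, SimulationTruth]:
    """Rainbow calibration-bead sample with eight (or fewer) sub-populations.

    Measured intensity on each fluorescence channel is drawn log-normally
    around ``intercept + slope * MEF_k``.  Scatter is one tight cluster;
    bead doublets (optional) sum the fluorescence of two independent beads
    and follow the doublet pulse geometry.
    """
    if n <= 0:
        raise InvalidInputError("n must be > 0")
    levels = {ch: np.asarray(v, dtype=np.float64) for ch, v in mef_values.items()}
    n_pop = None
    for ch, v in levels.items():
        if np.any(np.diff(v) <= 0):
            raise InvalidInputError(f"MEF levels for {ch} must be strictly increasing")
        if n_pop is None:
            n_pop = len(v)
        elif len(v) != n_pop:
            raise InvalidInputError("all channels must list the same number of levels")
    assert n_pop is not None

    def per_channel(x) -> dict[str, float]:
        if isinstance(x, dict):
            return {ch: float(x[ch]) for ch in levels}
        return {ch: float(x) for ch in levels}

    slopes = per_channel(slope)
    intercepts = per_channel(intercept)
    for ch, s in slopes.items():
        if s <= 0:
            raise InvalidInputError(f"slope for {ch} must be > 0")

    rng = stream_rng(seed, stream)
    pop = rng.integers(0, n_pop, size=n)
    doublet = rng.random(n) < doublet_fraction
    pop2 = rng.integers(0, n_pop, size=n)  # partner bead for doublets

    # one tight scatter cluster for all beads
    base = np.column_stack(
        [rng.normal(4.5, 0.03, size=n), rng.normal(4.3, 0.03, size=n)]
    )
    cols = _pulse_geometry(rng, base, doublet)

    mef_cols = {}
    for ch in levels:
        target = intercepts[ch] + slopes[ch] * levels[ch][pop]
        vals = _lognormal(rng, target, cv)
        target2 = intercepts[ch] + slopes[ch] * levels[ch][pop2]
        vals2 = _lognormal(rng, target2, cv)
        vals = np.where(doublet, vals + vals2, vals)
        cols[ch] = vals
        mef_cols[ch] = np.where(doublet, levels[ch][pop] + levels[ch][pop2],
                                levels[ch][pop])

    table = _assemble(cols, rng, n)
    truth = SimulationTruth(
        component_index=pop,
        multiplet_order=np.where(doublet, 2, 1).astype(int),
        component_labels=[f"bead_{k}" for k in range(n_pop)],
        true_mef=pd.DataFrame(mef_cols),
        seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Default study conditions shared by tests, CLI and the verification script
# ---------------------------------------------------------------------------


def default_background_components() -> list[ComponentSpec]:
    """Eight-component, threshold-hugging background cloud (asymmetric,
    multi-modal, as seen in buffer blanks on a small-particle cytometer)."""
    means = [
        (1.10, 1.20), (1.50, 1.10), (1.30, 1.80), (1.90, 1.50),
        (2.30, 1.30), (1.15, 2.20), (2.00, 2.10), (2.60, 1.80),
    ]
    sigmas = [0.12, 0.10, 0.15, 0.12, 0.10, 0.14, 0.16, 0.12]
    weights = np.array([0.22, 0.18, 0.14, 0.12, 0.10, 0.10, 0.08, 0.06])
    rhos = [0.3, -0.2, 0.1, 0.25, 0.0, -0.15, 0.2, 0.1]
    comps = []
    for m, s, w, r in zip(means, sigmas, weights, rhos):
        cov = np.array([[s**2, r * s * s], [r * s * s, s**2]])
        comps.append(ComponentSpec(np.array(m), cov, float(w), "background"))
    return comps


def default_cell_components() -> list[ComponentSpec]:
    """Three cell clusters well above the background cloud."""
    spec = [
        ((3.50, 3.30), 0.15, 0.5, 0.4),
        ((3.95, 3.65), 0.13, 0.3, 0.5),
        ((3.30, 3.95), 0.14, 0.2, 0.3),
    ]
    return [
        ComponentSpec(
            np.array(m),
            np.array([[s**2, r * s * s], [r * s * s, s**2]]),
            w,
            "cell",
        )
        for m, s, w, r in spec
    ]


def default_fluor_model() -> FluorModel:
    return FluorModel(
        means={"BL1-A": [3000.0, 12000.0, 1500.0],
               "YL1-A": [800.0, 2500.0, 500.0]},
        cvs={"BL1-A": [0.4, 0.4, 0.4], "YL1-A": [0.4, 0.4, 0.4]},
    )


def default_bead_levels() -> dict[str, list[float]]:
    """Eight-level rainbow bead set (MEF units per channel)."""
    return {
        "BL1-A": [90.0, 260.0, 700.0, 1900.0, 5200.0, 14000.0, 38000.0, 105000.0],
        "YL1-A": [70.0, 200.0, 560.0, 1500.0, 4200.0, 11500.0, 31000.0, 85000.0],
    }


def overlap_bead_levels() -> dict[str, list[float]]:
    """Bead set whose two dimmest levels nearly coincide on the first
    channel (unresolvable in 1D at cv~0.05) but separate on the second."""
    levels = default_bead_levels()
    levels["BL1-A"] = [100.0, 108.0, 700.0, 1900.0, 5200.0, 14000.0,
                       38000.0, 105000.0]
    return levels


def write_batch(
    out_dir: str | Path,
    seed: int = 0,
    n_samples: int = 3,
    events_per_sample: int = 20_000,
    blank_events: int = 30_000,
    bead_events: int = 10_000,
    background_fraction: float = 0.3,
    doublet_fraction: float = 0.2,
    bead_doublet_fraction: float = 0.05,
    bead_slope: float = 2.5,
    bead_intercept: float = 40.0,
    bead_cv: float = 0.05,
    bead_levels: dict[str, list[float]] | None = None,
    threshold: float = 10.0,
    write_truth: bool = True,
) -> Path:
    """Emit a complete synthetic batch directory (blank + samples + beads)
    as valid FCS 3.1 files with filename role tags and ordered timestamps.

    Ground-truth CSVs go to a ``truth`` sub-directory when requested.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "truth"
    if write_truth:
        truth_dir.mkdir(exist_ok=True)
    bg = default_background_components()
    cells = default_cell_components()
    fluor = default_fluor_model()
    t0 = _dt.datetime(2021, 3, 1, 9, 0, 0)

    def _write(table: EventTable, truth: SimulationTruth, name: str, minutes: int):
        start = t0 + _dt.timedelta(minutes=minutes)
        write_fcs(
            table,
            out_dir / name,
            acquisition_start=start,
            acquisition_end=start + _dt.timedelta(minutes=2),
        )
        if write_truth:
            truth.to_frame().to_csv(
                truth_dir / (Path(name).stem + ".truth.csv"), index=False
            )

    blank_table, blank_truth = simulate_blank(
        blank_events, bg, threshold=threshold, seed=seed, stream="blank-0"
    )
    _write(blank_table, blank_truth, "buffer_blank.fcs", 0)
    for i in range(n_samples):
        table, truth = simulate_cells(
            events_per_sample,
            cells,
            bg,
            background_fraction=background_fraction,
            doublet_fraction=doublet_fraction,
            fluor_model=fluor,
            threshold=threshold,
            seed=seed,
            stream=f"sample-{i}",
        )
        _write(table, truth, f"sample_{i + 1:02d}.fcs", 10 + 5 * i)
    bead_table, bead_truth = simulate_beads(
        bead_events,
        bead_levels or default_bead_levels(),
        slope=bead_slope,
        intercept=bead_intercept,
        cv=bead_cv,
        doublet_fraction=bead_doublet_fraction,
        seed=seed,
        stream="beads-0",
    )
    _write(bead_table, bead_truth, "calibration_beads.fcs", 10 + 5 * n_samples)
    return out_dir
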