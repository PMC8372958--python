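"""Singlet vs. multiplet discrimination from pulse geometry.

Two variants, both 2D mixture fits on cell-gated events:

* **ratio** — log10 side-scatter height vs. log10(height/area).  On an
  instrument calibrated so height and area agree for single particles, the
  log-ratio of a singlet sits near zero while a doublet's area doubles,
  pulling the ratio down by about log10(2).  Components whose fitted mean
  log-ratio falls within a tolerance of the singlet center are labelled
  singlet.
* **width** — log10 side-scatter height vs. log10 pulse width.  Multiplets
  ride through the laser longer, so their pulses are wider.  Components
  centered below a width cutoff are singlets; by default the cutoff is 1.4
  times the (linear) width center of the modal cluster, i.e. the modal
  log-center plus log10(1.4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SchemaError
from .fcs import EventTable
from .gmm import FitConfig, MixtureModel, assign, fit_gmm

RATIO_CHANNELS = ("SSC-H", "SSC-A")
WIDTH_CHANNELS = ("SSC-H", "SSC-W")


@dataclass
class SingletGateResult:
    keep_mask: np.ndarray
    component_index: np.ndarray  # -1 for events excluded before the fit
    component_labels: list[str]  # "singlet" | "multiplet" per component
    model_ref: MixtureModel
    variant: str  # "ratio" | "width"
    n_kept: int = 0
    n_total: int = 0

    def __post_init__(self) -> None:
        self.n_kept = int(np.sum(self.keep_mask))
        self.n_total = len(self.keep_mask)


def _features(table: EventTable, variant: str) -> tuple[np.ndarray, np.ndarray]:
    channels = RATIO_CHANNELS if variant == "ratio" else WIDTH_CHANNELS
    for ch in channels:
        if ch not in table.channels:
            raise SchemaError(f"required channel {ch!r} missing from event table")
    raw = table.data[list(channels)].to_numpy(dtype=np.float64)
    valid = np.all(raw > 0, axis=1)
    h = np.log10(raw[valid, 0])
    if variant == "ratio":
        y = h - np.log10(raw[valid, 1])  # log10(height / area)
    else:
        y = np.log10(raw[valid, 1])  # log10(width)
    return np.column_stack([h, y]), valid


def _label_components(
    model: MixtureModel, singlet_mask: np.ndarray, variant: str
) -> list[str]:
    if not singlet_mask.any():
        warnings.warn(
            f"singlet gate ({variant}): no component qualifies as singlet; "
            "zero events kept",
            stacklevel=3,
        )
    return ["singlet" if s else "multiplet" for s in singlet_mask]


def _gate(
    table: EventTable,
    model: MixtureModel,
    labels: list[str],
    variant: str,
) -> SingletGateResult:
    X, valid = _features(table, variant)
    comp_idx = np.full(table.n_events, -1, dtype=int)
    comp_idx[valid] = assign(model, X)
    singlet = np.array([lab == "singlet" for lab in labels])
    keep = np.zeros(table.n_events, dtype=bool)
    keep[valid] = singlet[comp_idx[valid]]
    return SingletGateResult(
        keep_mask=keep,
        component_index=comp_idx,
        component_labels=labels,
        model_ref=model,
        variant=variant,
    )


def singlet_gating(
    events: EventTable,
    n_clusters: int = 4,
    singlet_mean_center: float = 0.0,
    center_tolerance: float = 0.1,
    config: FitConfig | None = None,
    inits: list[MixtureModel] | None = None,
) -> SingletGateResult:
    """Height/area-ratio singlet gate.

    Components with fitted mean log10(height/area) within
    ``center_tolerance`` of ``singlet_mean_center`` are singlets.  The
    center can be moved (e.g. to the doublet position) for instruments with
    a different height/area calibration.
    """
    if config is None:
        config = FitConfig()
    X, _ = _features(events, "ratio")
    model = fit_gmm(X, n_clusters, config, inits=inits)
    centers = model.means[:, 1]
    singlet_mask = np.abs(centers - singlet_mean_center) <= center_tolerance
    labels = _label_components(model, singlet_mask, "ratio")
    return _gate(events, model, labels, "ratio")


def singlet_gating_width(
    events: EventTable,
    n_clusters: int = 4,
    singlet_width_cutoff: float | None = None,
    config: FitConfig | None = None,
    inits: list[MixtureModel] | None = None,
) -> SingletGateResult:
    """Height/width singlet gate.

    ``singlet_width_cutoff`` is in log10 width units; when absent it is set
    automatically to the modal cluster's log10 width center plus
    log10(1.4) (the modal cluster is the component holding the most
    events).  Components centered below the cutoff are singlets.
    """
    if config is None:
        config = FitConfig()
    X, _ = _features(events, "width")
    model = fit_gmm(X, n_clusters, config, inits=inits)
    hard = assign(model, X)
    if singlet_width_cutoff is None:
        counts = np.bincount(hard, minlength=model.k)
        modal = int(np.argmax(counts))
        singlet_width_cutoff = model.means[modal, 1] + np.log10(1.4)
    centers = model.means[:, 1]
    singlet_mask = centers < singlet_width_cutoff
    labels = _label_components(model, singlet_mask, "width")
    return _gate(events, model, labels, "width")


def apply_singlet_gate(
    events: EventTable, model: MixtureModel, labels: list[str], variant: str
) -> SingletGateResult:
    """Apply an already-fitted singlet gate to another sample of the same
    batch (same-gate-for-batch semantics)."""
    return _gate(events, model, labels, variant)
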