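"""Rainbow-bead fluorescence calibration to MEF units.

The calibration chain: gate the bead file down to singlet beads, identify
the bead sub-populations with a 2D Gaussian mixture on two log10
fluorescence channels, drop Mahalanobis outliers, compute each cluster's
arithmetic mean intensity on the linear scale, rank-match clusters to the
vendor-assigned MEF levels, and fit an ordinary least-squares line
``intensity = intercept + slope * MEF`` per channel.  Measured cell
fluorescence is then converted with the inverse map.

Fitting the bead clusters in two fluorescence dimensions resolves dim
sub-populations that coincide on a single channel, which is why the 2D
mixture beats any one-channel histogram split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import linregress

from .errors import CalibrationError, DataError, InvalidInputError
from .fcs import EventTable
from .gmm import FitConfig, MixtureModel, assign, fit_gmm, select_k_by_bic
from .singlet_gating import singlet_gating
from .cell_gating import log_scatter

DEFAULT_BEAD_CHANNELS = ("BL1-A", "YL1-A")

#: components closer than this Mahalanobis distance are duplicates of one
#: bead population and get merged
MERGE_DISTANCE = 1.5


@dataclass
class BeadSetSpec:
    """Vendor description of a calibration bead set: per-channel MEF levels."""

    name: str
    levels: dict[str, list[float]]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise InvalidInputError("a bead set needs MEF levels for >= 2 channels")
        for ch, v in self.levels.items():
            arr = np.asarray(v, dtype=np.float64)
            if arr.ndim != 1 or np.any(np.diff(arr) <= 0):
                raise InvalidInputError(
                    f"MEF levels for {ch} must be strictly increasing"
                )

    @property
    def n_levels(self) -> int:
        return len(next(iter(self.levels.values())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BeadSetSpec":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(name=doc["name"], levels=doc["levels"])

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            yaml.safe_dump({"name": self.name, "levels": self.levels})
        )
        return path


@dataclass
class BeadCalibration:
    """Linear map between measured intensity and MEF on one channel."""

    channel: str
    slope: float
    intercept: float
    cluster_means: np.ndarray  # ascending measured means (linear scale)
    mef_levels_used: np.ndarray  # matched vendor levels, ascending
    n_outliers_excluded: int
    r_squared: float

    def __post_init__(self) -> None:
        self.cluster_means = np.asarray(self.cluster_means, dtype=np.float64)
        self.mef_levels_used = np.asarray(self.mef_levels_used, dtype=np.float64)
        if self.slope <= 0:
            raise CalibrationError(
                f"{self.channel}: fitted slope {self.slope:.4g} is not positive"
            )
        if np.any(np.diff(self.cluster_means) <= 0) or np.any(
            np.diff(self.mef_levels_used) <= 0
        ):
            raise CalibrationError(
                f"{self.channel}: cluster means / matched MEF levels must be "
                "strictly increasing"
            )

    def to_dict(self) -> dict:
        return {
            "format": "cytogate-beadcal-1",
            "channel": self.channel,
            "slope": self.slope,
            "intercept": self.intercept,
            "cluster_means": self.cluster_means.tolist(),
            "mef_levels_used": self.mef_levels_used.tolist(),
            "n_outliers_excluded": self.n_outliers_excluded,
            "r_squared": self.r_squared,
        }


def gate_bead_singlets(
    bead_table: EventTable,
    config: FitConfig | None = None,
    min_events: int = 500,
) -> np.ndarray:
    """Boolean mask over bead events keeping singlet beads.

    First restricts to the dominant scatter cluster (cluster count chosen
    by BIC over 1-3, so clean single-cluster data is untouched), then
    applies the height/area-ratio singlet rule.
    """
    if config is None:
        config = FitConfig()
    if bead_table.n_events == 0:
        raise DataError("bead file contains no events")
    X, valid = log_scatter(bead_table)
    if X.shape[0] < min_events:
        raise DataError(
            f"only {X.shape[0]} positive-scatter bead events; re-acquire the "
            "bead sample"
        )
    k = select_k_by_bic(X, (1, 3), config)
    scatter_model = fit_gmm(X, k, config)
    hard = assign(scatter_model, X)
    dominant = int(np.argmax(np.bincount(hard, minlength=k)))
    keep = np.zeros(bead_table.n_events, dtype=bool)
    keep[valid] = hard == dominant

    ratio_result = singlet_gating(
        EventTable(bead_table.data.loc[keep].reset_index(drop=True)),
        n_clusters=2,
        config=config,
    )
    out = np.zeros(bead_table.n_events, dtype=bool)
    out[np.flatnonzero(keep)] = ratio_result.keep_mask
    if out.sum() < min_events:
        raise DataError(
            f"only {int(out.sum())} singlet bead events survive gating; "
            "re-acquire the bead sample"
        )
    return out


@dataclass
class BeadClusters:
    """Bead sub-populations resolved in 2D log-fluorescence space."""

    assignments: np.ndarray  # per (gated) event, index into ordered clusters
    linear_means: np.ndarray  # n_clusters x 2, linear scale, ordered by ch0
    model: MixtureModel  # components in the same order
    log_values: np.ndarray  # the fitted log10 matrix (for outlier checks)
    n_resolved: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_resolved = self.linear_means.shape[0]


def _log_fluor(bead_table: EventTable, channels) -> np.ndarray:
    for ch in channels:
        if ch not in bead_table.channels:
            raise InvalidInputError(f"channel {ch!r} missing from bead table")
    raw = bead_table.data[list(channels)].to_numpy(dtype=np.float64)
    pos = raw[raw > 0]
    if pos.size == 0:
        raise DataError("no positive fluorescence values in bead data")
    floor = 0.5 * pos.min()
    return np.log10(np.maximum(raw, floor))


def _merge_duplicates(model: MixtureModel) -> list[int]:
    """Indices of components to keep after merging near-coincident ones.

    Two components closer than MERGE_DISTANCE (Mahalanobis, under either
    covariance) describe the same bead population — the smaller-weight one
    is absorbed.
    """
    order = np.argsort(-model.weights)  # heavier components win
    kept: list[int] = []
    for j in order:
        duplicate = False
        for i in kept:
            for a, b in ((i, j), (j, i)):
                L = cholesky(model.components[a].covariance, lower=True)
                diff = model.components[b].mean - model.components[a].mean
                d = np.linalg.norm(solve_triangular(L, diff, lower=True))
                if d < MERGE_DISTANCE:
                    duplicate = True
                    break
            if duplicate:
                break
        if not duplicate:
            kept.append(int(j))
    return kept


def identify_bead_clusters(
    bead_table: EventTable,
    channels=DEFAULT_BEAD_CHANNELS,
    n_beads: int = 8,
    config: FitConfig | None = None,
) -> BeadClusters:
    """Resolve bead sub-populations with an ``n_beads``-component 2D GMM on
    log10 fluorescence.

    Non-positive intensities are floored at half the smallest positive
    observed value (the dimmest bead population can straddle zero).  When
    two fitted components land on one true population (fewer populations
    than requested), they are merged and a warning reports the resolved
    count.  Clusters are ordered by their mean on the first channel.
    """
    if n_beads < 2:
        raise InvalidInputError("n_beads must be >= 2")
    if config is None:
        config = FitConfig()
    # tight, numerous clusters need enough starts for k-means++ to cover
    # every population at least once
    from dataclasses import replace

    config = replace(config, n_random_inits=max(config.n_random_inits, n_beads))
    logX = _log_fluor(bead_table, channels)
    model = fit_gmm(logX, n_beads, config)
    # a component holding far less than a bead population's share of the
    # events is a noise/debris catch-all, not a bead cluster
    weight_floor = 0.25 / n_beads
    heavy = [i for i, c in enumerate(model.components) if c.weight >= weight_floor]
    if len(heavy) >= 2 and len(heavy) < model.k:
        model = MixtureModel(
            components=[model.components[i] for i in heavy],
            n_events_fit=model.n_events_fit,
            converged=model.converged,
        )
    kept = _merge_duplicates(model)
    if len(kept) < n_beads:
        warnings.warn(
            f"only {len(kept)} of {n_beads} bead populations resolved",
            stacklevel=2,
        )
        sub = MixtureModel(
            components=[model.components[i] for i in kept],
            n_events_fit=model.n_events_fit,
            converged=model.converged,
        )
        w = sub.weights
        for c, wi in zip(sub.components, w / w.sum()):
            c.weight = float(wi)
        model = sub
    hard = assign(model, logX)
    raw = bead_table.data[list(channels)].to_numpy(dtype=np.float64)
    lin_means = np.stack(
        [raw[hard == j].mean(axis=0) for j in range(model.k)]
    )
    order = np.argsort(lin_means[:, 0])
    remap = np.empty(model.k, dtype=int)
    remap[order] = np.arange(model.k)
    ordered_model = MixtureModel(
        components=[model.components[j] for j in order],
        log_likelihood=model.log_likelihood,
        n_events_fit=model.n_events_fit,
        converged=model.converged,
        n_iterations=model.n_iterations,
    )
    return BeadClusters(
        assignments=remap[hard],
        linear_means=lin_means[order],
        model=ordered_model,
        log_values=logX,
    )


def exclude_outliers(
    clusters: BeadClusters,
    mahalanobis_cutoff: float = 3.0,
) -> np.ndarray:
    """Assignments with outliers set to -1.

    An event is an outlier when its Mahalanobis distance to its assigned
    cluster, in the fitted log space, exceeds the cutoff.
    """
    out = clusters.assignments.copy()
    for j, comp in enumerate(clusters.model.components):
        rows = np.flatnonzero(clusters.assignments == j)
        if rows.size == 0:
            continue
        L = cholesky(comp.covariance, lower=True)
        diff = (clusters.log_values[rows] - comp.mean).T
        d = np.linalg.norm(solve_triangular(L, diff, lower=True), axis=0)
        out[rows[d > mahalanobis_cutoff]] = -1
    return out


def fit_bead_data(
    bead_table: EventTable,
    spec: BeadSetSpec,
    channels=DEFAULT_BEAD_CHANNELS,
    config: FitConfig | None = None,
    mahalanobis_cutoff: float = 3.0,
    plot_dir: str | Path | None = None,
) -> dict[str, BeadCalibration]:
    """Full bead-calibration chain; one linear calibration per channel.

    Clusters are matched to vendor MEF levels by rank on each channel;
    when fewer clusters than levels are resolved, the *lowest* levels are
    dropped (the trigger threshold censors dim beads, never bright ones).
    """
    if config is None:
        config = FitConfig()
    for ch in channels:
        if ch not in spec.levels:
            raise InvalidInputError(f"bead set {spec.name!r} lists no levels for {ch}")
    singlet_mask = gate_bead_singlets(bead_table, config)
    gated = EventTable(bead_table.data.loc[singlet_mask].reset_index(drop=True))
    clusters = identify_bead_clusters(gated, channels, spec.n_levels, config)
    assignments = exclude_outliers(clusters, mahalanobis_cutoff)
    n_outliers = int(np.sum((assignments == -1) & (clusters.assignments != -1)))

    raw = gated.data[list(channels)].to_numpy(dtype=np.float64)
    calibrations: dict[str, BeadCalibration] = {}
    for ci, ch in enumerate(channels):
        means = np.array(
            [
                raw[assignments == j, ci].mean()
                for j in range(clusters.n_resolved)
                if np.any(assignments == j)
            ]
        )
        means = np.sort(means)
        levels = np.asarray(spec.levels[ch], dtype=np.float64)
        if means.size < 2:
            raise CalibrationError(
                f"{ch}: only {means.size} bead cluster(s) usable; need >= 2"
            )
        matched = levels[-means.size:]  # drop the dimmest vendor levels
        # constant-CV noise: weight residuals by 1/intensity so the dim,
        # precisely-measured clusters anchor the intercept
        slope_w, intercept_w = np.polyfit(matched, means, 1, w=1.0 / means)
        r2 = float(linregress(matched, means).rvalue ** 2)
        calibrations[ch] = BeadCalibration(
            channel=ch,
            slope=float(slope_w),
            intercept=float(intercept_w),
            cluster_means=means,
            mef_levels_used=matched,
            n_outliers_excluded=n_outliers,
            r_squared=r2,
        )
    if plot_dir is not None:
        from . import plots

        plots.bead_report(Path(plot_dir), gated, clusters, assignments,
                          calibrations, channels)
    return calibrations


def apply_calibration(values: np.ndarray, cal: BeadCalibration) -> np.ndarray:
    """Convert measured intensities to MEF: ``(value - intercept) / slope``."""
    if cal.slope <= 0:
        raise CalibrationError("calibration has non-positive slope")
    return (np.asarray(values, dtype=np.float64) - cal.intercept) / cal.slope
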