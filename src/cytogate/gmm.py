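"""2D Gaussian mixture fitting by EM, with optional frozen components.

The central variant here is a constrained EM in which a subset of components
(the background distribution, previously fitted to a buffer blank) is held
fixed: their means, covariances, and the weight ratios *among* them never
change, while a single scalar — the total background weight ``pi_bg`` — and
all free (cell) components are optimised.  The M-step weight update under
this constraint is::

    pi_bg       <- (total posterior mass on frozen components) / n
    w_frozen_j  <- pi_bg * r_j          (r_j the fixed relative weights)
    w_free_j    <- N_j / n              (sums to 1 - pi_bg automatically)

which is the maximum-likelihood update, so the usual EM monotonicity
guarantee carries over.  With an empty frozen set the algorithm reduces
exactly (bit for bit) to ordinary EM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .errors import FitFailureError, InvalidInputError

MODEL_FORMAT_VERSION = "cytogate-gmm-1"

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianComponent:
    mean: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2) symmetric positive-definite
    weight: float
    frozen: bool = False

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(-1)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        d = self.mean.shape[0]
        if self.covariance.shape != (d, d):
            raise InvalidInputError("covariance shape does not match mean dimension")
        if not np.allclose(self.covariance, self.covariance.T):
            raise InvalidInputError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise InvalidInputError("covariance must be positive-definite")
        if not (0.0 <= self.weight <= 1.0 + 1e-12):
            raise InvalidInputError("component weight must lie in [0, 1]")


@dataclass
class MixtureModel:
    components: list[GaussianComponent]
    log_likelihood: float = np.nan
    n_events_fit: int = 0
    converged: bool = False
    n_iterations: int = 0
    log_likelihood_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([c.covariance for c in self.components])

    @property
    def frozen_mask(self) -> np.ndarray:
        return np.array([c.frozen for c in self.components], dtype=bool)

    def n_free_parameters(self) -> int:
        """Parameters actually estimated: frozen components cost nothing
        beyond the single background-weight scalar."""
        d = self.components[0].mean.shape[0]
        per_comp = d + d * (d + 1) // 2
        n_frozen = int(self.frozen_mask.sum())
        n_free = self.k - n_frozen
        if n_frozen == 0:
            return per_comp * n_free + (n_free - 1)
        return per_comp * n_free + (n_free - 1) + 1

    def to_dict(self) -> dict:
        return {
            "format": MODEL_FORMAT_VERSION,
            "components": [
                {
                    "mean": c.mean.tolist(),
                    "covariance": c.covariance.tolist(),
                    "weight": c.weight,
                    "frozen": bool(c.frozen),
                }
                for c in self.components
            ],
            "log_likelihood": None
            if np.isnan(self.log_likelihood)
            else self.log_likelihood,
            "n_events_fit": self.n_events_fit,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MixtureModel":
        if doc.get("format") != MODEL_FORMAT_VERSION:
            raise InvalidInputError(
                f"unknown model record format {doc.get('format')!r}"
            )
        comps = [
            GaussianComponent(
                mean=np.array(c["mean"]),
                covariance=np.array(c["covariance"]),
                weight=c["weight"],
                frozen=c["frozen"],
            )
            for c in doc["components"]
        ]
        return cls(
            components=comps,
            log_likelihood=doc["log_likelihood"]
            if doc["log_likelihood"] is not None
            else np.nan,
            n_events_fit=doc["n_events_fit"],
            converged=doc["converged"],
            n_iterations=doc["n_iterations"],
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MixtureModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FitConfig:
    n_random_inits: int = 4
    n_memory_inits: int = 2
    max_iterations: int = 300
    convergence_tol: float = 1e-6
    covariance_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random_inits < 0 or self.n_memory_inits < 0:
            raise InvalidInputError("initialization counts must be >= 0")
        if self.n_random_inits + self.n_memory_inits < 1:
            raise InvalidInputError("at least one initialization is required")
        if self.convergence_tol <= 0:
            raise InvalidInputError("convergence_tol must be > 0")


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = cholesky(cov, lower=True)
    diff = (X - mean).T
    sol = solve_triangular(L, diff, lower=True)
    maha = np.sum(sol * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * _LOG_2PI + logdet + maha)


def _log_weighted_densities(
    X: np.ndarray, weights: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> np.ndarray:
    k = len(weights)
    out = np.empty((X.shape[0], k))
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    for j in range(k):
        if weights[j] <= 0:
            out[:, j] = -np.inf
        else:
            out[:, j] = logw[j] + _log_gaussian(X, means[j], covs[j])
    return out


def responsibilities(model: MixtureModel, X: np.ndarray) -> np.ndarray:
    """Posterior component probabilities; rows sum to one."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X must be finite")
    logd = _log_weighted_densities(X, model.weights, model.means, model.covariances)
    lse = logsumexp(logd, axis=1, keepdims=True)
    return np.exp(logd - lse)


def assign(model: MixtureModel, X: np.ndarray) -> np.ndarray:
    """Hard assignment: argmax posterior, ties to the lowest index."""
    return np.argmax(responsibilities(model, X), axis=1)


class _InitFailed(Exception):
    pass


def _run_em(
    X: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    frozen_means: np.ndarray | None,
    frozen_covs: np.ndarray | None,
    frozen_rel_weights: np.ndarray | None,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, list[float]]:
    """One EM run.  Frozen components (if any) occupy the leading indices."""
    n, d = X.shape
    n_frozen = 0 if frozen_means is None else len(frozen_means)
    k = len(weights)
    floor = config.covariance_floor * np.eye(d)
    reset_counts = np.zeros(k, dtype=int)

    weights = weights.copy()
    means = means.copy()
    covs = covs.copy()
    if n_frozen:
        means[:n_frozen] = frozen_means
        covs[:n_frozen] = frozen_covs

    prev_ll = -np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        logd = _log_weighted_densities(X, weights, means, covs)
        per_event = logsumexp(logd, axis=1)
        ll = float(per_event.sum())
        if not np.isfinite(ll):
            raise _InitFailed("non-finite log-likelihood")
        history.append(ll)
        if it > 1 and abs(ll - prev_ll) <= config.convergence_tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll

        resp = np.exp(logd - per_event[:, None])
        Nj = resp.sum(axis=0)

        did_reset = False
        for j in range(n_frozen, k):
            if Nj[j] < 10.0 and n >= 10:
                if reset_counts[j] >= 1:
                    raise _InitFailed("component collapsed twice")
                reset_counts[j] += 1
                worst = np.argsort(per_event)[: max(d + 1, n // 100)]
                means[j] = X[worst].mean(axis=0)
                covs[j] = np.cov(X.T, bias=True) + floor
                did_reset = True
        if did_reset:
            # redo the E-step with the reset component before updating weights
            logd = _log_weighted_densities(X, weights, means, covs)
            per_event = logsumexp(logd, axis=1)
            resp = np.exp(logd - per_event[:, None])
            Nj = resp.sum(axis=0)
            prev_ll = -np.inf

        if n_frozen:
            pi_bg = float(Nj[:n_frozen].sum() / n)
            weights[:n_frozen] = pi_bg * frozen_rel_weights
            weights[n_frozen:] = Nj[n_frozen:] / n
        else:
            weights = Nj / n

        for j in range(n_frozen, k):
            if Nj[j] <= 0:
                raise _InitFailed("empty component")
            mu = resp[:, j] @ X / Nj[j]
            diff = X - mu
            cov = (resp[:, j, None] * diff).T @ diff / Nj[j] + floor
            means[j] = mu
            covs[j] = 0.5 * (cov + cov.T)
    return weights, means, covs, history[-1], converged, it, history


def _random_start(
    X: np.ndarray,
    n_free: int,
    n_frozen: int,
    frozen_rel_weights: np.ndarray | None,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.shape
    sub = X
    if n > 50_000:
        sub = X[rng.choice(n, 50_000, replace=False)]
    pooled = np.cov(sub.T, bias=True) + config.covariance_floor * np.eye(d)
    floor = config.covariance_floor * np.eye(d)
    if n_free == 1:
        centers = sub.mean(axis=0, keepdims=True)
    else:
        centers, _ = kmeans_plusplus(
            sub, n_clusters=n_free, random_state=int(rng.integers(2**31 - 1))
        )
    # one-hot assignment to the seeded centers gives per-component starting
    # moments; a shared pooled covariance would wash out tight clusters
    dist = np.linalg.norm(sub[:, None, :] - centers[None], axis=2)
    labels = np.argmin(dist, axis=1)
    k = n_frozen + n_free
    means = np.zeros((k, d))
    covs = np.zeros((k, d, d))
    weights = np.zeros(k)
    counts = np.zeros(n_free)
    for j in range(n_free):
        rows = sub[labels == j]
        counts[j] = len(rows)
        if len(rows) > d + 1:
            means[n_frozen + j] = rows.mean(axis=0)
            covs[n_frozen + j] = np.cov(rows.T, bias=True) + floor
        else:
            means[n_frozen + j] = centers[j]
            covs[n_frozen + j] = pooled
    free_frac = np.maximum(counts, 1.0)
    free_frac = free_frac / free_frac.sum()
    if n_frozen:
        pi_bg0 = 0.5
        weights[:n_frozen] = pi_bg0 * frozen_rel_weights
        weights[n_frozen:] = (1.0 - pi_bg0) * free_frac
    else:
        weights[:] = free_frac
    return weights, means, covs


def _memory_start(
    init: MixtureModel,
    n_free: int,
    n_frozen: int,
    frozen_rel_weights: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    free_comps = [c for c in init.components if not c.frozen]
    if len(free_comps) != n_free:
        return None
    d = free_comps[0].mean.shape[0]
    k = n_frozen + n_free
    means = np.zeros((k, d))
    covs = np.zeros((k, d, d))
    weights = np.zeros(k)
    free_w = np.array([c.weight for c in free_comps])
    if free_w.sum() <= 0:
        return None
    free_w = free_w / free_w.sum()
    for i, c in enumerate(free_comps):
        means[n_frozen + i] = c.mean
        covs[n_frozen + i] = c.covariance
    if n_frozen:
        pi_bg0 = 0.5
        weights[:n_frozen] = pi_bg0 * frozen_rel_weights
        weights[n_frozen:] = (1.0 - pi_bg0) * free_w
    else:
        weights[:] = free_w
    return weights, means, covs


def _fit_mixture(
    X: np.ndarray,
    frozen: list[GaussianComponent],
    n_free: int,
    config: FitConfig,
    inits: list[MixtureModel] | None,
) -> MixtureModel:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidInputError("X must be a 2D event matrix")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X must be finite")
    n, d = X.shape
    n_frozen = len(frozen)
    k = n_frozen + n_free
    if n_free < 1:
        raise InvalidInputError("at least one free component is required")
    if k > n:
        raise InvalidInputError(f"more components ({k}) than events ({n})")

    frozen_means = frozen_covs = frozen_rel = None
    if n_frozen:
        fw = np.array([c.weight for c in frozen])
        if not np.isclose(fw.sum(), 1.0, atol=1e-9):
            raise InvalidInputError(
                "frozen relative weights must sum to 1 "
                f"(got {fw.sum():.6g})"
            )
        frozen_means = np.stack([c.mean for c in frozen])
        frozen_covs = np.stack([c.covariance for c in frozen])
        frozen_rel = fw

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    starts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for _ in range(config.n_random_inits):
        starts.append(
            _random_start(X, n_free, n_frozen, frozen_rel, config, rng)
        )
    if inits:
        for init in inits[: config.n_memory_inits]:
            s = _memory_start(init, n_free, n_frozen, frozen_rel)
            if s is not None:
                starts.append(s)
    if not starts:
        raise InvalidInputError("no usable initialization")

    best: tuple[float, tuple] | None = None
    failures = 0
    for w0, m0, c0 in starts:
        try:
            result = _run_em(
                X, w0, m0, c0, frozen_means, frozen_covs, frozen_rel, config
            )
        except _InitFailed:
            failures += 1
            continue
        ll = result[3]
        if best is None or ll > best[0]:
            best = (ll, result)
    if best is None:
        raise FitFailureError(
            f"all {failures} initializations collapsed or diverged"
        )
    weights, means, covs, ll, converged, n_iter, history = best[1]

    components: list[GaussianComponent] = []
    for j, c in enumerate(frozen):
        comp = GaussianComponent(
            mean=c.mean, covariance=c.covariance, weight=float(weights[j]),
            frozen=True,
        )
        # keep the caller's arrays bit-identical
        comp.mean = c.mean
        comp.covariance = c.covariance
        components.append(comp)
    for j in range(n_frozen, k):
        components.append(
            GaussianComponent(
                mean=means[j], covariance=covs[j], weight=float(weights[j]),
                frozen=False,
            )
        )
    return MixtureModel(
        components=components,
        log_likelihood=ll,
        n_events_fit=n,
        converged=converged,
        n_iterations=n_iter,
        log_likelihood_history=history,
    )


def fit_gmm(
    X: np.ndarray,
    k: int,
    config: FitConfig | None = None,
    inits: list[MixtureModel] | None = None,
) -> MixtureModel:
    """Fit an unconstrained k-component Gaussian mixture by EM.

    Runs ``config.n_random_inits`` k-means++-seeded starts plus any
    warm starts in ``inits`` (used when their component count matches),
    and keeps the highest-likelihood result.  Deterministic for a fixed
    ``config.seed``.
    """
    if config is None:
        config = FitConfig()
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    return _fit_mixture(X, [], k, config, inits)


def fit_constrained_gmm(
    X: np.ndarray,
    frozen: list[GaussianComponent],
    n_free: int,
    config: FitConfig | None = None,
    inits: list[MixtureModel] | None = None,
) -> MixtureModel:
    """Fit a mixture in which ``frozen`` components are held fixed.

    The frozen components' means and covariances are returned bit-identical
    to the inputs; their weights become ``pi_bg * relative_weight`` with the
    scalar ``pi_bg`` optimised by EM alongside the free components.  The
    input ``frozen`` weights are interpreted as relative weights and must
    sum to one.  With ``frozen == []`` this is exactly :func:`fit_gmm`.
    """
    if config is None:
        config = FitConfig()
    return _fit_mixture(X, frozen, n_free, config, inits)


def bic(model: MixtureModel, X: np.ndarray) -> float:
    """Bayesian information criterion ``p ln(n) - 2 logL``; lower is better.

    The log-likelihood is evaluated on ``X``; ``p`` counts only parameters
    the fit actually estimated (frozen components cost one shared scalar).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] == 0:
        raise InvalidInputError("X must be non-empty")
    logd = _log_weighted_densities(X, model.weights, model.means, model.covariances)
    ll = float(logsumexp(logd, axis=1).sum())
    p = model.n_free_parameters()
    return p * np.log(X.shape[0]) - 2.0 * ll


def select_k_by_bic(
    X: np.ndarray,
    k_range: tuple[int, int],
    config: FitConfig | None = None,
) -> int:
    """Fit every k in the inclusive range and return the BIC minimiser.

    Ties break toward smaller k.  Each k uses a fresh set of random
    initializations derived from the same seed.
    """
    if config is None:
        config = FitConfig()
    k_min, k_max = k_range
    n = np.asarray(X).shape[0]
    if not (1 <= k_min <= k_max <= n):
        raise InvalidInputError(f"invalid k range [{k_min}, {k_max}] for n={n}")
    if k_min == k_max:
        return k_min
    best_k = None
    best_bic = np.inf
    last_err: Exception | None = None
    for k in range(k_min, k_max + 1):
        try:
            model = fit_gmm(X, k, config)
        except FitFailureError as exc:
            last_err = exc
            continue
        b = bic(model, X)
        if b < best_bic:
            best_bic = b
            best_k = k
    if best_k is None:
        raise FitFailureError(f"every k in [{k_min}, {k_max}] failed: {last_err}")
    return best_k
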