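# Methods

This note documents the statistical machinery behind `cytogate`, the
choices made where the design was open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Mixture model and constrained EM

All gating stages fit 2D Gaussian mixtures by expectation–maximisation in
log₁₀ signal space, where scatter and fluorescence populations are
approximately Gaussian. The central variant is a *constrained* EM used by
cell gating: a set of background components — previously fitted to a
buffer blank — is frozen, meaning their means, covariances, and the
relative weights among them never change. Only a single scalar, the total
background weight π_bg, and the free (cell) components are optimised.

The M-step weight update under this constraint is the maximum-likelihood
solution of the Lagrangian with the fixed-ratio side condition:

    π_bg      ← (Σᵢ Σ_{j∈frozen} rᵢⱼ) / n
    w_j       ← π_bg · ρ_j                (frozen j, ρ_j the fixed ratios)
    w_j       ← Nⱼ / n                    (free j; sums to 1 − π_bg)

where rᵢⱼ are posterior responsibilities and Nⱼ = Σᵢ rᵢⱼ. Because each
M-step still maximises the expected complete-data log-likelihood within
the constrained parameter set, the usual EM monotonicity guarantee holds;
the per-iteration log-likelihood history is stored on every fitted model
and asserted non-decreasing in the test suite. With an empty frozen set
the update reduces exactly — bit for bit — to ordinary EM, which is how
the unconstrained `fit_gmm` is implemented.

Frozen component arrays are passed through by reference, so the fitted
combined model contains the blank-fit means and covariances bitwise
unchanged. This is asserted end-to-end.

### Initialisation

Random starts are seeded by k-means++ on the data (subsampled to ≤50 000
events), followed by a one-hot assignment step that gives each component
its own starting mean, covariance and weight. Starting every component
from the pooled covariance instead proved unable to resolve tight,
well-separated clusters (e.g. low-noise bead populations): with a
covariance spanning the whole data range the responsibilities are nearly
uniform and the means collapse toward the grand mean on the first
iteration. Per-cluster starting moments fix this and match common
practice in mature EM implementations.

Warm starts re-use free components of previously fitted models from the
analysis memory (only when component counts match; weights are
renormalised). The best run over all starts, by final log-likelihood, is
returned. Everything is driven by one integer seed, so a fit is a
deterministic function of (data, configuration).

### Numerical choices

- Convergence: relative log-likelihood change < 1e-6, cap 300 iterations.
- Covariance floor: 1e-6 added to the diagonal after every M-step,
  preventing singular collapse on near-duplicate points.
- Degenerate components (posterior mass < 10 events) are re-seeded once
  from the lowest-likelihood events; a second collapse fails that start.
- Densities are evaluated via Cholesky factorisation with log-sum-exp
  normalisation; posteriors are exact row-normalised densities.
- BIC = p ln n − 2 ln L with p counting only estimated parameters: an
  unconstrained 2D k-component model has p = 6k − 1; a constrained model
  with f free components has p = 6f (5 per free component, f − 1 free
  weight ratios, plus the π_bg scalar). Frozen parameters were not
  estimated on the data at hand, so they are not charged. Ties in BIC
  selection break toward fewer components.

## Cell gating

The blank is fitted on (log₁₀ FSC-H, log₁₀ SSC-H) of events with both
heights positive; non-positive events cannot be log-transformed and are
dropped from fitting and never kept by any gate (they still count in
per-sample totals). The background component count defaults to BIC
selection over 1–12 — background clouds truncated at the trigger
threshold are strongly non-Gaussian and routinely need many components
(eight is typical) — but should be pinned once known, since BIC selection
refits every candidate k.

The combined fit pools the scatter data of all samples in the batch
(concatenated in sorted sample order so the result cannot depend on
listing order; subsampled to ≤200 000 events for EM speed — assignment
always uses every event). Component labelling is structural: frozen ⇒
background, free ⇒ cell. No positional heuristic re-labels components,
so a cell cluster sitting unusually low still gates as cells. The default
of 3 free cell components reflects the typical structure of a bacterial
sample (main population plus satellite sub-populations).

## Singlet gating

Both variants fit a plain mixture (default 4 components) to cell-gated
events, pooled per batch, then label components:

- **ratio**: feature y = log₁₀(SSC-H/SSC-A). Components with
  |mean_y − c₀| ≤ 0.1 are singlets; c₀ = 0 by default (height and area
  agree for singlets on a calibrated instrument) and is adjustable for
  other instruments. The 0.1 log₁₀ tolerance (≈ ±26 % linear) cleanly
  separates the singlet center (0) from the doublet center (≈ −0.30,
  area doubled).
- **width**: feature y = log₁₀ SSC-W. Components centered below the
  cutoff are singlets. The automatic cutoff is 1.4× the *linear* width
  center of the modal cluster (the component with most assigned events),
  i.e. modal log-center + log₁₀ 1.4; an explicit cutoff is given in
  log₁₀ width units. The cutoff axis is width, not height: pulse width is
  the quantity that distinguishes multiplets on this plot, and a
  multiplicative threshold on the modal (singlet) width is what makes the
  rule instrument-independent.

## Bead calibration

`fit_bead_data` chains four steps:

1. **Singlet bead gate** — the dominant scatter cluster (count chosen by
   BIC over 1–3, so clean single-cluster data is untouched) followed by
   the height/area-ratio singlet rule. Fewer than 500 surviving events is
   an error suggesting re-acquisition.
2. **Cluster identification** — an n-component (default 8) 2D GMM on
   log₁₀ of two fluorescence channels. Non-positive intensities are
   floored at half the smallest positive observed value: the dimmest bead
   population can straddle zero, and dropping those events would bias its
   mean. Components with far less than a population's share of events
   (< 0.25/n of the data) are treated as noise catch-alls and discarded;
   components whose means lie within Mahalanobis distance 1.5 of another
   component (under either covariance) are duplicates of one population
   and are merged. A resolved count below the requested count triggers a
   warning.
3. **Outlier exclusion** — events with Mahalanobis distance > 3 to their
   assigned cluster in log space are excluded from mean computation
   (expected exclusion ≈ 1.1 % for clean Gaussian clusters, the χ²₂ tail
   beyond 9).
4. **Line fit** — per channel, the arithmetic mean of linear-scale
   intensities of non-outlier events per cluster is matched to the vendor
   MEF levels by rank; when fewer clusters than levels are resolved the
   *lowest* levels are dropped, because the trigger threshold censors dim
   beads, never bright ones. The line `intensity = a + b·MEF` is fitted
   by least squares with 1/intensity residual weights. Bead intensity
   noise has a roughly constant coefficient of variation, so absolute
   residuals grow linearly with intensity; unweighted least squares lets
   the brightest clusters (3 decades above the dimmest) dominate and
   leaves the intercept with a sampling error of the same order as the
   intercept itself, while the weighted fit anchors it on the precisely
   measured dim clusters. The reported r² is the unweighted linear
   correlation of cluster means vs. levels. Calibration requires ≥ 2
   matched clusters, strictly increasing means, and a positive slope.

Fitting in two fluorescence dimensions is what resolves bead populations
that coincide on one channel; the test suite carries a one-channel
baseline demonstrating that the two dimmest populations of such a set are
unresolvable in 1D while 2D assignment is ≥ 99 % correct.

## Synthetic data

The generator emulates the features each pipeline stage keys on, with one
global seed feeding named RNG streams (adding a sample never perturbs
another sample's draws):

- **Background**: an 8-component mixture in log scatter space hugging the
  trigger threshold, asymmetric and multi-modal. Threshold truncation is
  by rejection sampling (clamping would create point masses that destroy
  mixture fits); exhausting the retry budget is an error.
- **Cells**: three log-normal scatter clusters well above background
  (defaults ≈ 1 log₁₀ unit away), 30 % background events and 20 %
  doublets among cells by default, per-component log-normal fluorescence.
- **Pulse geometry**: singlets have log₁₀(area/height) ~ N(0, 0.015) and
  log width ~ N(1.78, 0.05); doublets double the area, inflate height by
  a factor uniform in [1.0, 1.4], and shift log width by +log₁₀ 1.6
  (spread 0.05). These constants are generator defaults chosen so both
  geometric signatures separate doublets — they are not measured
  instrument properties.
- **Beads**: eight sub-populations, measured intensity log-normal around
  `intercept + slope·MEF` with constant CV (default slope 2.5,
  intercept 40, cv 0.05), one tight scatter cluster, optional doublets
  with summed fluorescence. An "overlap" level set makes the two dimmest
  populations nearly coincide on the first channel while separating on
  the second.

What passing tests show: the algorithms recover known structure under the
distributional assumptions they encode (log-normal clusters, Gaussian
ratio noise, linear calibration). What they do not show: robustness to
spectral spillover, time drift, heavy-tailed debris, or instruments whose
height/area calibration deviates from the singlet ratio assumption —
none of which the generator simulates.

## Problem sizes

Tests and the verification script run at desk scale, chosen to estimate
each quantity with comfortable statistical margin: 20 000 events per cell
sample (three samples per batch; matching typical per-sample singlet
yields in bacterial runs), 30 000-event blanks, 8 000–10 000-event bead
samples, 20 seeds for BIC recovery, 100 random instances for the EM
invariants.

## Known limitations

- No compensation/spillover handling; calibration is per-channel linear.
- Scatter gating is strictly 2D (FSC-H/SSC-H); no >2D mixtures.
- Only FCS DATATYPE F/I list-mode files are read; ANALYSIS segments and
  multi-dataset files are rejected.
- The number of cell components is user-specified, not selected
  automatically.
- The bead cluster↔level matching assumes censoring from below; a bead
  set whose *brightest* levels saturate the detector would be mismatched.
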