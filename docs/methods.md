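# Methods

This note records the modeling assumptions, parameter conventions,
numerical choices and known limitations of the package. The README
describes the pipeline; here we document why each piece is the way it
is.

## Model and assumptions

The observation model is a log-Gaussian Cox process on a panel of
cluster-level counts:

    Y[c, t] | Λ ~ Poisson(Λ[c, t])
    log Λ[c, t] = α_c + β_{month(t)} + F[c, t]
    F ~ GP(0, K ⊗ L̃²)

Assumptions worth making explicit:

- **Separability.** Spatiotemporal covariance factors as (temporal
  Gram matrix) × (spatial operator). Cross terms like "temporal
  correlation decaying differently between distant clusters" cannot be
  represented.
- **Conditional Poisson.** Overdispersion beyond what the latent field
  supplies is not modeled. A negative-binomial likelihood is left as an
  extension hook on `ModelSpec` (`likelihood="negative_binomial"`,
  `nb_overdispersion`); the estimation routines do not exercise it.
- **Known covariance factors at fit time.** `K` and `L̃²` are built
  from surrogate covariates *before* the latent-field fit; only the
  kernel hyperparameters `(σ², ρ_p, ρ_rbf)` are integrated over, via a
  grid. Uncertainty in the learned graph is not propagated.
- **Fixed effects.** Cluster intercepts plus month-of-year effects with
  December as the reference category (11 free β's). The month indicator
  is calendar membership `month(t) = m`. Fixed effects carry vague
  N(0, 1000) priors.

## Clustering stage

- Dissimilarity is Euclidean distance on column-z-scored attributes, so
  clustering is invariant to attribute units.
- The minimum spanning tree uses Prim's algorithm with lexicographic
  tie-breaking on (weight, i, j); reruns are bit-identical.
- Tree pruning evaluates **every** edge of every current subtree each
  iteration (full expansion). This is quadratic-ish but exact for the
  greedy objective, and cheap at the intended scale (≤ a few hundred
  units). Splits violating the active constraint (minimum cluster
  population, or size bounds) are excluded from the argmax; when no
  feasible split remains, the search stops early with a warning and
  returns the achieved number of clusters.
- Silhouette widths use the convention s(i) = 0 for singleton clusters
  and when both mean distances are zero (all-identical attributes).
- Point data carry no polygons, so contiguity is a great-circle
  distance threshold or symmetrized k-nearest-neighbors
  (`connected_knn_adjacency` grows k until the graph connects).
  Polygon-based queen/rook contiguity is out of scope.

## Censored counts and decomposition

- Privacy-masked cells ("<11") are imputed by a truncated-Poisson EM
  with one rate per (cluster, calendar-month) group — matching the
  monthly seasonal structure of the data; the grouping is an argument.
  The E-step fills each censored cell with E[Y | a ≤ Y ≤ b; λ], the
  M-step re-averages; the censored-data log-likelihood is
  non-decreasing and imputations are clamped to [a, b]. Final imputed
  counts are rounded (they feed a Poisson likelihood); the unrounded
  expectations are also returned.
- Seasonal decomposition is the classical additive one: centered
  12-term moving average for trend, month-of-year means of the
  detrended series (re-centered to sum to zero) for the seasonal part,
  remainder as residual. Trend edges are extended with the nearest
  defined value so residual-driven kernels see full-length series; the
  reconstruction identity trend + seasonal + residual = series holds
  exactly by construction.

## Graph learning

- The graphical lasso (off-diagonal L1 penalty, diagonal free) is
  solved by the classic block coordinate-descent sweep on the
  covariance with inner lasso coordinate descent. Convergence is
  verified by the stationarity (KKT) residual; non-convergence raises
  with the residual attached.
- Model selection minimizes `EBIC_γ = −2ℓ(Θ̂) + 4|E| ln T + 4γ ln p`
  (γ = 0.5 by default) along a 10-point log-spaced penalty path from
  λ_max (all off-diagonals shrunk) to 0.01·λ_max. The likelihood is
  evaluated at the **support-constrained MLE** of each candidate edge
  set (iterative modified regression with known structure), not at the
  shrunk path estimate — otherwise the criterion confounds support
  choice with L1 bias and systematically keeps one spurious edge. Ties
  resolve to the sparser model. The −(Tp/2)log 2π likelihood constant
  is omitted; it cancels across models on the same data.
- The penalty coefficients (4 per edge, 4γ on the dimension term) are
  intentionally heavier than the common BIC convention; selection is
  correspondingly conservative, and weakly-correlated panels can yield
  an empty graph (the spatial operator then degenerates to ε·I with a
  warning).

## Spectral filter

- Eigenvalues of `L = D − A` are sorted **ascending** and the filter
  keeps index i iff `i ≤ ceil(q·C)`: q = 1 keeps everything, any q > 0
  keeps the zero eigenvalue (the graph-constant mode). Keeping the
  *smallest* eigenvalues is the only reading consistent with low-pass
  smoothing (it guarantees `fᵀL̃f ≤ fᵀLf`); a `descending` flag
  provides the literal keep-largest variant, and `filter_fn` accepts
  arbitrary spectral filters.
- The spatial covariance is the matrix square `L̃·L̃` (elementwise
  squaring would break positive semidefiniteness) plus a jitter
  defaulting to `1e−6 × mean(diag(L̃²) + 1)`. Because the zero
  eigenvalue is always kept, `L̃²` is singular by design and the
  jittered covariance is severely ill-conditioned; see the whitening
  note below.

## Kernels

- The locally periodic kernel is
  `σ² exp(−c·sin²(π‖u−v‖/period)/ρ_p) · exp(−‖u−v‖²/(2ρ_rbf))` with
  `c = periodic_factor = 1` by default (2 selectable — both conventions
  circulate). Features are standardized column-wise before distances;
  purely temporal Gram matrices use raw month indices so the 12-month
  period stays physically meaningful.
- Banded (`|t1−t2| ≤ p`) and distributed-lag (`|t1−t2| ∈ D`) kernels on
  decomposition residuals are **indefinite in general** — a PSD kernel
  times a band indicator need not be PSD. Before use as a covariance
  factor, negative eigenvalues are clipped to zero and a relative
  jitter (1e−8·σ²) is added.
- The cross-covariate interaction kernel is not symmetric as defined;
  the Gram matrix entry is the average of the two directional
  evaluations so K stays a valid covariance.
- Additive mixtures use uniform convex weights 1/J; multiplicative
  mixtures use weights 1 (elementwise Schur products of PSD matrices
  stay PSD). For the M5 family the additive mixture spans the time
  kernel, banded and lag kernels for every (cluster, covariate) series,
  and interaction kernels for every unordered covariate pair.
- The Kronecker covariance is held in factored form (cluster index
  fastest: flat cell index = t·C + c). Solves, log-determinants and
  sampling use factor eigendecompositions or Cholesky factors; the
  dense matrix is only materialized below C·T = 5000 for testing.

## Inference

- Per hyperparameter configuration, the joint vector u = (F, α, β) is
  optimized by Newton-Raphson with step halving. **Whitening:** the
  optimization runs in v = L⁻¹u where L is the prior-covariance
  Cholesky factor (`chol(K) ⊗ chol(L̃²)` for the Kronecker prior), so
  the prior precision is the identity regardless of how close to
  singular the filtered operator makes the prior. The Laplace evidence
  is invariant under this linear change of variables, and the Gaussian
  approximation in original coordinates is N(L·v*, L·H⁻¹·Lᵀ) with
  H = I + (ZL)ᵀW(ZL).
- Convergence: gradient ∞-norm below `1e−8 × max(1, ‖AᵀY‖_∞)` — the
  relative scaling is required because gradient entries scale with
  count sums and an absolute 1e−8 is unreachable in double precision on
  large panels. Maximum 100 iterations; the line-search acceptance
  slack is likewise relative to the objective magnitude.
- Initialization: fixed effects from one least-squares pass on
  log(y + 0.5), latent field at zero.
- The hyperparameter grid is a Latin hypercube on log scale (one point
  per stratum per axis, seeded); grid weights are normalized
  exponentiated Laplace evidences — scattered LHS points have no
  natural quadrature areas, so base weights are uniform. M1R's τ gets
  its vague log-gamma(1, 1e−5) prior added to the evidence; kernel
  hyperparameters are uniform on the log-bounded box.
- Marginals of each scalar effect are evidence-weighted mixtures of the
  per-point Gaussian approximations: moments in closed form, quantiles
  by root-finding on the mixture CDF. **Only the Gaussian-approximation
  marginals are computed**; full and simplified Laplace refinements are
  a documented extension point. Consequently marginal means inherit the
  mode-vs-mean gap of skewed posteriors, which is O(1/count) per cell —
  negligible for the panel sizes targeted, and visible in single-cell
  toys.
- WAIC and DIC are computed from seeded draws of the mixture; the
  posterior predictive draws latent values at held-out cells from the
  conditional Gaussian mixture and counts from Poisson. The rolling
  protocol appends each step's rounded predictive mean (median
  selectable) to the history before refitting, so the filtration grows
  with the model's own forecasts; its intervals do not account for
  pseudo-observation error and can undercover at long horizons — the
  simultaneous protocol is the calibrated one.
- Poisson exposures enter as an optional log-offset, default zero (raw
  counts are modeled).

## Synthetic data

The generators define the study conditions for all tests:

- `generate_geography`: C geographic blocks one degree apart with
  ±0.35° within-block jitter (blocks touch but do not interleave),
  log-normal populations (median ≈ 60k), and attribute vectors at
  block centers rescaled so the closest pair of centers is 6 noise
  standard deviations apart — "well separated" in the sense that
  single-linkage contiguity clustering should recover the partition.
- `quasi_periodic_covariates`: annual sine with random phase + weak
  linear trend + AR(1) noise per unit; optionally a cluster-level
  AR-smoothed signal whose innovations are chain-correlated across
  cluster indices (coefficient 0.7, scale comparable to the seasonal
  cycle) — the regional structure the graph learner is supposed to
  find.
- `generate_latent_field_counts`: exact draws from the model via the factored
  Cholesky identity, with cluster intercepts uniform on a configurable
  log range (default e¹–e^2.5 ≈ 3–12 expected counts; recovery studies
  use 3.0–4.0 ≈ 20–55) and a sinusoidal month-effect profile anchored
  at zero in December. Log-intensities above 30 abort with advice to
  shrink σ².
- `generate_modulated_counts`: intensities
  `exp(a_c + A(t)·sin(2πt/P(t)))` with linearly drifting amplitude and
  period — a deliberately nonstationary regime that fixed monthly
  effects cannot track; drifting the period through zero raises.

What the synthetic data do **not** emulate: real covariate marginal
distributions, measurement error, missing months, population migration,
or age structure. Passing tests demonstrate internal consistency and
calibration under the model's own assumptions, not robustness to their
violation.

## Problem sizes

The shipped experiments use C = 4 clusters, T = 60 months, N = 20–30
units, Latin-hypercube grids of 8–24 points, 20 simulation seeds for
recovery, 200 held-out cells for calibration, and a 200k-draw
random-walk Metropolis chain (C = 2, T = 24) as the sampling
cross-check. These sizes were chosen so the full study runs on a single
CPU in minutes while leaving the statistical checks adequately powered;
everything scales by configuration.

## Known limitations

- Hyperparameter length-scales (ρ_p, ρ_rbf) are weakly identified from
  a single latent-field realization at C = 4, T = 60; the evidence
  surface is sharp in σ² but flat within roughly a factor of two in the
  length-scales. Grid selection should be read accordingly.
- Graph uncertainty and cluster-assignment uncertainty are not
  propagated into the posterior.
- The EBIC's heavy penalty makes the empty graph a common outcome on
  weakly dependent panels; the pipeline proceeds (covariance ε·I) but
  warns.
- Newton with a Poisson likelihood can overflow for log-intensities
  above ~50; the optimizer raises with advice rather than silently
  clipping.
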