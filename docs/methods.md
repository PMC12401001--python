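# Methods

This note documents the models and numerical choices behind `idpotency`:
what each component assumes, which parameters matter, what the synthetic
data does and does not emulate, and where the design was genuinely open.

## Preprocessing

Counts are filtered per cell on three thresholds — total counts, detected
genes, mitochondrial fraction — applied in that order for reporting
purposes (a cell failing several criteria is counted against the first).
Mitochondrial genes are recognized by a case-insensitive id prefix
(default `MT-`); the mitochondrial "percent" is the fraction of a cell's
total counts carried by those genes. Threshold values are dataset-specific
and therefore configuration inputs, not package defaults: the shipped
defaults (0, 0, 1.0) are vacuous on purpose. Author-flagged doublets are
removed via an explicit exclude list before thresholding; no doublet
detection is performed. Gene selection (e.g. to protein-coding genes) is an
exact-id set intersection against a user-supplied list — no identifier
alias resolution — and passing no list uses every gene, the conventional
fallback for organisms without a curated annotation. Normalization divides
each cell by its total count, giving relative-abundance profiles that sum
to one; distances are computed on these profiles directly, with no log
transform (any transform is left to the caller's embedding step).

## Intrinsic-dimension estimators

**TWO-NN.** Under local uniformity on a d-dimensional manifold, the ratio
mu = r2/r1 of each point's second- to first-neighbor distance is Pareto:
F(mu) = 1 − mu^(−d). Both standard reductions are implemented:

* `twonn_mle`: d = n / Σ ln mu — the Pareto maximum-likelihood estimate;
* `twonn_cdf`: sort mu ascending, assign empirical CDF F_i = i/(n+1)
  (this convention avoids the −ln(1−F) = ∞ endpoint without special-casing;
  F_i = i/n with the last point dropped is available), discard the top
  `ceil(0.1 n)` ratios, and fit d = Σxy/Σx² with x = ln mu, y = −ln(1−F)
  — a least-squares line through the origin. The discarded tail is where
  density inhomogeneity and manifold boundaries distort the Pareto law.

Neighbor search is exact (`scipy.spatial.distance.cdist`), ties broken by
point index via a stable argsort. Exact coordinate duplicates are collapsed
to their first occurrence before the search — r1 = 0 would make mu
undefined, and low-depth cells can collide after normalization — with the
collapsed count surfaced in diagnostics so data pathologies are visible.

`twonn_cdf` with 10% discard is the default for expression data. One
documented exception: the Hopfield temperature sweep defaults to
`twonn_mle`, because the ID of spin ensembles saturates above the
transition temperature and adjacent-temperature comparisons become
variance-limited; the MLE reduction has visibly lower variance than the
CDF fit at the sweep's ensemble size (300 configurations).

**PCA variants.** `pca_variance` returns the number of covariance
eigenvalues needed to reach a variance threshold (default 0.9);
`pca_pr` returns the participation ratio (Σλ)²/Σλ², a continuous proxy for
the count of dominant variance directions. Eigenvalues come from the SVD
of centered data, avoiding the gene-by-gene covariance matrix. These
global linear estimators complement the local TWO-NN view; they are more
sensitive to outlier sub-populations and to curvature.

**Finite-sample behavior.** All estimators are biased in the undersampled
regime. On uniform hypercubes at n = 2000 the TWO-NN estimate is accurate
within a few percent at d = 2 and d = 5 but sits 15–18% low at d = 10 (and
is still ~12% low at n = 10000) — the well-known boundary/undersampling
effect of ratio estimators. This is precisely why group comparisons in the
ID-score are made at matched sample sizes rather than on raw estimates.

On a union of manifolds with different dimensions, the pooled estimate is
dominated by the low-dimensional component: for an equal 2-d + 10-d
mixture the MLE identity gives 2n/(n/2 + n/10) = 3.33, far below the
arithmetic mean 6 and close to 2; the measured CDF-fit value is ≈ 3.3–3.5.

## The ID-score

Groups are compared at a single matched subsample size,
floor(0.75 × smallest group), over 10 independent subsamples drawn without
replacement. Floor is used for the size; each (group, replicate) draw
comes from its own deterministic substream of the master seed, keyed on
the group's rank in sorted name order and the replicate index, with group
members canonically ordered by cell id — so results are invariant to the
order cells or groups appear in the input. The per-group replicate mean
and standard deviation are then min-max rescaled across groups:
score = (mean − min)/(max − min), with the standard deviation divided by
the same range so error bars stay commensurate. Rescaling acts on the
replicate means (not the pooled replicate values); both choices are echoed
in the run metadata. Fewer than two distinct means make the score
undefined; the error raised carries the raw per-group results so unscaled
IDs can still be reported.

Two literature comparators ship alongside, computed independently of the
ID-score: per-cell Shannon entropy of the relative-abundance profile
(base 2; the base is a convention, not a claim) and the per-cell count of
expressed genes. They can disagree with the ID-score; no coupling exists
between the scorers.

## Local ID and root selection

Each cell's local ID is the default TWO-NN estimate on the sub-cloud of
the cell plus its k = 70 nearest neighbors (the focal cell is included —
the symmetric choice; the estimate is insensitive to one point among 71).
Coordinates are whatever the caller supplies: typically a low-dimensional
embedding computed upstream (diffusion map, UMAP, PCA), since computing
embeddings is outside this package's scope; full expression profiles work
too. k below 10 destabilizes the estimator and is refused unless
explicitly overridden. Local IDs are min-max rescaled across cells, the
argmax cell is proposed as the pseudotime root (ties broken by cell id and
flagged), and no smoothing over neighborhoods is applied. An externally
computed pseudotime can be Pearson-correlated against the local score; a
strongly negative value indicates the root choice and the trajectory
direction agree.

## Correlation network

Gene-gene Pearson correlations across the cells of one population; an
edge where |r| ≥ threshold (a positive-only mode exists). Zero-variance
genes are excluded and counted. Because "network size" is ambiguous, both
the edge count and the number of connected (degree ≥ 1) genes are
reported. The default threshold 0.7 is a demo value — for reported runs it
should be set deliberately — and a top-variance gene subset bounds the
quadratic cost on large matrices.

## Hopfield freezing model

P random ±1 patterns on N spins, Hebbian couplings
J_ij = (1/N) Σ_mu xi^mu_i xi^mu_j with zero diagonal, energy
E = −(1/2) Σ_{i≠j} J_ij s_i s_j. Sampling is single-spin Glauber
(heat-bath) dynamics — flip probability 1/(1 + exp(ΔE/T)) at uniformly
random sites, one sweep = N attempts — the canonical sampler for this
Hamiltonian. A zero-temperature quench (strict downhill moves) is separate.
The reference sweep uses N = 200, P = 5, six temperatures in [0.2, 3.0],
300 samples per temperature after 500 burn-in sweeps with thinning 10 —
sized to run in well under five minutes on one CPU; all parameters are
configurable. Each temperature gets an independent chain seeded by the
temperature's rank among the sorted distinct values, so per-temperature
results are invariant to sweep order. Ensembles that freeze to fewer than
3 distinct configurations are reported as degenerate rather than aborting.
Temperatures are absolute; the 1/N Hebbian normalization sets the scale,
with the paramagnetic transition near T = 1 for P ≪ N.

## Synthetic data generator

**Manifold samples** draw from a named latent generator (hypercube,
Gaussian, hypersphere surface, swiss roll), embed via a seeded random
orthogonal map (QR of a Gaussian matrix with sign-fixed diagonal for
determinism; the identity when the ambient dimension equals the source
dimension) and optionally add isotropic noise. Unions with per-component
offsets provide composite-manifold stress tests; overlapping supports only
warn, since touching manifolds are a legitimate case.

**Planted hierarchies** emulate the input statistics the scoring pipeline
consumes: groups of cells on latent manifolds whose dimension strictly
decreases with differentiation depth. Per group g with latent dimension
d_g, cells draw z uniform in [0,1]^{d_g} and per-gene rates
softplus(A_g z + b + c_g), normalized per cell; counts are
Poisson(rate × library size) with log-normal library sizes (negative
binomial available behind a flag). Design choices that matter:

* **Heavy-tailed baseline** b ~ N(0, 2.5) on log-rates, giving Zipf-like
  profiles spanning several orders of magnitude as real transcriptomes do.
  Profile mass concentrated on top genes also makes manifold structure
  detectable: the Poisson noise norm on a relative-abundance profile is
  √(Σp/M) = √(1/M) regardless of concentration, while the signal spread
  grows with Σp².
* **Nested loadings**: one shared loading matrix; group g uses its first
  d_g columns, scaled by amplitude/√d_g (amplitude 3). Nesting encodes
  differentiation as the progressive loss of variation directions — the
  freezing picture — and makes group-level nuisance (which genes happen to
  carry strong loadings) cancel between groups; the 1/√d column scale
  keeps each gene's signal variance independent of the group's dimension,
  so groups differ in manifold dimension, not overall variability. A small
  per-group baseline offset (sd 0.3) separates groups in expression space
  without changing their geometry.
* **Sequencing depth** log-normal with mean 10^6, sd 0.25 — a deeply
  sequenced full-length (read-count) regime. This is the binding
  parameter: the planted order is recoverable only when sampling noise is
  below the *lowest*-dimensional group's nearest-neighbor distance, which
  is the smallest in the hierarchy (denser sampling on fewer dimensions).
  At shallow UMI-like depths (10^3–10^4) all groups sit on the noise
  plateau and the measured IDs no longer track the latent dimension —
  itself a faithful reproduction of the undersampling problem, and
  reproducible by lowering `library_log_mean`.
* A fixed mitochondrial gene block (13 genes, 5% of rate mass, shared
  profile) exercises the mito filter.

What the generator does **not** emulate: gene-level dropout curves beyond
Poisson sampling, batch effects, doublets, cell-cycle structure, or
continuous differentiation trajectories (groups are discrete). Passing
tests on these fixtures therefore demonstrate that the pipeline recovers
planted geometric structure under realistic sampling noise — not that any
particular real dataset is this well-behaved.

## Determinism

Every stochastic component takes an integer seed and derives named
substreams (`numpy` `SeedSequence` spawn keys) per stage, group,
replicate, or temperature. CLI runs with identical inputs and seeds
produce byte-identical outputs; every output file is paired with a JSON
sidecar recording the resolved configuration and package version (no
timestamps, so sidecars are reproducible too).

## Known limitations

* Absolute ID values remain sample-size- and noise-dependent; only the
  matched-size comparison across groups is meaningful, and the [0,1]
  rescaling is relative to the groups present in the run.
* TWO-NN underestimates high dimensions at practical sample sizes (see
  above); scores involving groups of very different true dimension are
  compressed but order-preserving in our fixtures.
* Exact neighbor search is O(n²) in memory and time; group subsampling
  keeps this modest, but local-ID on very large embeddings (≫ 10^4 cells)
  will be slow by design (no approximate search, for reproducibility).
* The correlation network uses plain Pearson correlation on relative
  abundances; compositional effects are not removed.
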