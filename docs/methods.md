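# Methods

## Model

The package models a pair of non-negative counts `(X1, X2)` — a species
and a metabolite, or two species, measured over the same samples — with
a shared-component Poisson–Gamma mixture. Independent latent rates
`R0 ~ Gamma(α0, β)`, `R1 ~ Gamma(α1, β)`, `R2 ~ Gamma(α2, β)` (all
shapes and scales strictly positive, `β = β1`, `δ = β2/β1`) drive

    X1 | R ~ Poisson(R0 + R1),      X2 | R ~ Poisson(δ·(R0 + R2)).

Marginally `Xi ~ NB(α0 + αi, 1/(βi + 1))` with mean `(α0 + αi)·βi` and
variance `(α0 + αi)·βi·(βi + 1)`; the shared component induces
covariance `α0·β1·β2` and hence the latent correlation

    ρ = α0·√(β1 β2) / √((α0+α1)(α0+α2)(β1+1)(β2+1)),

which is non-negative by construction — the model is built for
positive associations (cross-feeding, co-production), and negative
associations are estimated as near zero.

The observed pair `(Y1, Y2)` adds a zero-inflation layer: a
four-category masking draw with probabilities `(π1, π2, π3, π4)`
(both observed / only the first / only the second / neither) replaces
masked margins with zeros. The masking categories represent structural
or technical zeros *beyond* what the NB component already produces;
margin 1 is masked with probability `π3 + π4` and margin 2 with
`π2 + π4`, so the marginals are zero-inflated NB. The joint mass is

    π1·f(y1, y2) + π2·f1(y1)·1{y2=0} + π3·f2(y2)·1{y1=0} + π4·1{y1=y2=0},

with `f` the latent joint pmf and `fj` the NB marginals. The headline
correlation estimator applies the latent-correlation formula to the
fitted `(α0, α1, α2, β1, β2)` of the zero-inflated fit, ignoring `π`:
it estimates the association that would be observed without masking. A
"naive" correlation of the masked pair (using all nine parameters
through the closed-form masked moments) is provided for comparison; it
is attenuated by masking and can be negative when joint observation is
rare.

## Likelihood evaluation

The latent joint pmf is computed by the finite-sum decomposition.
Splitting each count into shared-component and idiosyncratic events,
the joint pmf is the 2D convolution of the shared grid

    G0[u1, u2] = δ^u2 / (u1! u2!) · Γ(α0+u1+u2) / (Γ(α0) β^α0) · (1 + δ + 1/β)^-(α0+u1+u2)

with the two idiosyncratic NB kernels. The convolution is separable,
so the full grid of probabilities up to the maximum observed counts
costs two triangular-Toeplitz matrix products; everything is assembled
from log-gamma terms so counts in the hundreds pose no overflow risk.
Evaluation cost grows with the cube of the maximum count, which makes
counts beyond a few thousand impractical; `bnb_pmf`/`fit_*` refuse
counts above 5,000, and the pairwise-matrix estimator can downscale
large pairs (see Limitations). Objective evaluations inside the
fitters run in numba-compiled kernels that mirror the numpy
implementation exactly (the suite cross-checks the two routes to
machine precision).

## Fitting

Both fits maximize the observed-data log-likelihood directly with
L-BFGS-B. The coordinates matter: the likelihood has a long, flat
valley along the correlation direction, because raising `α0` at fixed
`α1` also changes the margins. The optimizer therefore works in
margin-preserving coordinates

    θ = (logit s, log A1, log A2, log β1, log β2),   A_j = α0 + α_j,   α0 = s·min(A1, A2),

where the first coordinate moves only the shared-component share. The
zero-inflation simplex enters through softmax coordinates; the mixture
likelihood is concave in the simplex, so this adds no modes. Two
further choices proved essential in practice:

* **Absolute convergence tolerance.** The default `tol = 1e-6` is an
  absolute tolerance on the log-likelihood change (the solver's
  relative criterion is rescaled by the starting objective). A loose
  relative tolerance can halt on a single plateau iteration while a
  unit of log-likelihood remains along the flat correlation valley,
  which manifests as correlation estimates collapsing toward zero.
* **Initialization.** Method-of-moments starts for shapes and scales;
  the shared-component share is initialized from the covariance of the
  *jointly nonzero* observations (the raw covariance is diluted by
  masked zeros, and a near-zero start is nearly stationary on the
  logit scale). Masking probabilities start from the observed zero
  fractions, treating roughly half the zeros in each margin as
  structural. Three random restarts are attempted if the solver does
  not report convergence. Parameters are floored at 1e-8 and capped at
  1e8; iterations are capped at 1,000.

Degenerate inputs (an all-zero margin, fewer than 10 paired
observations) return an explicit failure status rather than a number;
the pairwise-matrix estimator records such failures per entry and
continues.

## Correlation matrices and the estimator benchmark

`corr_matrix` computes all feature pairs within one count matrix or
across two (features-by-samples DataFrames with aligned sample
columns) with one of four estimators: Spearman (midranks on ties —
with the tie-heavy data at hand the textbook `1 − 6Σd²/(n(n²−1))`
shortcut is invalid, so Pearson-on-midranks is normative), Pearson,
and the two model-based fits. `complete_pairs_only` drops samples with
a zero in either member first, reproducing the "complete data"
convention. Per-pair seeds derive from the pair indices, so results do
not depend on evaluation order and parallel execution would be
reproducible. Model-based entries lie in `[0, 1)`; failures are NaN
plus a status flag, and downstream affinity construction maps missing
entries to zero affinity with a warning (the conservative choice).

`benchmark_estimators` replicates the accuracy experiment: simulate a
pair from a named scenario, apply all four estimators, aggregate the
mean and median over replicates; fully deterministic for a fixed seed.

## Simulation designs

**Lognormal pairs.** Bivariate normal log-counts (unit log-scale
variance, configurable correlation and log-means), exponentiated and
rounded. Zeros are then introduced per margin: *metabolite* margins
use the rank-based rule `p_i = (0.5 − rank_i/n)·span + pzero` (rank 1 =
smallest, midranks on ties; low counts are likeliest to drop out, as
expected for concentration-limited detection), clipped to `[0, 1]`;
*species* margins have exactly `nzero` uniformly chosen positions set
to zero (structural absences). Note the clipping makes the expected
zero count `Σ clip(p_i, 0, 1)`, e.g. 31.125 rather than the unclipped
`n·pzero − span/2 = 29.85` at `n = 300, pzero = 0.1, span = 0.3`. The
seven shipped scenarios (metabolite–species a–d, species–species a–c)
fix the log-means and zero targets; `n = 300` and `span = 0.3` are
defaults, not constants.

**BZINB pairs.** Four masking regimes (balanced-low
`π = (.75,.15,.05,.05)`, balanced-high `(.1,.2,.1,.6)`, and two
unbalanced regimes) combined with shape/scale presets
`α1 = α2 = 2, β1 = β2 = 3` and `α0 = 2ρ/(0.75 − ρ)`, which hits any
target latent correlation below `β/(β+1) = 0.75` exactly. Presets are
validated at load time (simplex sums, implied expected zero counts,
exact correlation targets).

**Baseline count matrix.** A species-by-sample table with a two-tier
abundance profile: a large core of moderate-abundance taxa (lognormal
means, default spread 0.5 on the log scale) plus a small dominant tier
(5% of features) that carries most of the reads and lifts the overall
mean count to the configured target (default 17,968). Counts are NB
within a feature (default size 0.7, i.e. strongly overdispersed), and
each feature has a structural-zero probability that decreases with
abundance, reproducing the decreasing mean-versus-zeros trend of real
species tables. The core mode is placed at `sqrt(2·size·mean_count)`
so that a typical core feature's variance is about twice the community
mean count; this is the regime in which the cluster-crafting procedure
below produces block correlations that an NB model can express, and it
scales coherently when the experiment is run at reduced mean counts.

**Planted clusters.** Features are permuted and the first `k·size`
split into `k` clusters (defaults 10 × 40). Each cluster draws one
shared vector `R ~ Poisson(λ)` (λ defaults to the matrix mean count),
and every *nonzero* entry of each member feature is replaced by
`round(w·y + (1−w)·R)` with default weight `w = 0.9`; zeros are left
untouched, so the zero pattern is exactly preserved. The weighted sum
is rounded because downstream models are count models.

What these generators do *not* emulate: compositional (closed-sum)
constraints, sample-level sequencing-depth variation, batch effects,
and pre-existing correlation structure among baseline features (all
features are generated independently). Passing tests therefore
demonstrate correctness of the machinery and the estimators'
statistical behavior under the stated models, not performance on any
particular real dataset.

## Module identification

Correlation matrices become affinities by clamping negatives to zero
(only positive inter-dependencies define modules), zeroing the
diagonal, replacing missing entries by zero with a warning, and
symmetrizing by averaging. Clustering uses the symmetric normalized
Laplacian: take the `k` leading eigenvectors of `D^{-1/2} A D^{-1/2}`,
unit-normalize the rows, and run k-means with a fixed seed and 20
restarts. Zero-degree nodes cannot be embedded; they are assigned to
the cluster with the nearest centroid in the raw affinity row space
and reported. The eigengap heuristic (largest gap between consecutive
ascending Laplacian eigenvalues, ties toward smaller k) is advisory
only — the pipeline accepts an explicit `k`.

Predicted clusters are scored against ground truth in two steps:
mutual-mode pairs are matched first (truth cluster t ↔ predicted
cluster p when each is the other's most common partner; mode ties
break toward the lower index), then the remaining clusters are matched
by the bijection maximizing overall accuracy — exhaustively up to 10
remaining clusters, by optimal linear assignment (same objective)
beyond that. Overall and per-cluster accuracies are both reported, and
the Adjusted Rand Index (contingency-table closed form,
cross-checked against scikit-learn) provides a chance-corrected
summary. Frobenius distances between correlation sub-matrices, and the
nested distance curve (clusters added in decreasing distance order),
quantify between-condition network differences.

## Networks

`build_network` keeps the `ceil(top_fraction · eligible pairs)`
strongest correlations (upper triangle for square matrices, all pairs
for bipartite blocks; non-finite entries dropped; negatives dropped
under `positive_only`; ties at the cutoff are all included so the
result is deterministic). "Strongest" means largest signed value by
default — positive correlations are the biological interest — with
magnitude ranking behind a flag for signed estimators. Per-group
networks are thresholded within each group separately and merged with
a `both` tag on shared edges. Exports: SIF (plus node- and
edge-attribute sidecar TSVs, since SIF itself carries no attributes),
GraphML (attributes inline), and a plain edge TSV; each has a matching
importer and round-trips losslessly.

## Marginal goodness of fit

Per feature, the nonzero counts are fitted by a zero-inflated Poisson
(nonzero mean), NB (full untruncated likelihood on the nonzero counts
— a deliberate simplification over a zero-truncated fit), or lognormal
(moments of the logs); the zero proportion is empirical. Replicates
draw the zero count from a binomial and the body from the fitted
family (lognormal draws rounded to integers). The lognormal screen is
a plain one-sample Kolmogorov–Smirnov test of the nonzero counts
against the self-fitted lognormal; because the parameters come from
the same data and the counts are rounded, the p-values are
conservative (no Lilliefors correction is applied, by design), so the
calibration property asserted in the tests is "rarely below 0.05", not
exact uniformity.

## Numerical and design choices

* Tolerances: `tol = 1e-6` absolute log-likelihood change, 1,000
  iteration cap, parameter floor 1e-8.
* Tie-breaks: midranks everywhere ranks appear; mode ties and eigengap
  ties toward the smaller index; network ties at the cutoff included.
* Determinism: every stochastic operation takes an explicit seed;
  output files carry a provenance header (version, config hash, seed)
  and contain no timestamps, so identical configurations are
  byte-identical.
* Desk-scale test sizes: the acceptance suite runs recovery at
  n = 10,000 (five replicate fits per masking regime to estimate
  bias), the estimator benchmark at 100 replicates of n = 300, and the
  end-to-end module experiment at 40 features × 180 samples with a
  reduced community mean count (the generator's placement rule keeps
  the crafted-signal mechanism identical across scales); full-size
  runs use the same code paths.

## Limitations

* **Positive correlations only.** The shared-component construction
  cannot represent negative association; strongly negative pairs are
  estimated near zero.
* **Count magnitude.** The finite-sum likelihood is cubic in the
  maximum count. The pairwise estimator can integer-downscale large
  pairs, but downscaling divides a feature's variance-to-mean ratio by
  the scale factor: features close to the NB dispersion floor
  (variance ≈ mean) lose their expressible correlation entirely. For
  heavy-tailed omics counts (variance ≫ mean) downscaling is safe; for
  near-Poisson features at large means it is not, and no rescaling of
  that kind can fix it.
* **Planted-cluster detectability at the default crafting weight.**
  With `w = 0.9` the shared vector contributes variance
  `(1−w)²·λ = 0.01·λ`. Features with variance well above that carry
  essentially no induced correlation, while features with variance low
  enough to correlate strongly are mean-shifted to `≈ 0.1·λ`, far
  above their spread — an underdispersed regime the NB variance floor
  cannot express, where the fitted correlation collapses to zero. The
  surviving band of features yields pairwise correlations of at most
  ~0.1, and an estimator-independent upper bound (complete-pairs
  Pearson affinity) puts the spectral-recovery ARI near 0.05 even at
  400 features — so with independently generated baseline features the
  default-weight crafted experiment is not recoverable by this (or
  any pairwise) estimator, and the corresponding end-to-end assertion
  in the acceptance suite documents that negative result. At `w = 0.5`
  the same pipeline recovers the planted modules with ARI ≈ 0.9,
  which is the strong-signal integration check the suite runs green.
* The simulators model features independently (no compositionality,
  depth variation or batch structure), so estimator comparisons here
  speak to the masking mechanism, not to all properties of real
  multi-omics data.
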