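# bzinbnet

Model-based correlation, module discovery and network construction for
zero-inflated paired count data — built for integrating microbiome
species profiles with metabolite abundances (and species with species),
where excess zeros from structural absences and technical dropout bias
the usual Spearman and Pearson estimates toward zero.

## The model

A pair of counts is modeled with a **bivariate zero-inflated negative
binomial (BZINB)**. The latent layer is a shared-component
Poisson–Gamma mixture: with independent

```
R0 ~ Gamma(α0, β),   R1 ~ Gamma(α1, β),   R2 ~ Gamma(α2, β),   β = β1, δ = β2/β1,
X1 | R ~ Poisson(R0 + R1),        X2 | R ~ Poisson(δ·(R0 + R2)),
```

so that marginally `Xi ~ NB(α0 + αi, 1/(βi + 1))` and the latent
("BNB") correlation is

```
ρ = α0 √(β1 β2) / √((α0+α1)(α0+α2)(β1+1)(β2+1))  ∈  [0, 1).
```

The observed pair `(Y1, Y2)` masks the latent pair with zeros by a
four-category multinomial `(π1, π2, π3, π4)`: both observed / only the
first / only the second / neither. Margin 1 is therefore masked with
probability `π3 + π4`, margin 2 with `π2 + π4`. All nine parameters are
estimated by maximum likelihood, and the headline estimator **ρ_BZINB**
applies the formula above to the fitted latent component — an estimate
of the underlying association, free of the zero masking. (A "naive"
correlation of the masked pair, involving all nine parameters, is also
provided for comparison.)

On top of the estimator the package provides:

* pairwise correlation matrices within one omics layer or across two
  (`corr_matrix`, or the sklearn-style `PairwiseCorrelation`),
* correlation affinities + normalized-Laplacian spectral clustering for
  module (cluster) identification, eigengap model selection, a
  mode-matching accuracy procedure and the Adjusted Rand Index
  (`SpectralModules`, `match_clusters`, `adjusted_rand_index`),
* thresholded network construction with per-group comparison and
  SIF/GraphML/TSV export for Cytoscape (`build_network`,
  `export_network`),
* marginal goodness-of-fit screens (zero-inflated Poisson / NB /
  lognormal, Kolmogorov–Smirnov on nonzero counts) (`gof_summary`),
* simulators for every evaluation design: zero-inflated bivariate
  lognormal pairs, BZINB pairs from preset scenarios, baseline
  species-table generation and semi-parametric planted-cluster crafting
  (`simulate` module).

## Worked example

Simulate a heavily masked pair with known latent correlation 0.5 and
compare estimators:

```python
import numpy as np
from bzinbnet import get_bzinb_preset, simulate_bzinb_pair, fit_bzinb, spearman, pearson

params = get_bzinb_preset("bzinb_b", rho=0.5)   # balanced-high masking
y1, y2 = simulate_bzinb_pair(params, n=300, seed=1)
print("zeros:", (y1 == 0).sum(), (y2 == 0).sum())

fit = fit_bzinb(y1, y2)
print(f"rho_BZINB = {fit.rho:.3f}   (true 0.5)")
print(f"pi_hat    = {np.round(fit.params.pi, 3)}")
print(f"spearman  = {spearman(y1, y2):.3f}")
print(f"pearson   = {pearson(y1, y2):.3f}")
```

prints

```
zeros: 221 248
rho_BZINB = 0.546   (true 0.5)
pi_hat    = [0.083 0.18  0.09  0.647]
spearman  = 0.229
pearson   = 0.215
```

With ~75% of each margin masked, the rank and product-moment
correlations collapse to ~0.2 while the model-based estimate recovers
the latent 0.5 (the fitted masking probabilities are close to the
generating `π = (0.1, 0.2, 0.1, 0.6)`).

A command-line pipeline mirrors the library
(`bzinbnet simulate | fit | corr | benchmark | cluster | network | gof`);
every output file carries a provenance header, and re-runs with the same
seed are byte-identical.

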