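# ivscape

Tools for asking whether the large *intraspecific variability* (IV) seen in
tree census data reflects intrinsic differences among conspecific
individuals, or the projection of a high-dimensional, spatially structured
environment onto the few covariates we actually measure.

The package is aimed at community ecologists and forest biometricians
working with multi-census inventory or trial data (tree id, species,
coordinates, census date, DBH). It provides four connected pieces:

1. **Virtual landscape experiment** (`ivscape.landscape`). An individual
   attribute is generated *deterministically* from `N` spatially
   autocorrelated environmental dimensions on a `C x C` grid:

   ```
   ln Y_ijt = β0_j + β1_j ln X1_ijt + β2_j X2_ijt + … + βN_j XN_ijt
   ```

   Conspecific individuals are exact clones; all within-species variation
   comes from where and when each individual grows. Analyzing the same data
   while observing only `X1` with the mixed model

   ```
   ln Y_ijt = β′0_j + b0_i + β′1_j ln X1_ijt + ε_ijt,
   b0_i ~ N(0, V_bj),  ε_ijt ~ N(0, V_j)
   ```

   yields large individual-effect variances `V_bj` — apparent IV that is
   pure unobserved environment.

2. **Hierarchical growth models** (`ivscape.hier`). Gaussian mixed models
   with crossed random intercepts, sampled by an exact conjugate blocked
   Gibbs scheme (Normal(0,1) priors on means, half-Student-t(3, 0, 2.5) on
   standard deviations via their inverse-gamma scale-mixture
   representation). Includes the clonal-trial model
   `ln(G+1) = β0 + b_block + b_genotype + b_date + b_tree + β1 z(ln D) + β2 z(ln C) + ε`
   and the forest model
   `ln(G+2) = β0 + b_species + b_tree + β1 z(ln D) + ε`, plus variance
   partitioning, R-hat/ESS convergence checks and posterior-predictive
   envelopes.

3. **Census processing** (`ivscape.growth`). Annualized growth `ΔDBH/Δt`
   (mm/year), endpoint-based mean individual growth, the standard record
   filters (growth outside [−2, 100] mm/year, minimum DBH, unidentified
   species, singletons), Moore-neighbourhood basal-area competition, and
   invertible log-shift-scale transforms.

4. **Spatial diagnostics** (`ivscape.spatial`). Per-species Moran's *I*
   screen (binary same-plot weights within 100 m; exact permutation
   p-values at small n), semivariance defined as the plain mean squared
   pairwise difference, binned semivariograms, and a per-species
   comparison of conspecific vs heterospecific squared growth differences
   using a rank statistic whose null distribution is obtained by permuting
   species labels over trees.

`ivscape.synth` generates desk-scale synthetic datasets with known truth —
a clonal trial (fully crossed blocks x genotypes) and a multi-species
forest inventory whose individual effects are either responses to latent
spatially autocorrelated fields (`iv_mode="environmental"`) or i.i.d.
draws of identical marginal variance (`iv_mode="unstructured"`) — so every
stage is testable without external data.

## Worked example

Partition the growth variance of a clonal *Eucalyptus* trial among its
random effects, from the fitted variance components:

```python
>>> import ivscape as iv
>>> part = iv.partition_variance({"individual": 0.23, "block": 0.06,
...                               "genetic": 0.13, "temporal": 1.3,
...                               "residual": 0.51})
>>> part.percent
{'individual': 10.31, 'block': 2.69, 'genetic': 5.83, 'temporal': 58.3, 'residual': 22.87}
```

Even with genetics controlled (clones) and a homogeneous site, the
individual share (10.31%) is nearly twice the genetic share (5.83%):
conspecific individuals differ for non-genetic, micro-environmental
reasons.

Run one realisation of the virtual experiment (grid 100 x 100, 10
environmental dimensions, 2 species x 100 clones, 2 dates):

```python
>>> from ivscape.experiments import virtual_experiment_metrics
>>> m = virtual_experiment_metrics(seed=11)
>>> round(m["vbj_mean_0"], 3), round(m["vbj_mean_1"], 3)
(0.7, 0.829)
>>> round(m["vbj_ratio_perfect_0"], 5), round(m["vbj_ratio_perfect_1"], 5)
(0.00378, 2e-05)
>>> m["moran_p_0"], m["moran_p_1"]
(0.007, 0.001)
>>> round(m["within_semivar_short"], 1), round(m["pooled_semivar_short"], 1)
(65.3, 80.1)
```

Reading: fitting only the observed covariate attributes substantial
variance to individual identity (`V_b1 = 0.70`, `V_b2 = 0.83`) although the
individuals are clones; observing all ten covariates collapses those
variances by 2–5 orders of magnitude (ratios ≪ 1); the attribute is
significantly spatially autocorrelated within both species (one-tailed
Moran p = 0.007 and 0.001); and at distances below the autocorrelation
range the within-species semivariance (65.3) sits below the pooled,
all-individuals semivariance (80.1) — conspecifics are locally more alike
than the community.

A shell pipeline over the same machinery:

```bash
ivscape synth forest --out census.csv --seed 1
ivscape prep-growth --census census.csv --out mean_growth.csv
ivscape spatial-screen --mean-growth mean_growth.csv --seed 1
ivscape semivar-compare --mean-growth mean_growth.csv --seed 1
```

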