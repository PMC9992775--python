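# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `ivscape`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Virtual landscape and the deterministic attribute model

**Random fields.** Each environmental dimension is a stationary, zero-mean,
unit-variance Gaussian random field with exponential covariance
`C(h) = exp(-h / r)` on a `C x C` cell grid, sampled exactly by circulant
embedding on a `2C x 2C` torus (negative embedding eigenvalues, which are
tiny for the exponential model, are clipped to zero). The exponential model
was chosen as the simplest stationary model with a single interpretable
range parameter `r` (in cell units). Dimension 1 is exponentiated, so `X1`
is a lognormal layer with strictly positive support and `ln X1` is Gaussian
— `X1` enters the attribute model through its logarithm while the other
dimensions enter linearly.

**Temporal change.** Some dimensions are static, some are redrawn
independently at each date. The default regenerates the *upper half* of the
dimensions (`{floor(N/2)+2 … N}`) and keeps `X1` and the lower unobserved
dimensions fixed. This choice is load-bearing: an individual random
intercept can only absorb a *persistent* individual deviation. If every
unobserved dimension were redrawn at each date, the unobserved contribution
to an individual's attribute would be serially independent across dates,
the true individual-effect variance would be essentially zero, and all
apparent IV would land in the residual. With a static unobserved component
the imperfect-knowledge model attributes it to `V_bj`, which is the
phenomenon of interest.

**Species responses.** `β_nj ~ N(0, coef_scale²)` i.i.d.; vectors are
redrawn in the (measure-zero) event of a tie. Default
`coef_scale = 0.3`, giving `Var(ln Y) ≈ (N+1) · 0.09 ≈ 1` at `N = 10` — a
plausible attribute spread. With one observed and nine unobserved
dimensions, the unobserved ones dominate `Var(ln Y)` for any common scale.
Much larger scales (e.g. 1.0) make `Y = exp(ln Y)` so heavy-tailed that
raw-scale spatial statistics are dominated by a handful of individuals;
that regime is numerically valid but scientifically uninformative.

**Geometry.** Individuals sit at cell centres `(col + 0.5, row + 0.5)` in
cell units, uniformly placed, immobile across dates; distances are planar
Euclidean.

## 2. Hierarchical models and the Gibbs sampler

All fitted models are Gaussian linear mixed models
`y = Xβ + Σ_k Z_k u_k + ε` with crossed random intercepts
`u_k ~ N(0, σ_k² I)` and `ε ~ N(0, σ² I)`:

- *Imperfect-knowledge model*: per species, `ln Y` on `ln X1` with an
  individual intercept (species-specific `V_bj`, `V_j`; no pooling across
  species, matching the species-specific variances in the model as
  written). Optional extra covariates give the fully observed benchmark.
- *Clonal-trial model*: `z(ln(G+1))` on `z(ln D)` and `z(ln(C+1))` with
  block, genotype, census-date and individual intercepts (pooled
  variances).
- *Forest model*: `z(ln(G+2))` on `z(ln D)` with species and individual
  intercepts; requires ≥ 2 species (the species variance is otherwise
  unidentifiable).

**Transforms.** "Log-transformed and scaled" is implemented as z-scoring
after the log-shift transform; the scaler (shift, mean, sd) is stored and
invertible. Variance components can be reported on the fitted
(standardized) scale or back-transformed to the log-response scale by
multiplying by the response-scaler variance — parameter-recovery checks
compare on the response scale. The 1 mm (clonal) and 2 mm (forest) shifts
keep logarithms of zero or mildly negative growth defined. The competition
index uses a 1 mm² shift for isolated trees.

**Priors.** Normal(0, 1) on each fixed effect; half-Student-t(3, 0, 2.5) on
every standard-deviation parameter (random-effect and residual). The
half-t is represented exactly as an inverse-gamma scale mixture
(σ² | a ~ IG(ν/2, ν/a), a ~ IG(1/2, 1/A²)), which makes every full
conditional conjugate.

**Sampler.** Blocked Gibbs: fixed effects jointly (Cholesky of the
posterior precision), each random-effect block vectorized per factor, then
the variance and mixing parameters. After each random-effect update an
exact extra Gibbs step is taken along the translation direction
`(β0 + d, u_k − d)`; this interweaving move leaves the posterior invariant
and removes the slow random walk between the intercept and the level means
that plain Gibbs exhibits. Defaults are 4 chains x 10,000 iterations,
5,000 warm-up, thinning 5; `McmcConfig.test_mode()` uses 2 chains x 2,000
(1,000 warm-up, no thinning) with identical priors. Chains are seeded by
spawning a `SeedSequence`, so results are reproducible and chain-parallel
safe.

**Diagnostics.** Split R-hat and bulk ESS per scalar parameter via arviz;
the default pass thresholds are R-hat ≤ 1.05 and ESS ≥ 400. Convergence
failures are reported, never silently accepted.

**Variance partition.** `percent_k = 100 · σ_k² / Σ σ²`, computed from
posterior-mean variance components (the convention that reproduces the
published percentage rows from their printed component estimates) and
reported at two decimals. A draw-wise partition is available through the
posterior draws themselves.

**Predictive envelope.** For each posterior draw the species' regression
line at `ln x1` is perturbed by a fresh individual effect `N(0, V_bj)`
(and by default a residual `N(0, V_j)`); the band is formed by quantiles
across draws. It therefore integrates parameter uncertainty and
individual-level IV, collapses when the variance draws are zero, and widens
monotonically in `V_bj`.

## 3. Census processing

- Annualized growth: `G = ΔDBH/Δt` per consecutive census pair, mm/year;
  `dbh_start` is the start-of-interval DBH. Zero or negative intervals
  raise an error naming the tree.
- Mean individual growth: `(DBH_last − DBH_first)/(t_last − t_first)`,
  endpoints only; single-measurement trees are excluded and counted.
- Filters, in order: growth bounds (keep `g_min ≤ G ≤ g_max`, strict
  removal — `G = −2` and `G = 100` exactly are retained), minimum
  start-of-interval DBH (default 100 mm; the minimum-DBH rule is applied to
  the interval start, a documented choice where either census could be
  meant), unidentified species (missing/empty names or "indet"-like
  labels), individuals with a single remaining observation, then species
  with a single remaining individual; applied once, not to a fixed point.
  The filter log conserves row counts by construction.
- Competition: sum of basal areas `π(DBH/2)²` over the ≤ 8 Moore
  neighbours on the planting grid, grouped by block (and census date when
  computed from growth records). Edge trees keep partial sums and are
  flagged rather than dropped.
- Units are mm, mm/year, mm² and decimal years throughout; the census
  reader warns when the DBH distribution looks like centimetres (median
  below 30).

## 4. Spatial statistics

**Semivariance.** The working definition is the plain mean of squared
pairwise differences over a pair set, *without* the conventional ½ factor
— this matches the definition used in the growth analyses the package
replicates; `classic=True` restores the ½. Every comparison in the package
is invariant to that factor. Under i.i.d. values the no-½ semivariogram is
flat at twice the variance.

**Moran's I.** `I = (n/S0) Σ w_ij z_i z_j / Σ z_i²` with binary weights
linking same-plot pairs within the radius (100 m default), not
row-standardized. The null mean `−1/(n−1)` and the randomization variance
(including the kurtosis term) are analytic. The one-tailed p-value for
positive autocorrelation is computed by Monte-Carlo permutation of the
values (999 permutations) for `n ≤ 600, and by the normal approximation
above that. Measured on exchangeable nulls at screen-realistic sizes
(n ≈ 40–150, binary distance weights), the normal approximation rejects at
0.065–0.08 at nominal 0.05; the permutation test restores exact
calibration, and at large n the normal approximation is both accurate and
orders of magnitude cheaper. `p_method="normal"` reproduces the classical
test everywhere.

**Species screen.** Per species (subsampled uniformly to 3,000 individuals
when more abundant), eligibility requires strictly more than 5 individuals
with at least one same-plot conspecific neighbour within the radius *and*
more than 5 conspecific pairs; ineligible species are flagged, not tested.
Summary percentages ("% species", "% individuals") use eligible species —
and the individuals of eligible species — as denominators; raw counts are
reported alongside so other denominators can be formed.

**Intra- vs inter-specific comparison.** For a focal species, the two
samples are squared mean-growth differences over conspecific pairs and
over focal–heterospecific pairs (same plot, within 100 m). The test
statistic is the difference in mean rank between the two pair classes,
ranks taken once over the pooled pair set — a Mann–Whitney-type rank
statistic. Its p-value is obtained by permuting species labels over trees
within plots (299 permutations; the table is subsampled to ≤ 150 focal and
≤ 400 other trees for tractability). This design choice matters: squared
differences sharing a tree are strongly dependent, so treating the pairs
as two independent samples (the textbook Mann–Whitney normal
approximation) is badly anti-conservative — measured type-I error 0.27 at
25 focal trees, rising with abundance to above 0.5. The label permutation
respects the dependence and is exactly calibrated under exchangeability.
The naive test remains available (`method="mannwhitney"`) for
comparability with analyses that used it. Classification: `intra<inter`
or `intra>inter` when p < α, by the sign of the rank statistic; reported
semivariances are descriptive means over the full pair sets. The
abundance control (`max_per_species`) thins the whole table to at most
that many individuals per species before any pairing.

## 5. Synthetic data generators

**Clonal trial.** Fully crossed design: every genotype planted as a square
plot (10 x 10 by default) in every block, at 2.449 m spacing (6 m² per
tree, i.e. 1,666 trees/ha); blocks are spatially disjoint. Growth is
generated on the scale the model fits:
`ln(G+1) = β0 + b_block + b_genotype + b_date + b_tree + β1 z_c(ln D) + β2 z_c(ln(C+1)) + ε`,
where `z_c` uses fixed reference constants (the fit re-standardizes
empirically; variance components are unaffected by that affine change).
DBH accumulates `G · Δt` between censuses, so annualized growth recomputed
from the census table equals the generated growth exactly, and the truth
record (all effects, residuals, competition and DBH states) closes the
generative loop. Default variance components (temporal 1.3 ≫ individual
0.23 > genotype 0.13 > block 0.06, residual 0.51, on the log scale) mirror
the relative magnitudes estimated from a real clonal trial; recovery
experiments set the individual variance to 0.26 = 2 x genotype to probe
the individual-vs-genotype contrast. Five censuses over six years from
~50 mm initial DBH.

**Forest inventory.** 2,700 trees of 15 species in 6 plots of
100 m x 100 m (≈ 450 trees/ha, a realistic density for a ≥ 100 mm DBH
tropical inventory; the trees-per-species ratio is in the range of real
50-ha-plot censuses), 6 censuses at 2-year intervals. Species abundances
follow a log-series rank-abundance curve (x = 0.95; `uniform` available).
Ten latent unit-variance fields with log-spaced ranges 30–150 m represent
environmental drivers from soil-scale to topographic-scale structure —
scales commensurate with the 100 m analysis radius; fields structured far
below the probe scale would be invisible to the protocol by construction.
Species response vectors are random *directions* with a common norm
(total environmental response variance 0.7 on the log scale for every
species), so:

- in `environmental` mode, a tree's individual effect is its species'
  response evaluated at its location — conspecific neighbours share it,
  heterospecific neighbours decorrelate through their different response
  directions;
- in `unstructured` mode, individual effects are i.i.d. normal with the
  *identical* per-species variance (the matched-variance contract holds
  exactly in the generative sense; empirical within-plot variances differ
  by spatial sampling noise, since a 100 m plot spans few correlation
  lengths of the broad fields).

Species baseline offsets default to zero (`species_effect_sd = 0`):
species differ through their response to the environment, not through
global means. This makes the unstructured mode a true exchangeable null
for both spatial diagnostics, so detection differences between modes
measure spatial structure and nothing else. Growth links through
`ln(G+2)`; DBH accumulates between censuses; records below the 100 mm
observation floor are censored from the output as a real inventory would
not measure them.

**What the generators do not emulate.** No mortality, recruitment or
dispersal-limited conspecific aggregation; no measurement error; no
temporal environmental change in the forest generator (fields are static,
appropriate for mean-growth analyses); competition only in the clonal
trial. Passing tests therefore demonstrate the statistical machinery under
clean conditions, not robustness to demographic turnover or observation
noise in real inventories.

## 6. Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the study designs: the
virtual experiment at `C = 100`, 100 individuals per species, `J = 2`,
`N = 10`, `T = 2` with 2 chains x 2,000 iterations; clonal recovery at 3
blocks x 5 genotypes x 25 trees x 4 censuses (1,125 growth records, 2
chains x 4,000 thinned by 2); detection pipelines at the generator
defaults above. Because a single landscape or trial realisation carries
design-level randomness (2 response vectors, 5 genotype effects), headline
quantities are reported as medians over three replicate realisations.

Degenerate inputs raise errors rather than warnings: constant values in
`log_shift_scale` and `morans_i`, all-zero weights, all-zero variance
partitions, empty pair sets, empty prediction grids, single-chain
diagnostics. Posterior medians (not means) order variance components with
few levels, whose posteriors are strongly right-skewed. Ties in the rank
statistic use midranks. Distance binning is right-open except the last
bin, which includes its upper edge.

## 7. Known limitations

- The Gibbs sampler covers Gaussian likelihoods with crossed random
  intercepts — exactly the model family used here — not random slopes or
  non-Gaussian responses.
- The permutation comparison's subsampling caps (150 focal / 400 other
  trees) trade a little power for bounded cost on abundant species.
- The Moran screen's binary-weight, 100 m protocol has low power for
  species with few individuals; ineligible and non-significant rare
  species are expected even under strong environmental structure (the
  per-species results table carries abundance so this can be inspected).
- Variance components with very few levels (3 blocks, 3–4 dates) have
  heavy-tailed posteriors; their posterior means can sit far above the
  truth while the posterior sd is correspondingly large. This is a
  property of the inference problem, not of the sampler.
- The no-½ semivariance convention makes curve *levels* twice the
  classical ones; shapes and all comparisons are unaffected.
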