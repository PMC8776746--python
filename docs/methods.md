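# Methods

`stresspan` implements a landscape-pangenomics inference chain: from a strain
x gene copy-count matrix sampled along environmental gradients to per-gene
stress-response statistics, trait-based predictions of gene loss, selection
signatures, population differentiation and genome-position structure.  This
note records the models, the defaults, and the choices made where the design
was genuinely open.

## Study structure and the synthetic generator

The analysis assumes a nested sampling hierarchy: sites, soil samples within
sites, and bacterial strains isolated per soil sample.  The synthetic
generator emulates a field study of this shape with defaults of **20 sites x
3 soil samples x 6 strains (360 strains, 60 samples)** and **5000 genes**
(fraction core: 0.1).  Strains per sample are fixed at 6 for determinism.

Generator components (all driven by one seeded `numpy` generator, so a config
is bit-reproducible):

* **Environment.** Latent per-sample stress 4-vectors (acidity, aridity,
  heat, salinity) are multivariate normal with an equicorrelation of 0.3,
  mapped monotonically to raw variables: temperature (22 ± 4 °C per SD),
  rainfall (600 − 180 mm per SD, floored at 5 mm), pH (6.5 − 0.8 per SD) and
  salinity.  Salinity has a point mass at zero (default 30% of samples) and
  is log-linear in the latent above that, which exercises the ln(x + 0.01)
  transform in the standardization step.
* **Gene network.** A duplication–divergence growth process (new vertex
  copies a template's neighbourhood, each neighbour kept with probability
  0.6, template attached with probability 0.15) mixed with bridge vertices
  (probability 0.25, attached to two uniform vertices).  Duplication creates
  high-cosine-similarity twins; bridges create high-betweenness connectors,
  so both traits have spread (CV > 0.2 at 200+ genes).
* **Pangenome.** Accessory gene `g` is present in strain `s` with
  probability `logistic(alpha_g + sum_e beta_ge x_e(sample) + u_site +
  u_sample)`; `alpha_g ~ U(−1, 1)`; random-intercept SDs 0.3 (logit scale).
  Stress slopes follow a spike-and-slab: each accessory gene is
  stress-responsive with probability 0.5 (most genes in real pangenomes show
  no environmental occurrence signal — the empirical z histogram is massed
  near zero); non-responsive genes have all four slopes exactly 0, and
  responsive genes get `beta_ge = −0.5 + (−0.5)·cos*_g + 0.3·btw*_g +
  (−0.5)·dup*_g + N(0, 0.3)`, with starred traits standardized across genes.
  The −0.5 baseline on the responsive half plants pervasive gene loss along
  all four gradients at a *fitted* aggregate richness slope of ≈ −0.05 to
  −0.065 log units per SD (a 5–6.5% per-SD gene loss, the scale a field
  study of this design reports; note the fitted global slope is smaller than
  the instantaneous x = 0 derivative because strong-loss genes saturate out
  and gain genes grow); the trait weights plant the redundancy-is-lost /
  betweenness-is-retained pattern.  Copy counts of present genes are 1 + Poisson with a per-gene
  planted duplication rate, so the measured duplication trait matches the
  planted one in expectation.
* **SNPs.** Per soil sample, a Balding–Nichols model: locus ancestral
  frequency p0 ~ U(0.1, 0.9); sample frequency ~ Beta(p0(1−F)/F,
  (1−p0)(1−F)/F) with `F(sample) = logistic(logit(0.1) + 0.5·(heat +
  salinity)/2)`; haploid genotypes are Bernoulli draws.  Differentiation
  therefore rises with heat and salinity only.
* **dN/dS summaries.** Per gene, the proportion of codons under credible
  purifying selection is Beta-distributed with category means 0.80 (loss),
  0.60 (neutral), 0.75 (gain) at precision 20; the any-positive-codon flag is
  Bernoulli at 0.15 for loss and 0.05 otherwise.  Per soil sample, the mean
  core-gene purifying proportion declines on the logit scale with heat and
  salinity (−0.4 per SD from a baseline of 0.97, precision 300).
* **Genome map.** An 8 Mbp circular chromosome with a planted retention
  hotspot on [0, 850 kb): core genes and weakly-responding accessory genes
  (|planted response| below the accessory median) are placed inside it with
  5x enrichment; everything else is uniform.  Coordinates are 0-based,
  half-open; strand is ignored.

What the generator does **not** emulate: the empirical gene-frequency
spectrum of real pangenomes (it matches structure, not the spectrum),
linkage among SNP loci, phylogenetic relatedness among strains, spatial
autocorrelation between neighbouring sites, and annotation error.  Passing
recovery tests therefore demonstrates that the estimators are correct and
calibrated under the assumed models, not that those models capture every
feature of field data.

## Stress standardization

Each raw environment variable is standardized to mean 0, SD 1 across the 60
soil samples (sample SD, n−1), after ln(x + 0.01) for salinity; pH and
rainfall are negated after standardization so that **higher always means more
stressful** (acidity, aridity).  Standardization is at the soil-sample level
because stress is a sample property.

## Pangenome summaries

Genes are labelled **core** at presence frequency >= 0.99, **singleton** when
present in exactly one strain, **accessory** otherwise.  Before richness and
occurrence analyses, singletons and genes present in *every* strain are
removed: both carry no information about between-strain variation.  The
ubiquity filter (100%) is deliberately distinct from the 99% core label; both
thresholds are configurable.  Gene richness is the per-strain count of
distinct genes after filtering; pangenome diversity is the per-soil-sample
union (not sum) of member gene sets.

## Mixed models

Richness and diversity are counts and use a negative-binomial (NB2,
variance mu + alpha mu^2, log link) GLMM; per-gene occurrence uses a binomial
(logit) GLMM.  All four standardized stresses enter simultaneously, so each
coefficient is adjusted for collinearity among gradients.  Random intercepts:
site and soil sample for strain-level models; site only for the
sample-level diversity model.

Fitting is a purpose-built Laplace implementation: for fixed variance
parameters the joint mode of fixed effects and random intercepts is found by
penalized Fisher scoring with step halving (the Hessian is assembled in
O(n p^2 + q) using the grouped indicator structure); the variance parameters
(and NB dispersion) maximize the Laplace-approximate marginal likelihood via
Nelder-Mead on the log scale.  Fixed-effect SEs come from the fixed-effect
block of the inverse joint Hessian; p-values use a t reference with
between-cluster degrees of freedom at the finest grouping level (covariates
are constant within soil samples), the standard finite-sample correction to
the anti-conservative normal Wald test — empirically calibrated to
0.05 ± 0.03 per coefficient under the generator's null at the study scale
(normal Wald, including lme4's, reaches ~0.08–0.11 on unfavourable designs).  With no grouping factors the same machinery is an ordinary
GLM, which matches `statsmodels` to ~1e-6; variance parameters can also be
pinned (e.g. at zero) to check this limit explicitly.

Per-gene models use a three-tier strategy: a cheap fixed-effects logistic fit
doubles as a (quasi-)separation screen (runaway coefficients |b| > 12 flag
`separation`, z undefined); otherwise the full GLMM is fitted (the variance
search warm-starts from the previous gene, 20 simplex evaluations — the
per-stress z-scores are insensitive to variance-parameter precision well
below this); if it fails, the GLM result is reported with status
`no_random_effects_fallback`.  The headline statistic is **z = coefficient /
SE** per stress: negative z means the gene is more likely absent under high
stress.

## Trait meta-regression and loss weighting

Betweenness is unnormalized Brandes shortest-path centrality (scale is
immaterial: traits are standardized before regression).  Mean cosine
similarity of a gene is the average, over **all** other network vertices
(zeros across components included; per-component averaging available), of
`|N(u) ∩ N(v)| / sqrt(deg u · deg v)` on self-exclusive adjacency rows,
computed sparsely.  Duplication level is the mean copy count among carrying
strains (the count−1 convention is available).

The meta-regression is OLS of the long-format z table on stress type (4
levels, no global intercept, so per-stress mean z is read off directly) plus
stress x trait interactions, with HC1 heteroskedasticity-robust SEs because
per-gene z variances are heterogeneous.  Gene z-scores enter untransformed
(winsorization is available but off by default).

Genes with any z below −2 are embedded in a regular tetrahedron whose
vertices are the four stresses, with barycentric weights proportional to the
rectified negative z (`max(−z, 0)`, normalized to sum 1) — scale-invariant in
z by construction.  A gene is "exclusively lost" under the stress holding at
least 0.75 of its weight; otherwise "shared".  The specificity summary
chi-square-tests the exclusive counts against uniformity.

## Selection signatures

Gene-level: genes are stratified by their z extremes (decrease: any z < −2;
increase: any z > +2 and not decrease; none: all |z| < 0.5 — the bands are
package defaults, configurable), subsampled to 1000 per category.  The
purifying-codon proportion is modelled by beta regression (logit mean link,
common precision; `statsmodels` BetaModel) after the boundary squeeze
(y(n−1)+0.5)/n; the any-positive flag by logistic regression with a
separation check per category.  Population-level: the per-sample mean
purifying proportion over core genes is beta-regressed on the four stresses
simultaneously.

## Fst

The estimator is Hudson-style for haploid data: per locus, within diversity
`Hw = 2p(1−p)·n/(n−1)` averaged over the two populations and between
diversity `Hb = pa(1−pb) + pb(1−pa)`, combined across loci as a ratio of
averages, `F = 1 − mean(Hw)/mean(Hb)`; loci monomorphic in both populations
drop out.  Negative pair estimates are retained (unbiased for regression).
This recovers the planted Balding–Nichols parameter to within ±0.05 at 2000
loci and gives exactly 1 for a fixed difference.

Soil samples are grouped into 5 stress bins by Ward clustering in the 4-D
stress space with greedy rebalancing to equal sizes, and Fst is computed only
within bins.  The Fst ~ mean-pair-stress regression is OLS; inference is by
permutation of whole stress 4-vectors across samples.  Two schemes are
implemented: the preferred one re-runs the *entire* procedure (binning, pair
formation, regression) per permutation — exact under sample exchangeability,
measured type-I ≈ [0.040, 0.050, 0.035, 0.055] per stress over 200 generator
nulls — because the within-bin pair set itself depends on the observed
stress, re-using it while permuting stress is mildly anti-conservative (up
to ~0.11 for the skewed salinity axis).  The cheaper fixed-pair scheme
remains available when only a pair table exists.

## Circular-genome smoothing

Per-gene z-scores (or traits) on the circular chromosome are smoothed by GP
regression with a Matern-3/2 kernel on the geodesic circular distance plus a
white-noise nugget.  Hyperparameters (range, marginal SD, noise SD) maximize
the marginal likelihood; the range is bounded in [L/2000, L/6] — the upper
bound, with jitter, protects positive-definiteness of the geodesic Matern on
the circle — and a failed search falls back to range = L/20 with a flag.
Tracks are evaluated on a regular grid (default step L/2000) whose endpoints
0 and L coincide; predictions are exactly periodic and rotation-equivariant.
When more than 1200 genes are mapped, a deterministic position-stratified
subsample of 1200 trains the GP (cubic cost).  The 95% band is the GP
predictive interval of the latent mean — a frequentist analogue of a
posterior credible band, equivalent only qualitatively.

**Retention hotspots** are maximal grid intervals where |mean| falls below
half of the track-wide median level |median| and the band excludes the
median — regions whose smoothed response shrinks toward zero regardless of
the predominant sign; intervals may wrap the origin.  Core-gene density is a
wrapped-Gaussian KDE (default bandwidth 50 kb) integrating to the gene count.
The co-location statistic is the grid Jaccard between hotspot intervals and
top-decile core-density regions; its null shuffles core-gene positions
uniformly (the density side is recomputed per permutation; the GP is not
refitted, which keeps the null purely positional).

## Pipeline

`stresspan run --config cfg.yaml` executes environment → pangenome →
occurrence → traits → loss → selection → Fst → smoothing, writing each
stage's tables as TSV plus `report.json` with a per-stress summary (richness
trend, trait interactions, loss specificity, dN/dS slope, Fst trend,
hotspot/core overlap).  The per-gene occurrence stage is cached on a content
hash of its inputs.  With the seed fixed, the report's analytical content is
bit-identical across reruns (wall-clock timings are reported separately).
All stochastic steps (simulation, stratification subsampling, permutations)
derive their seeds from the single pipeline seed.

Problem sizes used by the test-suite recovery checks (chosen as the package's
standard verification scales): 50 replicates for sign-recovery checks, 200
replicates for type-I calibration, 1000 genes for per-gene z validity, 5000
genes for the trait meta-regression, 2000 SNP loci for Fst recovery, 1000
mapped genes for hotspot recovery.

## Known limitations

* Wald-normal p-values from the Laplace GLMM are approximate; with 20 sites
  they are adequately calibrated here, but very small cluster counts would
  need a t reference or profile likelihood.
* The per-gene fallback hierarchy reports but does not model selection bias
  from excluding separated genes; strongly environment-restricted genes are
  exactly the ones most likely flagged.
* The GP band ignores hyperparameter uncertainty.
* Beta-regression precision is held common across categories/samples.
* The trait meta-regression treats per-gene z as homoskedastic up to robust
  SEs; a weighted or errors-in-variables version would use the per-gene SEs.
* At the generator's default conditions the end-to-end run typically calls
  *no* retention hotspots: with spike-and-slab responsiveness the planted
  hotspot changes gene *composition* (a ~0.4 z-unit contrast) while the
  per-gene z noise SD is ~2.7, so the credible band cannot exclude the track
  median.  The smoother's recovery is validated on its stated strong-contrast
  configuration (N(−2, 0.5²) background vs N(0, 0.5²) window); detecting the
  composition-driven hotspot end-to-end would need many more mapped genes or
  a mean-shift (not composition) planting.
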