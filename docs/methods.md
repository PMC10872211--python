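# Methods

This note documents the models, algorithms, defaults, and numerical
choices behind `wildg`, and what the synthetic-data generator does and
does not emulate.

## Pedigree relatedness

Pedigrees are validated (unique ids, acyclicity, parents present) and
topologically sorted with a deterministic tie-break (cohort, then id).
Individuals that appear only as parents are auto-inserted as founders of
the earliest cohort with a logged warning, since field pedigrees routinely
omit such rows.  Unknown parents contribute zero relationship — immigrants
are treated simply as founders; genetic groups are not modelled.

The dense numerator relationship matrix A follows the tabular recursion
a_ij = (a_j,sire + a_j,dam)/2, a_ii = 1 + a_sire,dam/2, guarded by a
configurable dimension cap (default 20,000).  Inbreeding F is computed by
memoized coancestry recursion without forming A.  The sparse A⁻¹ uses
Henderson's rules with inbreeding: the Mendelian-sampling variance is
d = ½ − ¼(F_s + F_d) (both parents known), ¾ − ¼F_p (one known), or 1
(founder).  Tests verify A against an independent coancestry recursion
(1e-12) and against gene-dropping Monte Carlo (10⁵ allele drops, ±0.02),
and A·A⁻¹ = I to 1e-8.

## Animal model

Per population and trait group, phenotypes follow

y_r = x_r'β + a_i(r) + pe_i(r) + u_year(r) + w_obs(r) + e_r

with a ~ N(0, A ⊗ G), pe ~ N(0, I ⊗ PE), year ~ N(0, I ⊗ Y), observer
effects with independent per-trait variances (morphology only), and
e ~ N(0, I ⊗ R).  Fixed effects: intercept, age (centered quadratic or
age-class factor), and for morphology sex, sex×age, and measurement date
(centered cubic or period factor); treatment contrasts with the first
level as reference.  Missing quantitative covariates are column-mean
filled ("average data augmentation") or the record dropped, per flag;
missing categorical covariates always drop the record, since no average
exists for a factor.  Missing trait values within a record are imputed by
conditional-normal data augmentation inside the sampler.

Sampling is single-site Gibbs: fixed effects as one matrix-normal block
(exact, using the Cholesky of X'X), each individual's 3-vector of breeding
values conditional on its pedigree neighbours through the sparse A⁻¹ rows,
PE/year/observer effects per entity, then inverse-Wishart draws for G
(scale ν₀V₀ + a'A⁻¹a, df ν₀ + n), PE, Y, R, and scaled-inverse-χ²
draws for observer variances.  Priors are slightly informative:
V₀ = diag(phenotypic variance / number of random factors, residual
included), ν₀ = number of traits.  The kernel is numba-compiled and costs
O(nonzeros + records) per sweep (~0.7 ms per iteration at ~800
individuals); chains are bit-reproducible given (data, settings, seed).

Chain profiles: `full` (2×10⁵ burn-in, 10⁶ iterations, thin 10³ → 1,000
retained) mirrors full-scale practice; `desk` (5×10³/5×10⁴/50) is the
default for synthetic work; `smoke` (10³/6×10³/20) for quick checks.
Convergence diagnostics report lag-1 autocorrelation (pass: all |ρ₁| <
0.1) and an initial-positive-sequence effective sample size for every
(co)variance parameter.  Longer chains are a manual re-run; no automatic
extension is attempted.

Zero-truncation of fledging success is a data filter (zero records
removed upstream), and all traits are then modelled as Gaussian.

## Standardization

V̄a_t is estimated by the resampling route: for every posterior G draw of
every population, 1,000 zero-mean multivariate-normal deviates are drawn
and pooled; V̄a_t is the variance of coordinate t of the pool.  (The
analytic limit — the equal-weight mean over populations of posterior-mean
Va — is the test oracle.)  Populations are weighted equally.  Every G
draw is then divided elementwise by √(V̄a_i·V̄a_j): correlations are
preserved draw by draw, cross-population variance ratios are untouched,
and the result is dimensionless.  Mean-standardized evolvability is
deliberately not offered: laying date is an interval-scale trait with no
natural mean.

## Covariance tensor

Symmetric n×n matrices are vectorized diagonals-first with off-diagonals
scaled by √2 so Euclidean and Frobenius inner products coincide.  S is
the covariance (denominator m−1) of the m populations' posterior-mean
vectorized standardized Gs.  Eigen-decomposition of S yields eigenvalues
α_i and orthonormal eigentensors E_i; posterior uncertainty in the
fraction of variance along each E_i is propagated by rebuilding S_t from
draw t of every population and projecting it through the *fixed*
eigentensors (the per-draw eigendecomposition alternative is available;
which the original analyses used is not stated).  Eigentensor signs are
fixed by making the largest-magnitude loading of the leading trait
eigenvector positive.  Coordinates are Frobenius inner products
⟨G_kt, E_i⟩; tensor distances are Euclidean in the first two coordinates.
Posterior modes use a Gaussian KDE with Silverman bandwidth evaluated at
the sample points; intervals are central 50/75/95% quantiles.

Eigentensor null p-values are empirical: the proportion of null-replicate
G sets whose rank-i eigenvalue fraction is at least the observed one
(reported as < 1/n_null when zero).

## Geometry

g_max is the leading eigenvector per draw, sign-aligned to the
posterior-mean leading eigenvector to avoid sign-flip artefacts;
matrices whose top two posterior-mean eigenvalues differ by < 1e-8 are
flagged degenerate rather than assigned an arbitrary direction.  Angles
use the arccosine of the absolute dot product (range 0–90°).  Orientation
divergence between two populations is supported when the posterior median
between-population angle exceeds the 95th percentile of both populations'
within-posterior angle distributions (angles between independent draw
pairs of one posterior).

## Null model

Per replicate, one posterior draw index is used coherently for founder G,
fixed effects, and non-genetic covariance matrices.  Founder breeding
values are drawn per population from that draw's G, pooled, permuted, and
reassigned across populations (the pooled multiset is exactly preserved);
the "randomized G" of a population is the sample covariance of its
post-shuffle founder values (a refit on founders alone cannot separate
components, so the sample covariance is used).  Non-founder breeding
values follow the infinitesimal recursion: mean = mean of known parents'
values, covariance = ½·G_rand·(1 − F̄) plus ¼·G_rand per unknown parent.
Phenotypes are recomposed as design × fixed-effect draw + simulated BV +
fresh PE/year/observer/residual draws from the same posterior draw, and
refitted with the identical model.  Full scale is 1,000 replicates with
200 retained samples per null fit; the desk default is 50/100, and the
calibration tests run 20/100 with shortened chains.  Null replicate G
sets are standardized by their own V̄a, mirroring the observed set.

## Climatic niche

Eight temperature variables (annual mean, diurnal range, seasonality, max
of warmest month, min of coldest month, annual range, warmest- and
coldest-quarter means) over distribution-masked cells are centered and
scaled to unit variance before PCA (they mix °C levels, ranges, and a
dispersion measure; unscaled PCA is available by flag).  Axis signs make
the largest-magnitude loading positive.  The niche center is the origin
of the PC space (the multivariate masked-cell mean); site climate is the
nearest grid cell (raster-extraction semantics, no interpolation);
distances are Euclidean in (PC1, PC2).  Geographic distances are great
circles on a spherical earth (R = 6,371 km) and serve only to report the
niche/geography correlation.

## Association statistics

Mantel tests correlate off-diagonal upper triangles, permuting rows and
columns of the second matrix jointly; p = (1 + #{r_perm ≥ r}) / (n_perm +
1), one-sided greater by default (two-sided by flag), default 9,999
permutations, seedable.  The randomized distance regression removes
inter-pair dependence by independently permuting each pair's values
across the replicate axis (each pair's marginal multiset is exactly
preserved), then fits one OLS slope per replicate over the m(m−1)/2
pairs; significance is the 95% empirical interval excluding zero.  The
data-vs-null comparison reports the proportion of randomly paired draws
where the null slope is at least the data slope.  Posterior scalars
(volume, a standardized Va) are regressed on a per-population gradient
draw by draw.  Leave-out reruns rebuild the tensor upstream on the
reduced population set.

## Synthetic-data generator

The generator emulates the *statistical* structure the analysis assumes,
not demography: overlapping generations from monogamous annual pairing
with Poisson recruitment (default 1 recruit per pair), adult survival 0.5,
carrying capacity equal to the founder count (default 200), 25 years of
monitoring, and immigrant founders arriving in any year at 5% of capacity
per year — values chosen to give pedigrees whose founder fraction,
lifespan distribution, and record counts resemble nest-box passerine
studies.  Sexes are assigned consistently with pedigree roles.  Breeding
values follow the infinitesimal model (founders N(0, G); offspring around
the parental mean with segregation covariance ½G(1−F̄), an unknown parent
contributing ¼G).  Morphological traits (tarsus, wing, mass; h² = 0.4)
are recorded on both sexes with repeated measures and an observer effect;
life-history traits (laying date, clutch size, fledging success;
h² = 0.25, genetic correlation 0.7 between clutch size and fledging
success) on females once per breeding year.  All architectures default to
unit phenotypic variance so components are directly interpretable as
proportions.

The climate field mixes three spatially smoothed latent surfaces (a
dominant south–north temperature level, a continentality/variability
field, and a nuisance field) through a fixed loading matrix into the
eight variables, yielding a dominant first PCA axis by construction.
Populations are placed at even quantiles of the niche PC1 score while
held near the median PC2 — a transect along the dominant gradient.

The gradient parameter δ plants a climate-aligned life-history G
gradient: along the population's (centered, scaled) PC1 score z, variance
drifts log-linearly along the leading eigenvector and the laying-date
axis (factor e^{0.45·δ·z}, keeping G positive definite at the cold end),
and the matrix rotates in the g_max–laying-date plane by
45°·tanh(δ·z), so size, shape, and orientation all change monotonically
with climate.  δ = 0 gives one shared G everywhere; δ = 3 is the
"strong gradient" setting used in the power analyses.  What passing tests
on these data do *not* show: robustness to extra-pair paternity (social
pedigrees treated as exact), non-Gaussian trait distributions, selection
or G×E within the simulation, or spatial demography — none of which the
generator emulates.

## Test and acceptance profiles

Problem sizes in the test suite are chosen so the whole battery runs on
one CPU in well under half an hour: parameter recovery uses 8 replicate
populations of ~600 individuals with 10⁴-iteration chains; the null-model
calibration uses ten whole-experiment replicates of a 5-population study
(~450 individuals each, 20 null replicates, 2×10³-iteration chains); the
power analysis uses ten replicates of a larger 5-population study (~2,300
individuals each, δ = 3, 5 null replicates).  These are scaled-down
versions of the same procedures the `full` profile runs at full size;
all thresholds are on calibration (type-I behaviour) and power
(majority-significant), not on matching any particular field estimate.

## Known limitations

- The Gibbs sampler is single-site over individuals; for very deep
  pedigrees with few records, mixing of breeding-value chains slows and
  longer thinning is needed (the diagnostics flag this).
- The observer term is diagonal (independent per-trait variances), not a
  full covariance matrix.
- The null model's retry logic re-draws a failed replicate up to three
  times; systematic failures (e.g., degenerate recomposed data) abort.
- Posterior modes from KDE are sample-evaluated; with < 3 draws the
  median is returned.
- The dense A path refuses pedigrees above the cap; A⁻¹ and the sampler
  have no such limit.
- Orientation comparisons are data-hungry: with a few hundred phenotyped
  individuals per population, the posterior spread of g_max directions is
  10–15°, which dominates per-draw pairwise angles; angle-vs-gradient
  regressions over the 10 pairs of a 5-population study then have limited
  power even for strong planted orientation gradients, and reliably
  detecting them needs either thousands of individuals per population or
  more populations.  The tensor-distance statistics do not share this
  weakness.
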