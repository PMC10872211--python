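# wildg

Multi-population **G-matrix** divergence analysis for wild pedigreed
populations.

Long-term monitoring studies of wild vertebrates (ringed birds at nest
boxes, for example) yield decades of phenotypes linked by a social
pedigree.  From such data the additive genetic variance–covariance matrix
**G** of a trait set can be estimated per population with an animal model,
and the question arises whether evolutionary potential — the size, shape,
and orientation of **G** — varies across a species' range, and whether that
variation tracks the climatic niche.  `wildg` implements the complete
analysis chain for that question, driven by a synthetic-data generator so
every stage is testable without access to restricted field data:

1. **Pedigree machinery** — validation, the numerator relationship matrix
   A (a_ij, with diag 1 + F), its sparse Henderson inverse, inbreeding
   coefficients F.
2. **Animal model** — Bayesian multivariate mixed model per population,
   partitioning phenotypic (co)variance into additive genetic (G),
   permanent environment (PE), year (Y), observer (Obs), and residual (R)
   components via a Gibbs sampler with slightly informative
   inverse-Wishart priors (scale = phenotypic variance / number of random
   factors, degree of belief = number of traits).
3. **Standardization** — all G posteriors divided elementwise by
   √(V̄a_i·V̄a_j), where V̄a is the interpopulation mean additive genetic
   variance per trait, making cross-population variance ratios unitless
   and comparable (a value above 1 = more variance than the species
   average).
4. **Covariance tensor** — the m populations' standardized G-matrices are
   vectorized (√2 off-diagonals) and the eigenstructure of their q×q
   covariance matrix S yields orthonormal *eigentensors*: matrix
   directions that maximize among-population variance, each decomposable
   into trait eigenvectors.
5. **Geometry** — g_max (leading eigenvector, the line of least
   resistance), eccentricity (λ₁/Σλ), volume (Σλ = trace), and
   posterior within-vs-between orientation divergence tests.
6. **Null model** — founder breeding values drawn from each population's
   posterior G, shuffled *across* populations, propagated down each
   pedigree under the infinitesimal model (segregation covariance
   ½·G_rand·(1−F̄)), recomposed into phenotypes with the original fixed
   and non-genetic effects, and refitted — simulating a single common G.
7. **Climatic niche** — PCA over eight temperature variables on
   distribution-masked grid cells; populations projected on (PC1, PC2);
   niche distances and distances to the niche center.
8. **Association** — Mantel tests, element-shuffled randomized distance
   regressions with 95% credible intervals on the slope, data-vs-null
   slope comparisons, posterior-scalar-vs-gradient regressions, and
   leave-out robustness reruns.

## Worked example

The numbered scripts under `analysis/` run the full demonstration study —
five populations on a synthetic European temperature gradient, a planted
climate-aligned life-history G gradient, morphology left gradient-free as
the negative control:

```bash
cd analysis
python 01_simulate_study.py
python 02_fit_animal_models.py
python 03_standardize_tensor.py
python 04_geometry.py
python 05_null_model.py
python 06_niche.py
python 07_associations.py
```

Output from `07_associations.py` (seed 20240915):

```
morphology:
  tensor distance ~ niche distance: Mantel r = 0.03 (p = 0.431); slope -0.002 [-0.042:0.046]
  g_max angle ~ niche distance: Mantel r = 0.41; slope 0.42 [-0.71:2.28]
  volume ~ center distance: slope -0.03 [-0.12:0.09]
  tarsus Va ~ niche PC1 (temperature axis): slope -0.00 [-0.03:0.02]
life_history:
  tensor distance ~ niche distance: Mantel r = 0.61 (p = 0.041); slope 0.534 [0.447:0.645] *
  g_max angle ~ niche distance: Mantel r = 0.80; slope 5.70 [1.50:10.88] *
  volume ~ center distance: slope 0.46 [0.32:0.60] *
  laying_date Va ~ niche PC1 (temperature axis): slope 0.27 [0.22:0.32] *
  null slope 0.006 [-0.096:0.105]; data > null at p = 0.000
  without ['pop3', 'pop1']: slope 0.579 [0.316:0.841]
```

Reading this: where a climate-aligned G gradient exists (life history),
tensor distances between standardized G-matrices increase with niche
distance (slope credible interval excludes 0), the association vanishes
under the founder-shuffling null (null slope ≈ 0; data slope beats it at
p = 0.000), g_max orientation diverges with climate, and laying-date
genetic variance tracks the temperature axis; where no gradient was
planted (morphology), every association is non-significant.  A `*` marks
a 95% credible interval excluding zero.  Earlier stages print the niche
PCA (PC1 63%, PC2 36% of climate variance), the eigentensor variance
fractions (life history E1 98%; morphology E1 74%, E2 16%), and the
eigentensor-1 null p-value (0.050 at 20 null replicates).

The library surface is importable directly (`wildg.pedigree`,
`wildg.animal_model`, `wildg.tensor`, ...); `wildg.workflow.run_pipeline`
wires the whole chain from a single `PipelineConfig` (YAML-loadable).

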