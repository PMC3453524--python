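# Methods

## Models

`gsmix` fits three mixed-model classes to a quantitative trait `y` recorded
on genotyped animals from full-sib families, by Gibbs sampling:

1. **Polygenic (animal model)**
   `y = mu + X1 b + X2 c + Z u + e`, with cage effects
   `c ~ N(0, I sigma2_c)`, polygenic breeding values `u ~ N(0, A sigma2_u)`
   (`A` the pedigree additive relationship matrix) and residuals
   `e ~ N(0, I sigma2_e)`.

2. **Genomic (multi-marker association model)**
   `y = mu + X1 b + X2 c + Q (a o s) + e`, where `Q` is the marker design
   matrix, `a` are base effects with a fixed `N(0, 1)` prior and `s` are
   non-negative per-marker scaling factors that carry all marker-level
   shrinkage. Under the non-mixture prior `s ~ TN>0(0, sigma2_g1)`
   (half-normal). Under the two-component mixture prior a marker belongs
   with probability `pi0 = 1 - pi1` to a near-null component
   `s ~ N(0, sigma2_g0)` and with probability `pi1` to the substantial
   component `s ~ TN>0(0, sigma2_g1)`. `sigma2_g0` is fixed at 1% of the
   phenotypic variance divided by the number of markers and is never
   sampled; `pi1` is a known constant of the run (standard settings: 100,
   70, 40, 10, 7.5, 5, 2.5%).

3. **Combined** — both genetic terms at once; the polygenic term absorbs
   genetic variation the markers cannot capture.

Because only the product `beta_j = s_j * a_j` enters the likelihood, the
`(s, a)` decomposition is not separately identified; every reported
quantity (genomic values, genomic variance, inclusion indicators) is a
function of `beta`, `delta` or `g = Q beta` only.

## Gibbs update cycle

All location parameters have normal full conditionals and are updated
single-site with residual updating (the residual vector always equals the
data minus every currently fitted term). Polygenic values use the sparse
`A^-1` built by Henderson's rules with the inbreeding adjustment, so one
sweep costs O(nnz(A^-1)).

The per-marker update is the heart of the sampler and is done as a joint
`(delta_j, s_j)` block with `s_j` integrated analytically out of the
component odds: with `lambda = w'w / sigma2_e` and `l = w'e_j / sigma2_e`
(`w = Q_j a_j`, `e_j` the residual with marker `j` removed), each
component's conditional posterior for `s` is `N(m_k, v_k)` with
`v_k = 1/(lambda + 1/sigma2_gk)`, `m_k = v_k l`, and the marginal
likelihood ratio includes the truncated-normal normalising factor
`2 Phi(m_1 / sqrt(v_1))` for the substantial component. The indicator is
drawn from these integrated odds, then `s_j` from its component full
conditional (normal, or truncated-at-zero normal), then the base effects
`a` single-site. An indicator update conditional on the current `s` mixes
far more slowly; the integrated form is what makes small-`pi1` mixtures
usable.

Variance components `sigma2_e, sigma2_c, sigma2_u, sigma2_g1` get
scaled-inverse-chi-square full conditionals with the flat-on-variance
improper prior (`nu = -2`, zero scale), the standard choice in
animal-breeding samplers, bounded below at 1e-10. `sigma2_g1` is updated
from the scaling factors currently in the substantial component and is
held at its current value when fewer than four markers are included (the
flat-prior draw is undefined below three degrees of freedom).

### Numerical choices

- Truncated-normal draws use the inverse-CDF method with Acklam's rational
  approximation to the normal quantile; truncations further than five SDs
  into the tail switch to Robert's exponential rejection sampler.
- Log of the normal CDF switches to the asymptotic tail expansion below
  `x = -8` to keep the component log-odds finite.
- Design columns are centred inside `fit()` for every encoding. Uncentred
  per-allele columns contain a constant component (reference + alternate
  counts = 2) that is confounded with the general mean; under the flat
  `sigma2_g1` prior that flat direction lets the scaling factors drift
  unboundedly. Centring removes it; for biallelic markers the centred
  per-allele and centred-dosage codings span the same space, and posterior
  mean genomic values agree between the two (tested).
- Chains are bit-reproducible for a given seed (a single internal RNG
  seeded once per chain).
- Default chain: 50,000 iterations, 10,000 burn-in, thinning 10. Tests and
  the acceptance script use much shorter chains with tolerances set by the
  measured Monte Carlo error at those lengths.

### Verification hooks

`fit()` exposes keyword-only switches used by the test suite and useful
for any verification work: `fix_variances` (hold any subset of variance
components at known values), `freeze_delta` (all markers substantial),
`freeze_s` (constant scaling, which reduces the marker layer exactly to
ridge regression with penalty `sigma2_e / s0^2`), and `likelihood=False`
(the chain then reproduces its own prior: `E[delta] = pi1`,
`E[s | delta=1] = sigma_g1 sqrt(2/pi)`). These switches select code paths
inside the same kernel, so they verify the production updates, not copies.

## Derived quantities

- **Genomic variance** `sigma2_a` of one posterior sample is the empirical
  variance across animals of `g = Q beta`, which expands to the sum of
  per-marker contributions plus all LD covariances weighted by the allele
  frequencies (equal to the quadratic form `beta' C beta` with `C` the
  empirical column covariance; asserted to 1e-10).
- **Phenotypic variance** per sample is the sum of that sample's
  components, so heritability draws `h2_u = sigma2_u / sigma2_p` and
  `h2_a = sigma2_a / sigma2_p` lie in [0, 1] by construction and satisfy
  `h2_u + h2_a + (sigma2_c + sigma2_e)/sigma2_p = 1` exactly.
- **Intervals** are central 95% posterior quantiles (not HPD): determinate
  given the draws and adequate for the unimodal posteriors seen here.
- **Marker evidence**: the posterior inclusion probability `p1_hat(j)` is
  the mean of `delta_j` over stored samples, clamped to
  `[1/(2S), 1 - 1/(2S)]` so the prior-to-posterior odds ratio
  `PPOR = (p1/(1-p1)) / (pi1/(1-pi1))` stays finite; evidence classes use
  strict thresholds (substantial > 3.2, strong > 10, decisive > 100,
  boundary values in the lower class).

## Cross-validation design

Only animals from families with at least two phenotyped members are
eligible for validation. Each replicate round splits the eligible animals
into five disjoint validation sets (1:5 validation:training) and the
procedure is repeated once, giving ten sets. *Within-family* mode
allocates each family's members round-robin across the five groups from a
random start, which guarantees at least one sib stays in training;
*between-family* mode assigns whole families greedily (largest first into
the currently smallest group, order shuffled by seed), and requires at
least ten multi-member families. Training fits mask validation phenotypes
as missing — a masked animal contributes no residual term but keeps its
polygenic value (linked through `A`) and genomic value (from genotypes),
which is exactly how validation animals are predicted. Masking is
verified to be equivalent to dropping the records.

Predictive ability is the Pearson correlation between the predicted
breeding value (`u`, `g` or `u+g` by model class) and the realized
observation, the phenotype minus the *training* fit's estimates of the
mean, fixed effects and covariates (cage and genetic terms stay in).
Using training-only corrections avoids leaking validation information;
an unseen factor level in validation raises an error.

## Synthetic populations

The generator emulates the statistical structure the models assume, not
any particular real dataset:

- **Pedigree**: three recorded generations — grandparents, parents, and
  one generation of phenotyped full-sib offspring (default 175 families,
  family sizes Poisson(11) truncated at 2). Families are unrelated in the
  recorded pedigree; relatedness beyond it lives in the genotypes.
- **Genotypes**: eight fully inbred founder strains (one haplotype each,
  alleles Bernoulli(0.5) per marker) are crossed and the population mates
  at random for 50 generations (default burn-in population 200 diploids)
  with Haldane recombination at 0.5 cM/Mb, which produces
  distance-dependent LD; recorded founders are drawn from matings of the
  final burn-in generation and alleles drop through the pedigree by
  meiosis, so Mendelian consistency is exact.
- **Trait**: `y = mu + sex + slope*covariate + cage + Q_qtl beta + u + e`
  with QTL effects drawn reflected-gamma (shape 0.4; few large, many
  small — a normal option exists) and rescaled so the realized genomic
  variance among phenotyped animals hits the target; the polygenic term
  flows down the pedigree by gene dropping (`u_child` = parent average +
  Mendelian deviation of variance `sigma2_u/2`), independent of the
  marker panel, so genomic and polygenic variance are separable by
  construction; cages are drawn per family (Poisson mean 3.1 cages per
  family) and never span families.

What the generator does **not** emulate: genotyping error, sex
chromosomes, selection or non-random mating in the recorded generations,
non-Gaussian residuals, dominance/epistasis, and real-data fixed-effect
structures richer than one factor plus one covariate. Passing tests
therefore show the machinery is correct under the model's own
assumptions; they do not certify performance on data violating them.

## Observed behaviour worth knowing

- With 175 unrelated families and cages nested inside families, the
  polygenic heritability estimator itself has a standard deviation near
  0.09 at `h2 = 0.5` (confirmed against REML on the exactly equivalent
  family+cage random-intercept model): single-dataset `h2_u` estimates
  0.37–0.68 at truth 0.5 are data realizations, not sampler error. The
  posterior tracks REML to ~0.02 throughout.
- Narrowing the mixture (`pi1` 100% → 2.5%) shrinks the posterior genomic
  variance monotonically, and evidence counts at a fixed PPOR threshold
  grow from moderate to small `pi1` (40% → 10%). At very small `pi1` with
  few, strong, well-separated simulated QTLs the expected number of
  included markers can fall below the number of detectable QTLs; LD
  partners then compete for inclusion and the count of markers past the
  threshold can dip by a few. Real traits with many small-effect loci do
  not hit this capacity bound.
- Between-family predictive ability of the polygenic model is ~0 on these
  synthetic populations because recorded families are unrelated — an
  accentuated version of the low between-family polygenic accuracy seen
  in real full-sib designs, and the reason the genomic model's
  between-family advantage is so visible here.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run populations of 18–175
families (≈200–2,000 phenotyped animals) with 40–250 markers and chains
of 500–600,000 iterations, chosen so each check's Monte Carlo error is
small against its tolerance while the whole suite stays desk-scale. The
oracle comparisons (mixed-model equations, closed-form ridge, REML,
binomial/half-normal moments) are computed independently of the sampler
in every case.
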