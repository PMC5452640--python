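# Methods

## The problem

Hybrid breeding programs evaluate new candidate lines as testcrosses in
multi-location yield trials over successive years. Each selection cycle
starts with a large first-stage trial series (GCA1), advances a selected
fraction to a second year (GCA2) and a small remainder to a third (GCA3);
only one to two percent of the genotypes that enter GCA1 are ever seen in
GCA3. First-stage trials of different cycles share no genotypes or checks,
so the yearly datasets are *disconnected*: genotype main effects and
genotype-by-year (GY) interaction cannot be separated through replication of
genotypes. Genomic prediction trained on such multi-year data will silently
divert marker information into fitting GY noise unless GY is modelled.

The package implements the resolution this field has converged on: although
genotypes are not replicated across years, their *alleles* are. Giving the
GY effect a block-diagonal marker-kinship covariance

&nbsp;&nbsp;&nbsp;&nbsp;var(w) = Z_gy Z_gy' σ²_gy,&nbsp;&nbsp;
Z_gy = diag(Z_(year 1), Z_(year 2), …)

ties same-year genotypes together in proportion to marker similarity while
forcing exact zero covariance between years; any cross-year covariance must
flow through the marker main-effect term Z_g u_g, whose linear combinations
are the genomic estimated breeding values (GEBV, v = Z u_g). REML can then
apportion within-year versus cross-year marker covariance to σ²_gy and σ²_g
respectively.

## Stage-wise analysis

All prediction approaches factor the single-stage plot model

&nbsp;&nbsp;&nbsp;&nbsp;γ = T : G×Y×L + T·(G×Y×L) + (Y·L)/S/R/B + e

into stages (T tester, G genotype, Y year, L location, S trial, R replicate,
B incomplete block; tester fixed, everything else random):

1. **Stage 1** (per year-location): genotype-by-tester cell means fixed,
   S/R/B random. The adjusted means m1 leave with *Smith weights* — the
   diagonal of the inverse of their estimated covariance — which become
   fixed residual weights downstream.
2. **Stage 2**: either per year (year-wise, used by A1/A1K), or across years
   with genotype fixed (used by A4/A5), or combined directly with the GP fit
   (A2/A3).
3. **GP stage**: a ridge fit of marker main effects (RR-BLUP), optionally
   plus the marker-by-year term; GEBVs for validation genotypes are always
   Z_vs û_g from the marker main-effect block only — a GY prediction for an
   unseen year is never attempted.

The six approaches:

| label | training data | GY treatment |
|-------|---------------|--------------|
| A1  | disconnected GCA1 years | none (fixed year effects only) |
| A1K | disconnected GCA1 years | marker kinship in the GP fit |
| A2  | complete cycles, one fit of all m1 | marker kinship |
| A3  | as A2 | marker kinship, one variance per year |
| A4  | complete cycles, three stages | identity GY in stage 2, none in GP |
| A5  | as A4 | marker kinship in stage 2 |

Predictive ability is ρ_GP = corr(v̂, m2_VS), the Pearson correlation with
the validation set's adjusted means, with a Fisher-z 95% interval for single
runs and an across-draw t-interval for repeated-sampling scenarios.

## REML engine

Average-information REML with EM fallback. Per iteration the engine forms
V = Σ_k σ²_k Z_k Z_k' + σ²_e diag(1/w) densely, takes the AI step, halves it
while the restricted likelihood would decrease or a component would leave
the parameter space, and otherwise falls back to the (monotone) EM update.
Further numerical choices, all of which matter in practice:

* **Boundary handling.** Components are constrained non-negative by
  projection and flagged; a zero estimate is a first-class result (severely
  unbalanced programs genuinely produce them) and is released again if its
  score turns positive.
* **Step restriction.** No component may grow more than tenfold (plus an
  offset of the response variance) per iteration, and a hard ceiling of
  1e7 × var(y) applies. Without this, near-exact-fit toys drive variance
  ratios into regions where the likelihood is numerical noise.
* **Conditioning guard.** States whose covariance Cholesky factor indicates
  a condition number above ~1e8 are rejected like any failed trial step; the
  restricted likelihood cannot be evaluated reliably there.
* **Convergence.** Relative log-likelihood change < 1e-8 and relative
  parameter change < 1e-6, at most 200 iterations; non-convergence flags the
  fit instead of raising.
* **Fixed-effect coding.** For fits whose purpose is adjusted means, the
  target factor is cell-mean coded (no intercept) and all other fixed
  factors are sum-to-zero coded, so the BLUE vector *is* the vector of
  adjusted means at the average level of the other factors and its
  covariance block feeds the Smith weights directly. Generic fits (the GP
  stage) use an intercept with treatment coding, first level as reference.
  Rank deficiencies are resolved by a Gram-Schmidt screen that always keeps
  the mean cells and drops whichever later column is aliased.
* **Term cleanup.** Identity random terms with a single level, one level
  per observation (residual-aliased, e.g. the L·G·T term at the m1 level),
  or a level partition identical to a fixed term are dropped with a warning
  and reported as zero components. Terms duplicating an *earlier random*
  term are likewise dropped by default — except in diagnostic fits
  (`drop_duplicate_random=False`), where both are kept so the information
  matrix can exhibit the confounding.
* **Asymptotic correlations.** Computed from the expected information at
  convergence. Parameters estimated at zero are non-estimable and reported
  as NaN. Exactly confounded pairs make the information singular; a
  vanishing ridge is added before inversion so such pairs report the
  limiting correlation −1, the conventional ill-conditioning signal.

Dense linear algebra throughout: the intended problem sizes (hundreds to a
few thousand mixed-model equations) never justify sparse machinery.

## Synthetic breeding programs

`simulate_program` generates the data structure the analysis assumes:

* **Founders** are fully inbred, allele frequencies per marker drawn from a
  configurable range (default 0.2–0.8). New lines draw each marker
  independently from one of two parents — no linkage map, because the
  analysis models consume only marker covariance, never recombination. This
  is a documented limitation: linkage disequilibrium decay and map-dependent
  phenomena are outside what passing tests can show.
* **Cycle structure**: per cycle, GCA1 in year c, survivors to GCA2 in year
  c+1 and GCA3 in year c+2, truncation-selected on simple testcross means.
  Default advance fractions (0.10, 0.15) put the GCA3/GCA1 ratio at 1.5%,
  inside the one-to-two-percent band typical of such programs. Testers are
  shared by GCA1/GCA2 within a cycle, renewed at GCA3 and for each new
  cycle. GCA1 genotype sets of different years are disjoint.
* **Yields** are composed additively: marker-driven G (v = Z u_g with
  u_g ~ N(0, σ²_G/m I), so every line's marginal genetic variance is exactly
  σ²_G) and GY (independent u_gy per year, so true cross-year GY covariance
  is zero), iid identity effects for L, GL, YL, GYL, the tester terms, trial,
  replicate and block, plus plot error. Units are dt/ha-scale yields around
  a base of 80.
* **Default variance magnitudes** for G, GY, L, GL, YL, GYL (6.75, 0.58,
  143.57, 1.11, 92.65, 3.83) are calibrated to component estimates from
  commercial German hybrid rye yield trials. Tester-term variances have
  no comparable anchor and default to 0.5–1.0, small fractions of σ²_G,
  flagged as unanchored. Plot error defaults to 12, giving plot-level
  heritabilities in the realistic range for hybrid rye yield. The default
  program scale (3 cycles × 300 genotypes, 500 markers) simulates in
  seconds; study-size runs only need larger counts.
* **Field layout**: resolvable incomplete-block designs with two replicates
  and blocks of 12–16 plots by default. Trials too small to fill the block
  minimum use one undersized block; explicitly configured block counts are
  validated strictly.
* A single RNG stream keyed by `seed` drives every draw in documented order,
  so programs are bit-reproducible.

`simulate_crossed_trial` provides the connected genotype × year × location
factorial companion used for variance-component recovery checks, where G and
GY are identifiable through genotype replication.

## Study conditions used by the tests and the acceptance script

Everything is scaled down from study size so the whole suite runs on one
CPU in minutes; the structure, not the scale, carries the properties.

* *Stage-wise ≡ single-stage*: 20 genotypes × 2 testers × 2 locations ×
  2 years, complete, one plot per cell. With saturated first stages the
  two-stage chain is algebraically identical to the single-stage fit, and
  the test demands agreement to 1e-6 relative. (With replicated first
  stages the diagonal Smith-weight approximation is no longer exact — the
  known price of stage-wise analysis.)
* *REML recovery*: 200 crossed trials of 16 genotypes × 3 years ×
  6 locations × 2 replicates at the calibrated variance magnitudes.
* *GY dissection*: 50 disconnected two-year control training sets of 100
  GCA1 genotypes per year from a 20-founder pool, 120 markers, 3 locations,
  with σ²_GY set equal to σ²_G — the regime the kinship-GY model exists
  for. A1K's advantage is asserted directionally (sign test), never as a
  numeric effect size; with σ²_GY = 0 the paired difference is centred on
  zero. The founder-pool size matters: the dissection operates through
  cross-year kinship, and an effectively unrelated population carries no
  cross-year information to exploit.
* *Heterogeneity recovery*: two-cycle complete training sets in which one
  year's GY variance is inflated fivefold; the heterogeneous fit must rank
  that year's component largest in ≥90% of 100 replicates.
* *Confounding diagnostic*: ten genotypes per year in two fully
  disconnected years with identity G and GY reproduce the asymptotic
  correlation −1; replacing identity with marker kinship and giving each
  year two genetic backgrounds raises the correlation above −0.9.

## Known limitations

* No dominance or epistasis, no spatial field trend, no genotype-specific
  error heterogeneity, and no linkage — the simulator emulates the factor
  structure and variance decomposition of real programs, not their genetics.
* Smith weighting carries only the diagonal of the stage-1 precision;
  off-diagonal information is discarded, as in routine practice.
* The stage-1 covariance used for weights is conditional on plug-in
  variance estimates, the standard approximation.
* Exactly equivalent model pairs fitted by separate REML runs (e.g. the
  three-stage variants when the GY component vanishes) agree only to
  convergence tolerance as propagated through the weights, not to machine
  precision.
* Pedigree-based (A-matrix) BLUP, factor-analytic G×E structures, spatial
  models and Bayesian marker priors are out of scope.
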