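# Methods

## Model

SNP genotypes are coded 0/1/2 copies of the minor allele but treated as
*unordered categories*: the risk carried by a heterozygote need not be half
that of a minor-allele homozygote, so imposing the numeric coding (as
standard PCA does) builds an additive assumption into the analysis.
Categorical PCA (CPCA) instead models each genotype call as a multinomial
observation whose natural parameters have low-rank structure.

For sample i and SNP j, with category 0 (major-allele homozygote) as the
reference,

    theta^k_ij = v^k_j . u_i + mu^k_j,      k in {1, 2},
    P(G_ij = k) = exp(theta^k_ij) / (1 + exp(theta^1_ij) + exp(theta^2_ij)),

where u_i in R^l are per-sample principal component scores shared across
categories, v^k_j in R^l are per-SNP, per-category loadings, and mu^k_j are
per-SNP offsets.  The reference-category constraint theta^0 = 0 removes the
softmax gauge freedom; the likelihood value is unchanged and the model
reduces exactly to Bernoulli (logistic) PCA when only two categories occur.
The stacked ((c-1)d x l) loading matrix is constrained to have orthonormal
columns.

The log-likelihood maximized is

    l = sum_ij [ theta^{k(ij)}_ij - log(1 + exp theta^1_ij + exp theta^2_ij) ],

with k(ij) the observed category.  The constant multinomial base measure is
omitted (it shifts l by a data-only constant).

### Existence of the maximizer, and the ridge option

Because every sample carries its own free score, the MLE frequently does not
exist: any sample whose genotype pattern aligns with a loading direction can
be fit perfectly by sending its score to infinity (the exact analogue of
separation in logistic regression).  On small panels this is the rule, not
the exception.  Likelihoods and probabilities are therefore computed with
max-subtracted softmax (finite for arbitrarily large parameters, no
clipping), and `FitConfig.ridge` optionally adds a Gaussian penalty
`-(lambda/2) sum theta^2` on the natural parameters.  The penalty is gauge
invariant (theta is untouched by the orthonormalization and recentering
steps), guarantees a finite optimum, and for small lambda leaves
well-identified cells essentially untouched while pinning would-be-divergent
natural parameters near |theta| ~ log(1/lambda).  The default is lambda = 0
(plain likelihood); the supervised pipeline uses lambda = 1e-3 so that
first-PC scores of separated samples stay bounded — unbounded scores act as
high-leverage outliers in the downstream trait regression and measurably
reduce power.

## Fitting algorithm

Alternating damped Newton ascent, cycling:

1. **Scores.** Each u_i solves an l-dimensional concave subproblem; one
   Newton step with the exact per-sample gradient and Hessian (multinomial
   covariance projected through the loadings).
2. **Recentering.** The score mean is shifted into the offsets
   ((u - c)v + (mu + cv) leaves theta unchanged); without this the block
   updates crawl along the flat translation direction.
3. **Orthonormalization.** QR of the stacked loading matrix; scores are
   back-rotated by R^T so every theta is preserved to machine precision
   (otherwise the likelihood could decrease).
4. **Loadings and offsets.** Per SNP column, Newton updates of the loading
   rows and the offset vector (category blocks sequential in the reference
   path; the compiled latent_dim = 1 kernel takes one joint Newton step on
   the (V^1_j, V^2_j, mu^1_j, mu^2_j) block, which converges faster and is
   covered by a cross-path consistency test).

Every block step is step-halved (up to `damping` = 20 halvings) and accepted
only on strict improvement, so the objective trace is non-decreasing; Newton
steps are norm-capped at 100 so halving can always land in the concave
region, and coordinates with flat curvature (e.g. a category with no
observations) are frozen rather than being allowed to poison the joint
solve.  Convergence is declared when the relative objective change drops
below `tolerance` (default 1e-6) or after `max_iterations` (default 200).
The surface is non-convex; `n_restarts` (default 5) seed-controlled random
restarts are run and the best final likelihood kept.  Initialization: scores
and loadings from N(0, 0.1^2) draws, offsets at smoothed per-SNP empirical
log-odds.  The first PC's sign is fixed by non-negative correlation with
per-sample minor-allele counts (association statistics are sign-symmetric;
this only stabilizes output across runs).

On tiny panels the block scheme can settle at blockwise-optimal points that
a joint optimizer escapes; restarts mitigate but do not eliminate this, and
the acceptance suite verifies the fit dominates a multi-start derivative-free
maximizer of the same likelihood.

## Supervised association layer

For a SNP set S (gene or pathway) and binary trait y:

1. Each SNP in S is screened by the two-sided Wald p-value of a univariate
   logistic regression of y on its numeric genotype (custom vectorized IRLS;
   Firth's penalized refit under separation).
2. Twenty nested candidate subsets are formed by thresholding at each
   increment of 5 percentiles (nearest-rank) of the screening p-values,
   membership by p <= threshold; duplicate subsets are collapsed.
3. For each unique subset the first PC is extracted (CPCA; or PCA / logistic
   PCA for the comparison arms) and y is regressed on it; the set's
   statistic M is the signed Wald t of largest magnitude, exact ties going
   to the smaller subset.
4. The null distribution of M is estimated by redrawing trait labels i.i.d.
   Bernoulli(prevalence) — prevalence defaulting to the observed case
   fraction — and repeating steps 1-3; the add-one empirical p-value is
   (1 + #{|M_b| >= |M_obs|}) / (B + 1).  Nulls are kept per set by default;
   `pool_null` enables cross-set pooling.
5. Benjamini-Hochberg adjustment (statsmodels step-up) across sets.

Because the PC extractors are unsupervised, subset scores depend only on the
genotype submatrix; they are cached across permutation rounds and fitted
warm-started along the nested subset chain.  The pipeline's solver settings
(one start, tolerance 1e-3, <= 40 iterations, ridge 1e-3) are deliberately
lean: the Wald statistic is insensitive to the residual score drift, and the
identical procedure is applied to observed and permuted traits, so the
permutation test remains exact regardless of solver tolerance.  A
single-SNP subset under the Bernoulli reduction admits no latent factor
below saturation; its score is the binarized genotype itself.

Permutations can stop early (`early_stop_alpha`): once enough null
exceedances have accrued that the final add-one p-value could no longer fall
below the level, remaining rounds are skipped.  Decisions at that level are
identical to the full run; stopped sets receive conservative p-values
computed from the truncated sample.  Calibration studies run the full B.

## Case-control simulator

Emulates a haplotype-resampling design without external reference data:

* **Haplotypes.** A pool (default 10,000) drawn from a block latent-Gaussian
  threshold model: within blocks of 10 SNPs the latent normals share
  correlation rho = 0.7 and are thresholded at each SNP's MAF quantile
  (MAFs ~ Uniform(0.05, 0.5)); blocks are independent.  This reproduces the
  qualitative LD structure (correlated neighboring SNPs) of real panels but
  not recombination-distance decay, allele-frequency spectra, or long-range
  LD — power numbers on it are internally comparable across methods, not
  directly comparable to studies on real haplotypes.
* **Genotypes.** Two haplotypes drawn with replacement per individual and
  summed, so entries are always in {0, 1, 2}.
* **Disease model.** P(case | G) = min(1, f0 * prod over causal SNPs of
  rr(G)), rr(0) = 1, rr(1) = rr1, rr(2) = rr2, multiplicative across the
  (default 3) disease SNPs of a causal gene; baseline penetrance f0 = 0.05.
  Setting the homozygote risk only slightly above the heterozygote risk
  (e.g. rr = (1.2, 1.3)) makes the truth deliberately non-additive.
* **Sampling.** Rejection sampling until the case and control quotas are
  met; controls are unaffected individuals.

All seeds derive deterministically from (scenario seed, replicate, gene).

## Study sizes used by the test and acceptance runs

Chosen once for a single-CPU desk-scale budget:

* Type-I calibration: 200 null gene datasets (20 SNPs each), 100 cases +
  100 controls, B = 99 permutations, full-length (no early stopping).
* Power comparison: 5 causal genes of 12 SNPs (3 disease SNPs each), 100
  cases + 100 controls, B = 49 permutations with early stopping at
  alpha = 0.05; 50 replicates per risk level in the test suite, 25 in the
  acceptance script (which also covers the middle risk level (1.3, 1.4)).
* Parameter recovery: rank-1 ground truth, d = 20, n in {100, 300, 1000},
  10 seeds.

These are an order of magnitude below a realistic association study
(hundreds of cases, genes of up to ~175 SNPs); power levels are accordingly
much lower than a full-scale study would give, and method differences carry
Monte-Carlo noise of several percentage points.  In particular the relative
standing of the categorical model against its binarized and numeric
competitors depends on sample size: the categorical model estimates twice as
many per-SNP parameters, a variance cost that is most visible exactly at
desk scale.

## Known limitations

* latent_dim > 1 is supported by the reference solver but untested beyond
  smoke level; the association layer uses only the first PC.
* The permutation null regenerates labels as Bernoulli draws (variable
  margins) rather than permuting the observed labels; with the discrete
  add-one p-value this makes the test slightly conservative (empirical
  rejection a little below nominal at alpha = 0.05 with B = 99).
* No covariate adjustment, no missing-data likelihood (missingness is
  resolved at read time), no family designs.
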