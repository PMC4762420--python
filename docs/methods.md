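# Methods

`prscog` implements a pruning-and-thresholding (P+T) polygenic-risk-score
analysis relating genetic liability to ischemic stroke (and its small-vessel,
large-vessel and cardioembolic subtypes) to cognitive ability in stroke-free
cohorts, followed by cross-cohort random-effects meta-analysis. This note
records the model, the parameter choices that matter, and the design
decisions made where more than one defensible option existed.

## Scoring model

For a target cohort with effect-allele dosage matrix `X` (entries 0/1/2,
missing allowed) and base-GWAS effects `beta_j` with p-values `p_j`, the
score of person `i` at threshold `t` is

    PRS_i(t) = sum over {j : p_j < t, x_ij observed} of beta_j * x_ij

Thresholding is strict (`p < t`) and the canonical thresholds are 0.8, 0.5,
0.1, 0.05, 0.01, so the SNP sets are nested. Missing genotypes are skipped,
not mean-imputed; the per-person count of nonmissing SNPs enters the
association model as a covariate, which is the construction that makes an
unimputed sum interpretable. Four stroke phenotypes times five thresholds
yield twenty scores per participant.

Before scoring, effects are harmonized to the cohort: variants absent from
the summary statistics, strand-ambiguous variants (A/T, G/C), and variants
with cohort minor-allele frequency below 0.02 are removed; where the summary
effect allele is the cohort's other allele the beta is negated. No
strand-flip rescue is attempted for non-ambiguous mismatched pairs — such
records are dropped and counted, on the view that if ambiguous SNPs are
removed outright no strand inference should be trusted elsewhere either.

## Variant QC

A variant is retained iff call rate >= 0.98, MAF >= 0.01, and a chi-square
(1 df) Hardy–Weinberg goodness-of-fit p >= 0.001, evaluated jointly on the
input dataset (not sequentially re-estimated). The chi-square test rather
than the exact test was chosen because it is closed-form checkable against
an independent oracle; an exact-test option is an obvious future extension.
Monomorphic expected counts return p = 1 (the model fits trivially; the MAF
filter is what removes such sites).

## LD pruning

Pruning follows the conventional `--indep-pairwise 200 5 0.25` reading of a
"200-SNP sliding window" rule: windows of 200 SNPs sliding by 5 within a
chromosome; within a window, pairs are scanned in index order and when both
members of a pair with squared dosage correlation above 0.25 are still
retained, the lower-MAF member is dropped (tie: the later-positioned one);
passes repeat until stable. r² is the squared Pearson correlation of
dosages over pairwise-complete samples — the unphased composite LD measure —
computed once on the full input. The window step (5) and the removal rule
are not forced by the scoring recipe itself; they are documented here and
pinned by an independently coded greedy oracle in the tests. Pairwise r² for
all pairs within the window distance is computed blockwise with matrix
products, so pruning 10,000 SNPs in a 5,000-person cohort takes seconds
rather than hours.

Pruning is run once per cohort on the QC-passed, summary-intersected,
non-ambiguous, MAF >= 0.02 variant set rather than once per stroke
phenotype; when all four summary tables cover the same variants (true for
the generator and for consortium-style emissions) the result is identical
and the cost is a quarter.

## Population structure

Stratification covariates are the first 4 components of classical
(Torgerson) multidimensional scaling of the allele-sharing distance
`D_ij = 1 - mean_v(1 - |x_iv - x_jv|/2)` over variants observed in both
samples. Negative eigenvalues (possible for non-Euclidean distances) are
truncated at zero; the sign convention makes each component's
largest-magnitude loading positive. For large cohorts the top-k eigenpairs
come from a Lanczos solver with a fixed start vector, so results are
deterministic. MDS is computed on the pruned variant set — the conventional
workflow for array data and far cheaper than the full set; the
`mds_max_variants` option additionally caps the number of (seeded,
uniformly subsampled) variants entering the quadratic distance computation,
and the functions accept any dataset if a user prefers the pre-pruning set.

## Cognitive phenotypes

Each subtest is first residualized on age and sex. General fluid ability
(gf) is the first principal component (correlation-matrix PCA, unrotated,
listwise deletion) of the fluid subtests, oriented to correlate positively
with their mean; general cognitive ability re-runs the same PCA with the
crystallized (vocabulary-type) test added as a column — "the gf battery
plus the crystallized test" is read as an enlarged battery, not as
averaging gf with the extra test. The cognitive-aging phenotype
residualizes later-life gf on the age-adjusted childhood ability score,
age and sex; cohorts without a childhood measure simply do not form it.
The default association battery is the 3 fluid subtests, the crystallized
test, gf and general — six phenotypes, hence a 20 x 6 = 120-cell
association grid per cohort.

## Association

Each cell of the grid is a partial correlation: score and phenotype are
each residualized on an intercept, the score's nonmissing-SNP count and the
4 MDS components; `r` is the Pearson correlation of the residuals and the
two-sided p comes from `t = r sqrt(df/(1-r^2))`, `df = n - 2 - k`.
Participants reporting a stroke before cognitive testing are excluded
first. Deletion is listwise per test, maximizing each cell's n. P-values
are uncorrected by default (the phenotypes and scores are strongly
inter-correlated, making simple corrections conservative); Bonferroni and
Benjamini–Hochberg adjustments are available behind a flag.

## Meta-analysis

Per-cohort correlations are pooled on the Fisher z scale with sampling
variance `1/(n - 3 - k)` — the partial-correlation correction with k the
number of covariates partialled out. Cochran's Q uses fixed-effect weights;
between-study variance is the DerSimonian–Laird moment estimator
`tau2 = max(0, (Q - (m-1)) / (sum w - sum w^2 / sum w))`; random-effect
weights `1/(v_i + tau2)` give the pooled z, its standard error, and the
back-transformed omnibus correlation. Q's p-value is the chi-square(m-1)
tail. Pooling raw r with variance `(1-r^2)^2/(n-1-k)` is available behind
`scale="r"` for sensitivity analysis. The three meta-analysis phenotypes
are gf, general and crystallized ability, with per-cohort column-name
mapping for cohorts that name their crystallized test differently
(20 scores x 3 phenotypes = 60 pooled results).

## Synthetic cohorts

The generator produces the three inputs the pipeline needs, with the
statistical features the analysis is sensitive to:

* **Genotypes.** Variants carry uniform MAFs in [0.05, 0.5] and sit in
  contiguous LD blocks. Within a block, each haplotype's liabilities share
  an exchangeable latent correlation `block_rho` (default 0.8); a liability
  below the Phi^{-1}(MAF) quantile codes one allele copy. The two haplotypes
  are independent, so Hardy–Weinberg holds marginally and dosages are
  binomial at each site. Latent rho 0.8 translates to adjacent dosage
  r² ≈ 0.28, and the default block size of 10 SNPs makes sliding-window
  pruning at r² > 0.25 retain roughly a quarter of the panel — comparable
  to pruning behavior on dense SNP arrays. (An earlier draft used 50-SNP
  exchangeable blocks, which made pruning retain under a tenth of the panel
  — much harsher than any real array — and was revised on that ground.)
  Genotypes go missing independently at rate 0.02, matching the 0.98
  call-rate floor.
* **Summary statistics.** True log-odds effects are spike-slab: each SNP is
  causal with probability 0.6, and causal effects are normal with variance
  `h2 / (m_causal * 2 p (1-p))`, so the total liability-scale variance
  explained is `h2` (default 0.38, the SNP heritability reported for
  all-ischemic stroke). Observed betas add noise with the GWAS sampling
  standard error `1/sqrt(2 n_gwas p (1-p))`; `n_gwas` defaults to 10,000,
  roughly the effective size of a 12,000-case/62,000-control GWAS. These
  defaults put the mean per-SNP non-centrality `sqrt(h2 n_gwas / m_causal)`
  near 0.8 — a weak-per-SNP-power regime, which is the regime in which
  scores built from more SNPs correlate more strongly with the outcome, the
  behavior the analysis is designed to exhibit. A `flip_fraction` of
  records is emitted with swapped alleles and negated beta, and an
  `ambiguous_fraction` of variants receives A/T or G/C allele pairs, so
  harmonization is exercised rather than vacuous.
* **Phenotypes.** The latent cognitive factor is
  `g = -sum_k rho_g[k] * std(X beta_k) + sqrt(1 - sum rho^2) eps`, so a
  positive genetic correlation `rho_g` between a stroke liability and
  cognition produces a *negative* score-cognition correlation, with
  magnitude analytically predictable for recovery tests. Defaults:
  all-ischemic 0.3, SVD and LVD 0.2, cardioembolic 0 (the subtype the study
  found unassociated). Three fluid subtests (loadings 0.7/0.65/0.6) and a
  crystallized test (0.6) load on g with unique noise plus linear age and
  sex effects; a childhood score has stability 0.7 with g; stroke history
  is logistic in the combined standardized genetic risk with the intercept
  at 3% prevalence (inside the 1.9%–5% range of the cohorts emulated).

Every stage draws from its own substream derived deterministically from
(seed, stage label), so identical configs are bit-reproducible and changing
one fraction (e.g. `flip_fraction`) leaves all other draws untouched —
which is what makes the flipped-vs-unflipped score-equality oracle exact.

What the generator does *not* emulate: realistic human LD maps and
recombination hotspots, allele-frequency spectra skewed toward rare
variants, case-control ascertainment in the base GWAS, relatedness and
ancestry admixture in the target cohorts, and instrument-specific test
score distributions. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and well-calibrated under its stated
assumptions, not that effect sizes from any particular real cohort will be
reproduced.

## Numerical choices and degenerate inputs

* Pairwise r² over fewer than 3 complete pairs is treated as 0 with a
  warning; constant vectors give r² = 0.
* Partial correlations flag (rather than fabricate) results where a
  residual variance is numerically zero; degrees of freedom always charge
  every covariate column.
* A score whose nonmissing-SNP count is constant (no missing data) would be
  collinear with the intercept; the count covariate is dropped for that
  score and the covariate list in the output reflects it.
* PCA composites use a symmetric eigensolver with a fixed sign convention;
  composites are reproducible to 1e-8 across runs.
* HWE on a site with zero expected heterozygotes returns p = 1; an
  all-zero count triple is a domain error.
* Problem sizes used by the shipped checks: study-scale recovery runs use
  one cohort of 5,000 participants and 10,000 SNPs; grid-structure and
  meta-analysis checks use three cohorts of a few hundred participants;
  Monte-Carlo calibrations use 10,000 null partial-correlation draws and
  2,000 homogeneous three-cohort meta-analyses.

## Known limitations

* The score is an unweighted P+T sum; shrinkage estimators (LDpred,
  lassosum) are out of scope.
* The exact Hardy–Weinberg test and founders-aware HWE are not implemented.
* Windows are SNP-count based; kilobase-based windows and p-value-informed
  clumping are not implemented (the recipe prunes, it does not clump).
* MDS offers no out-of-sample projection; admixed cohorts would need more
  than 4 components.
* The raw-r meta-analysis scale uses the large-sample variance
  approximation and is intended only for sensitivity checks.
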