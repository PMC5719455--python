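# Methods

This note records the models implemented by `admixrisk`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that a maintainer would otherwise have
to reverse-engineer.

## The comparative-risk model

The quantity of interest is the relative burden of GWAS-reported risk
alleles between two population samples. For each risk SNP the package
forms the 2×2 table of risk / non-risk allele counts in populations A and
B and computes the natural-log odds ratio

    log OR = ln[(RA_A / NRA_A) / (RA_B / NRA_B)],

positive when the risk allele is commoner in A. Missing genotype calls are
excluded from both the numerator and denominator of each frequency.

*Variance model.* The standard error is Woolf's, `sqrt(1/a + 1/b + 1/c +
1/d)` over the four allele counts. This is the standard choice for
frequency-derived odds ratios; allele counts (2N per population) rather
than sample counts enter the cells. When any cell is zero, the
Haldane–Anscombe correction adds 0.5 to all four cells before both the
estimate and the SE; a `corrected` flag is preserved for audit. 95%
intervals are Wald intervals with the conventional 1.96 multiplier, and
"per-SNP significant" means the interval excludes zero — a deliberate
convention, since no exact test is implied by the estimator.

*Meta-analysis.* Fixed effects pool with inverse-variance weights
`w = 1/se²`. Random effects use DerSimonian–Laird:
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, then re-weight by
`1/(se² + τ²)`. p-values and CIs use the normal reference — with k on the
order of 10²  the difference from a t reference is negligible, and the
choice is recorded in output metadata. The implementation is authored
here and cross-checked in the test suite against
`statsmodels.stats.meta_analysis.combine_effects(method_re="dl")`, which is
never used as the computational path.

*Polygenic risk score.* `PRS = Σ RAᵢ / Σ Aᵢ` per individual — an
unweighted, normalized risk-allele count. The denominator counts callable
alleles (2 per non-missing SNP), so individuals with different missingness
remain comparable and scores always lie in [0,1]. Effect sizes are not
used as weights: the SNP set is assembled from heterogeneous studies whose
effect sizes are not on a common scale. Individuals with zero called risk
SNPs receive NaN with a flag rather than a fabricated score.

## Catalog filtering

Three rules extract a trait's risk-SNP set from a GWAS-catalog-style
table: study size ≥ 100,000 genotyped SNPs, association p < 1e-5, and
"strongest association in its genomic locus". The locus rule is
implemented as greedy distance-based clumping: survivors are sorted by
ascending p (ties: larger study first, then rsid) and accepted unless an
already-accepted SNP lies within `clump_window_bp` (default 1 Mb) on the
same chromosome. Distance clumping with a configurable window is the
standard lead-SNP practice when no LD panel is attached; the greedy
procedure is provably equivalent to "repeatedly keep the strongest
remaining SNP and discard its window", which the tests verify by brute
force on small catalogs. Sorting inside the filter makes the output
invariant to input row order. The "case-control study" qualifier is not
machine-checkable from the tabular schema; only the study-size rule is
enforced, and the limitation is stated here rather than silently faked.

## Ancestry estimation

*LD pruning* slides a window of 50 SNPs advancing by 5 and drops the
later-positioned member of any pair whose squared dosage correlation
exceeds `r2_threshold` (default 0.1). Missing calls are mean-imputed for
the correlation only; monomorphic SNPs are retained untested and logged.
A published description of this style of pruning quotes a bare "r ≥ 0.05"
threshold; whether r or r² was meant is ambiguous, and 0.05 on r would
discard nearly everything, so the package parameterizes the threshold on
r² and leaves the value to the caller rather than guessing.

*Allele-sharing distance.* For samples i, j over loci called in both:
similarity `s = 1 − |dᵢ − dⱼ|/2` per locus (1 for identical genotypes, 0.5
for het vs hom, 0 for opposite homozygotes); distance is `1 − mean(s)`.
Pairs sharing zero called loci raise an error naming the pair — there is
no defensible imputation at that point. The exact missing-data convention
of PLINK's allele-sharing distance is not fully specified in its
documentation lineage; the definition above is declared, not inferred.

*Projection.* Classical (Torgerson) MDS on the distance matrix:
double-center −½D², take top eigenvectors scaled by √eigenvalue.
Classical MDS was preferred over running PCA on distance-matrix rows
because it has a testable exactness property (it recovers Euclidean
configurations up to rotation); a PCA-on-rows variant reproduces the same
qualitative cluster structure but has no such invariant. Non-positive
eigenvalues yield zero coordinates with a warning; each column's sign is
fixed by making its largest-magnitude loading positive.

*Supervised fractions.* Given reference allele frequencies for K
ancestral populations (clipped into [1e-4, 1−1e-4] to keep the likelihood
finite), each individual's ancestry vector q maximizes

    Σ_m [ d_m ln(Σ_k q_k p_km) + (2 − d_m) ln(Σ_k q_k (1 − p_km)) ]

over the simplex via EM multiplicative updates from a uniform start,
skipping missing loci. The update preserves the simplex exactly and the
log-likelihood is non-decreasing (asserted in tests at every iteration).
Defaults: `tol = 1e-6` on the max change in q, `max_iter = 2000`;
non-converged individuals are returned with a flag rather than an
exception. Identical reference rows make q non-identifiable; the estimator
returns the uniform vector with a warning. This supervised estimator
targets the same quantity as unsupervised ADMIXTURE-style clustering but
requires reference panels; joint estimation of frequencies and fractions
is out of scope.

## Resampling controls

Replicate machinery is fully vectorized and seeded:

* **Bootstrap** (default 10,000 replicates): resample the k risk SNPs with
  replacement, recompute the fixed-model pooled log OR.
  `z = mean/sd` of the replicate distribution, two-sided normal p.
* **Random SNP sets** (default 500,000 replicates): sample size-matched
  SNP *sets* (without replacement within a set — they are sets, not bags)
  from the pooled panel of disease-associated SNPs, compute the fixed
  pooled log OR per set; `z = (observed − mean)/sd` of the null. Sampling
  pools SNPs across diseases rather than stratifying by disease. Fixed-
  model pooling is used inside replicates; recomputing DerSimonian–Laird
  hundreds of thousands of times is supported but off by default.
* **Disease scan**: per trait, the difference of population mean PRS;
  `z = mean/sd` across traits.

The z definitions are declared in every output sidecar, since "z-test"
alone underdetermines them. A replicate distribution that is constant up
to float round-off (relative sd ≤ 1e-12) is flagged degenerate with
z = ±inf rather than dividing by noise.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
nothing more:

* **Ancestral frequencies**: per SNP a common ancestral frequency
  `p0 ~ U[0.05, 0.95]` (truncated to avoid monomorphic SNPs, which would
  make ORs undefined), then per population k a Beta draw with mean p0 and
  variance `F_k·p0(1−p0)` (Balding–Nichols). Default drift
  `F = (0.10, 0.14, 0.25)` for the African/European/Native-American-like
  branches — typical continental differentiation, with the American branch
  most drifted. The Balding–Nichols form is a modelling choice; no claim
  is made that real reference panels follow it.
* **Admixture**: per individual `q ~ Dirichlet(α)` of its cohort profile;
  per allele copy an ancestry from q, then an allele Bernoulli(p).
  Default cohort profiles use α = 15 × (mean ancestry vector) with means
  (0.76, 0.13, 0.11) for the Afro-Latino-like cohort and
  (0.07, 0.75, 0.18) for the Mestizo-like cohort, 94 individuals each;
  concentration 15 puts the sd of the major fraction near 0.10, a
  realistic within-cohort spread.
* **Risk SNPs**: `n_risk_snps` (default 165) SNPs chosen without
  replacement; the alternate allele is the risk allele by convention
  (fixed conventions keep truth files trivial); its frequency in the
  target ancestry is shifted by `risk_shift_delta` (default +0.15),
  clamped to [0.01, 0.99] so no cell of a downstream 2×2 table is forced
  to zero. A zero delta is a true no-op.
* **Catalog**: one passing row per truth risk SNP plus three decoy
  classes — weak-p rows, small-study rows, and same-locus "shadow" rows
  placed inside the clump window with weaker p — so the three-rule filter
  has a known correct output. A separate helper emits multi-trait decoy
  diseases over the non-risk SNP panel for the disease scan and the
  random-set pool.
* **Missingness**: i.i.d. at `missing_rate` (default 1%), injected after
  genotype generation.
* **Seeding**: one master seed spawns named independent substreams
  (frequencies, fractions, genotypes, missingness, risk-SNP choice,
  catalog, duplicates), so changing one stage's parameters never perturbs
  another stage's draws, and identical config + seed is bit-reproducible.

What it does **not** emulate: linkage disequilibrium (SNPs are independent;
a duplicate-column option exists solely to exercise pruning), haplotype or
coalescent structure, selection, genotyping-error correlation, phenotypes,
and realistic GWAS discovery noise (truth risk alleles are exactly known).
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to LD-induced redundancy or
ascertainment effects in real catalogs.

## Group comparisons

Two-group PRS comparisons use the pooled-variance t-test by default with a
Welch option (the choice is not dictated by the method and both are
exposed); more than two groups use one-way ANOVA. Zero within-group
variance with differing means returns an infinite statistic with a
degenerate flag instead of an exception. The ancestry–risk relationship is
the Pearson correlation of a chosen ancestry fraction with the PRS, p-value
from the exact t transform `t = r√((n−2)/(1−r²))`, a least-squares line,
and an equal-count decile-bin summary (bin sizes differ by at most one)
with per-bin PRS quartiles — the standard box-plot-per-decile presentation.

## Problem sizes and determinism

The shipped study conditions are two cohorts of 94 individuals, a
1,200-SNP panel with 165 risk SNPs, delta +0.15, 1% missingness. The test
suite and the acceptance script scale replicate counts to desk scale
(bootstrap 10,000 — the full default; random sets 50,000 rather than the
500,000 pipeline default, a reduction that moves the z statistic by well
under 0.1 on fixed pools; supervised-ancestry recovery at 5,000 SNPs ×
100 individuals). All stochastic stages take explicit seeds; the pipeline
manifest records a checksum of every artifact, and re-running an identical
configuration reproduces every file byte for byte.

## Known limitations

* rsID-only SNP matching between catalog and genotypes; no positional
  fallback or liftover.
* Strand-ambiguous (A/T, C/G) risk alleles are matched only by exact
  identity; no strand flipping is attempted, and mismatches are dropped
  with a warning — silent strand guessing corrupts ORs.
* Biallelic SNPs only; multi-allelic VCF records are skipped (or rejected
  under a strict flag); indels and binary PLINK are unsupported.
* The PLINK-text format does not record which allele is counted, so an
  exact dosage round trip requires passing the counted alleles back to the
  reader; without the override, dosages are recovered up to a per-variant
  complement.
* Per-SNP CIs are Wald intervals on allele counts; their finite-sample
  coverage at extreme frequencies is approximate (the null-calibration
  test bounds the realized type-I rate).
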