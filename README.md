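# admixrisk

Comparative genetic-risk analysis between admixed populations: per-SNP
risk-allele log odds ratios, fixed/random-effects meta-analysis, unweighted
polygenic risk scores, supervised ancestry estimation, and the resampling
controls that guard such comparisons against systematic allele-frequency
bias. The package targets population-genetics researchers who want to
contrast the aggregate burden of GWAS-reported risk alleles between two
population samples — for example an Afro-Latino cohort versus a Mestizo
cohort — and to relate that burden to continental ancestry fractions.

Because real admixed-cohort genotypes are typically restricted-access, the
package ships a first-class synthetic-data generator that emulates
three-way admixed genomes (African / European / Native American-like) with
Balding–Nichols-differentiated allele frequencies, Dirichlet ancestry
profiles, designated risk SNPs with a configurable ancestry-correlated
frequency shift, decoy-laden GWAS-catalog tables, and missing calls — so
every stage of the analysis is testable end-to-end with known ground truth.

## The statistics

**Per-SNP contrast.** For populations *A* and *B*, with risk-allele and
non-risk-allele frequencies *RA* and *NRA* estimated from allele counts,

    log OR = ln[ (RA_A / NRA_A) / (RA_B / NRA_B) ]

Positive values mean a higher risk-allele burden in *A*. Standard errors
use Woolf's method on the four allele counts, with the Haldane–Anscombe
correction (add 0.5 to every cell) when any count is zero; 95% Wald
intervals flag per-SNP significance.

**Meta-analysis.** Per-SNP log ORs are pooled by inverse-variance weighting
(fixed effects) and by DerSimonian–Laird (random effects, between-SNP
variance τ²).

**Polygenic risk score.** Per individual, the unweighted normalized sum

    PRS = Σᵢ RAᵢ / Σᵢ Aᵢ

where *RAᵢ* ∈ {0,1,2} counts risk alleles at SNP *i* and *Aᵢ* ∈ {0,1,2}
counts called alleles; missing SNPs contribute to neither sum, so scores
lie in [0,1]. Effect sizes are deliberately not used as weights because
catalog effect sizes from different studies are not comparable.

**Controls.** (1) a bootstrap over the risk-SNP set (robustness to outlier
SNPs), (2) a null distribution of pooled log ORs from random size-matched
disease-SNP sets (systematic frequency bias), and (3) a multi-disease scan
of mean-PRS differences (systematic scoring bias), each summarized by a
z-test.

**Ancestry.** LD pruning on genotype-dosage r², allele-sharing distances,
classical MDS for visualization, and supervised maximum-likelihood
ancestry fractions: per individual, EM maximizes the binomial likelihood of
the dosages under a mixture of reference allele frequencies over the
simplex.

## Worked example

```python
from admixrisk import (SimulationConfig, simulate_study, filter_catalog,
                       align_risk_alleles, or_table, meta_analyze,
                       polygenic_risk_score, group_prs_test)

cfg = SimulationConfig(n_snps=1200, n_risk_snps=165,
                       risk_shift_delta=0.15, seed=1)
study = simulate_study(cfg)

risk_set = filter_catalog(study.catalog, "trait_of_interest")
aligned = align_risk_alleles(study.genotypes, risk_set)
ors = or_table(aligned, "choco_like", "antioquia_like")
meta = meta_analyze(ors, model="fixed")
prs = polygenic_risk_score(aligned)
t = group_prs_test(prs, groups=["choco_like", "antioquia_like"])
```

This prints (via the obvious f-strings):

```
retained 165 of 200 catalog rows
pooled log OR (fixed) = 0.635 [0.596, 0.675], p = 1.03e-218
119/165 SNPs significant, 107 favour choco_like
mean PRS: 0.592 vs 0.474, t = 29.8, p = 9.06e-73
```

The catalog filter discards all 35 decoy rows (weak p-values, small
studies, same-locus shadows) and recovers exactly the 165 designated risk
SNPs. Because the generator shifted risk-allele frequencies by +0.15 in the
African-like ancestral population, and the `choco_like` cohort draws ~76%
of its ancestry from it versus ~7% for `antioquia_like`, the pooled log OR
is strongly positive, most significant SNPs favour the African-like cohort,
and the mean PRS separates the cohorts.

## Command line

```bash
admixrisk simulate --seed 7 --out demo/
admixrisk filter-catalog --catalog demo/catalog.tsv \
    --trait trait_of_interest --out demo/risk_snps.tsv
admixrisk run-all --config pipeline.yaml   # full pipeline + manifest
```

`run-all` writes every intermediate artifact (VCF, frequency tables, OR
table, meta JSON, null distributions, PRS, ancestry fractions, MDS
coordinates, decile summaries) plus a manifest with per-stage checksums;
re-running an identical config and seed reproduces every file byte for
byte.

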