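# ptqtl

Genetic mapping of **post-transcriptional** regulation in cell-type-specific
cohorts: RNA-editing and alternative-polyadenylation (APA) phenotypes,
cis-QTL association models for both, hierarchical multiple-testing
correction, and the downstream statistics used to interpret such maps —
sharing (π1), RNA-structure enrichment, GWAS colocalization, and mediation.

## Who this is for

Groups mapping molecular QTLs beyond steady-state expression — for example
in sorted neural progenitors and neurons from tens of donors — where the
phenotypes are read-count ratios (editing rates) or composition fractions
(poly(A) usage) rather than normalized expression, and where standard
eQTL tooling does not fit the error model.

## The models

**Editing (edQTL).** The edit rate of site *i* in donor *j* is the fraction
of reads supporting the edited allele (A-to-G). Each cis variant (±100 kb,
same gene) is tested with a binomial GLM on the per-donor read-count pairs:

    logit E[edited_ij / total_ij] = α + β·g_j + Σ γ_c·c_j

with dosage *g*, covariates *c* (3 genotype-MDS axes, a batch factor, and a
tuned number of global editing PCs). β is the per-minor-allele log-odds of
editing; the Wald p-value uses, by default, an HC3 sandwich variance with a
t reference so that latent-factor overdispersion does not inflate the tail.

**APA (apaQTL).** Poly(A) usage (PAU) of a 3'UTR isoform is its share of
the gene's isoform expression. After filtering and rank-based
inverse-normal transformation, each variant within ±25 kb of either UTR end
is tested with an EMMAX-style linear mixed model,

    y = α + β·g + Σ γ_c·c + ε,   cov(ε) = σᵤ²·K + σₑ²·I,

where K is the identity-by-state kinship (leave-one-chromosome-out) and
(σᵤ², σₑ²) are REML estimates under the covariates-only null, reused for
every cis variant of a phenotype.

**Multiple testing (eigenMT-FDR).** Per phenotype the minimum nominal p is
multiplied by the effective number of independent cis variants (eigenvalue
count explaining 99% of the genotype correlation), then Benjamini–Hochberg
runs across phenotypes; phenotypes with global q < 0.05 are significant and
receive a primary variant (smallest p; ties by distance, then position).

**Downstream.** Storey π1 for sharing between scans; MAF/distance-matched
permutation enrichment of significant variants in RNA secondary-structure
categories; LD-thresholded conditional colocalization (pair GWAS and QTL
index variants at r² > 0.8, refit the QTL conditioning on the GWAS index
dosage, call colocalized when the signal vanishes); BIC-weighted mediation
model comparison for (variant, mediator, expression) triads.

A synthetic-cohort generator (`ptqtl.syndata`) produces every input — LD
structured genotypes from founder-haplotype pools, binomial/beta-binomial
editing counts with latent and batch factors, multinomial isoform counts,
GWAS summaries with shared/distinct/absent causal variants, annotations —
with ground truth for recovery testing.

## Worked example

```python
from ptqtl import syndata, pipeline

cfg = syndata.SimConfig(seed=1, frac_edit_qtl=0.1, beta_edit=1.5)
geno = syndata.simulate_genotypes(cfg)
counts, truth = syndata.simulate_editing_dataset(geno, cfg)
res = pipeline.run_edqtl_pipeline(
    geno, counts, pipeline.RunConfig(pc_grid=(0, 1)), batch=truth.batch
)
print(res.n_significant, "significant sites of", len(res.phenotypes),
      "tested; PCs chosen:", res.chosen_pcs)
print(res.primaries[["phenotype_id", "variant_id", "beta", "p_nominal"]].head())
```

Output:

```
19 significant sites of 164 tested; PCs chosen: 0
  phenotype_id variant_id      beta     p_nominal
0     site0014    rs00088  1.207456  7.671164e-16
1     site0023    rs01133  1.429070  6.848905e-23
2     site0026    rs00164  1.305888  1.077891e-21
3     site0062    rs00409  1.326513  3.040428e-14
4     site0067    rs01431  1.489399  7.896761e-16
```

The run planted a logit effect of 1.5 at 10% of 200 sites across 80 donors;
the scan recovers 17 of the 20 causal sites (the fitted `beta` column is the
log-odds change per minor allele, close to the planted values) with 2
additional calls — consistent with the 5% FDR target.

The same flow works from the shell on a written dataset:

```bash
ptqtl simulate --out ds --seed 1
ptqtl edqtl --dataset ds
ptqtl apaqtl --dataset ds
ptqtl enrich --dataset ds --n-perm 1000 --seed 1
ptqtl coloc --dataset ds
```

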