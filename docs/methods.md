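# Methods

This note documents the statistical models, the synthetic-cohort generator,
the numerical choices, and the known limitations of the package. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Phenotype construction

**Editing.** An editing site's phenotype in a donor is the pair
(edited reads, total reads); the edit rate is their ratio, missing when the
total is zero. A site enters QTL mapping when at least 85% of donors cover
it with ≥ 10 reads and ≥ 2 edited reads (both bounds inclusive). Because
the covered donors differ between sites, each site carries its own
supporting-donor set into association testing; there is no global donor
intersection. DNA-level validation (`validate_with_dna_reads`) pools
ATAC-style allele counts per site over donors and calls a site validated
when only the unedited allele appears; the minimum DNA depth per donor is a
parameter (default 1 read, since the appropriate floor is context
dependent). The Alu editing index is the pooled — read-weighted, not
region-averaged — percentage of G reads among A+G reads across a sample's
Alu regions.

**APA.** PAU of an isoform is its count share within the gene, per donor;
shares over a gene sum to one where defined and are never renormalized
after filtering. Isoforms need ≥ 10 raw counts in ≥ 10% of donors (the
filter deliberately uses raw counts; the alternative was unspecified
upstream). For genes left with exactly two isoforms the two PAU vectors are
complementary, so one is dropped uniformly at random under the run seed and
recorded in the provenance flags. "Quantile normalization" is implemented
as a per-isoform rank-based inverse-normal transform (average ranks for
ties, offset (r − 0.5)/n), the standard choice for Gaussian-LMM QTL
phenotypes; a classical across-sample quantile mode is available via
`normalize_pau(method="quantile")`. Isoforms with < 10 non-missing donors
or zero variance are flagged and excluded from testing.

## Association models

**Binomial GLM (editing).** Logistic regression on the aggregated
(edited, unedited) response, fit by IRLS to a gradient max-norm below 1e-8
or 100 iterations, with step damping and a divergence guard; fitted
per-allele log-odds beyond ±15 are flagged as (quasi-)separation and return
no p-value rather than a misleading one. The default pipeline test is a
Wald test with an **HC3 leverage-adjusted sandwich variance and a t(n − p)
reference**. Rationale: the generator's default latent global-editing
factor (and any real unmodelled donor factor) makes counts overdispersed;
the model-based variance then rejects far above its level (about 25% at
nominal 5% without the PC covariate in our calibration runs) and — worse
for a min-p-based hierarchical correction — has a heavy far tail even when
the average level looks acceptable. HC3 with leverage adjustment matters
because the few homozygous-minor donors are high-leverage points at
cohort-scale n. The model-based variance (plain Wald, normal reference)
remains available with `robust=False` and is exact when the binomial model
holds.

**Linear mixed model (APA).** EMMAX-style two-stage fit: the kinship is
eigendecomposed once; the variance ratio λ = σᵤ²/σₑ² is profiled by bounded
scalar REML optimization on log λ ∈ [−12, 12] (tolerance 1e-6); a boundary
solution (λ → 0) collapses to OLS and is flagged, not an error. Every cis
variant of a phenotype is then tested by GLS with the frozen error
covariance and a t(n − p) Wald test. With K = I the procedure reproduces
OLS exactly (tested to 1e-8). The IBS kinship is
K[j,j'] = mean over variants of (2 − |d_j − d_j'|)/2 on rounded dosages;
leave-one-chromosome-out variants are excluded when configured. Note the
null-boundary property of variance components: for an iid phenotype the
REML σ̂ᵤ² is the standard ~50:50 mixture of an exact zero and a small
positive value; the package does not shrink it further, because the
quantity that matters — the calibration of the association test — is
unaffected.

**Covariates.** Population structure enters as the top-3 classical-MDS
axes of the IBS distance (equivalently, principal coordinates of 1 − K); a
batch factor (e.g. FACS sorter) enters one-hot; global phenotype PCs are
computed from the (mean-imputed, centered) donors × phenotypes matrix. The
PC count is tuned by rerunning the full scan over a grid and keeping the
count that maximizes significant phenotypes at 5% eigenMT-FDR, ties toward
the smaller count. This count-maximization is only safe when the
per-variant test is calibrated at every grid point — the reason the robust
variance is the pipeline default.

**Variant filter.** Per phenotype, on its supporting donors, a variant is
testable when it has ≥ 2 heterozygotes and either no or ≥ 2
homozygous-minor donors; dosage hardening (rounding) is used for class
counting only, the continuous dosage for testing.

**eigenMT-FDR.** Cis variants are taken in consecutive positional windows
of ≤ 200; per window, eigenvalues of the variant correlation matrix are
counted (descending) until 99% of the variance is covered; the sum over
windows, clamped to [1, M], multiplies the phenotype's minimum p
(Bonferroni-style), and BH runs across phenotypes. Exact duplicate dosage
columns are collapsed before windowing — they carry no independent tests,
and because the 0.99 eigen count is not additive across windows, leaving
them in would make m_eff depend on where window boundaries fall. Window
merging refinements are omitted, so m_eff is conservative (never smaller
than a merged variant would give).

## Downstream statistics

**π1.** Storey's estimator on the replication p-values of discovery
(phenotype, variant) pairs: π̂0(λ) over λ = 0.05…0.95 (step 0.05), smoothed
by a cubic polynomial weighted by √(1 − λ) — the right-hand bins estimate
π0 from few points and would otherwise dominate — evaluated at the largest
λ and clamped to [0, 1]. Below 100 p-values the raw value at λ = 0.95 is
used. Its accuracy is assessed as bias across replicate mixtures; a single
5000-p-value draw has a sampling SD near 0.04.

**Structure enrichment.** For each significant variant, permutations draw
one non-significant variant without replacement, matched on MAF and
absolute distance-to-site within ±50% relative tolerance (distance floor
1 bp so zero distances stay matchable); unmatchable variants are excluded
with a warning. The default p counts permutations whose in-category count
**reaches or exceeds** the observed count: with small discrete counts the
strict "greater-than" convention deletes the tie mass and rejects ~2× its
nominal level, so the tie-inclusive convention is the default and the
strict count is reported alongside (`p_strict`, with its add-one-corrected
version `p_add_one` = (1 + #greater)/(1 + n_perm)). Matched sampling is
overall (not per-category); per-permutation exhaustion of the unused pool
falls back to re-use of an eligible variant, which is rare whenever the
non-significant pool is several times the significant set.

**Colocalization.** GWAS index variants are the genome-wide significant
hits (p < 5e-8) greedily pruned to pairwise r² < 0.2, ascending p, ties by
position. Each (GWAS index, QTL index) pair with r² > 0.8 triggers a refit
of the QTL model with the GWAS index dosage appended to the covariates;
"no longer significant" is operationalized as conditional p ≥ 0.05
(configurable — no threshold is canonical). Identical or perfectly
collinear pairs cannot be conditioned on and are called colocalized with a
collinear flag, since conditioning on (a copy of) the variant itself
removes the signal by construction.

**Mediation.** The three causal diagrams for a (variant X, mediator M,
expression Y) triad — forward X→M→Y, independent X→M & X→Y, reactive
X→Y→M — are each scored by the BIC of their joint Gaussian likelihood (two
regressions per model, variables residualized on covariates first);
exp(−ΔBIC/2) weights, normalized, are reported as approximate posterior
probabilities. Requires ≥ 30 complete cases; zero-variance mediator or
outcome yields no result.

## The synthetic cohort

The generator emulates the study design the pipeline targets: ~80 donors
per cell type, imputed common variants (target MAF drawn from
[0.05, 0.5]), ~50× read coverage at editing sites, a latent global-editing
factor (logit SD 0.5) and a per-site batch shift (SD 0.5) for a two-level
FACS-sorter factor, and ~10% of phenotypes carrying a cis effect.

* **Genotypes** — per LD block (20 consecutive variants), a pool of 8
  founder haplotypes is drawn so each variant's pool frequency matches its
  target MAF (at least one carrier, never all); donor haplotypes copy a
  founder along the block with switch probability 0.01 per variant. This
  gives exact {0,1,2} dosages, within-block LD, independent blocks, and
  `ld_block_size=1` degenerates to unlinked variants. Relatedness
  duplicates both haplotypes between disjoint donor pairs
  (monozygotic-twin-like sharing — the configuration where unadjusted
  association tests fail most clearly).
* **Editing counts** — coverage is negative binomial (size 5) around the
  mean; edited counts are binomial, or beta-binomial with intraclass
  correlation ρ (ρ = 0 reduces exactly to binomial). Baseline logits are
  N(logit 0.2, 0.8), spanning realistic site-level edit rates.
* **Isoform counts** — per gene, 2–4 isoforms with logistic-normal usage
  (donor noise SD 0.5) and multinomial counts at negative-binomial gene
  depth (mean 200); the planted effect adds β·dosage to the first
  isoform's log-odds.
* **GWAS** — an independent cohort of 5000 individuals drawn from the same
  founder pools; trait effect 0.3 SD per allele, which clears 5e-8 down to
  MAF ≈ 0.05. The null scenario redraws noise until no variant is
  genome-wide significant.
* **Annotations** — region classes and Alu flags match the observed
  predominance of intronic/3'UTR Alu sites; structure categories default
  to a stem-heavy baseline with an optional planted enrichment factor on
  causal variants.

What the generator does **not** emulate: read-level artifacts (mapping
bias, strand errors), realistic genome-wide LD decay and population
demography, shared causal architecture between editing and APA phenotypes,
and expression-level confounding of PAU. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
generative assumptions, not robustness to upstream artifacts.

## Study sizes used by tests and the reproduction script

Type-I: 500 null site-variant pairs at n = 80, coverage 50. FDR: 20
replicate cohorts (200 sites, 2000 variants) with 10% causal sites at logit
β = 1.5. Effect recovery: 200 causal sites at β = 1.0. Relatedness
contrast: 100 cohorts (80% twin pairs, polygenic share 0.9), 20 null
variants each, EMMAX vs OLS. π1: 20 replicate mixtures of 5000 p-values
per true π1 ∈ {0, 0.3, 0.6}. Enrichment: 200 null datasets × 200
permutations; 25 datasets with a 3× planted stem enrichment. Colocalization:
50 simulations per scenario with causal variants planted at MAF ≥ 0.2,
β = 2.5, coverage 100 — conditions under which the QTL itself is reliably
mappable, so the measurement isolates the pairing/conditioning logic rather
than association power. Mediation: 100 forward-generated triads at n = 80,
path coefficients 0.8.

## Known limitations

* The binomial IRLS treats donors as independent given covariates; shared
  latent structure beyond the fitted PCs is only guarded against by the
  sandwich variance, not modelled.
* m_eff windows are positional and non-overlapping; no window merging.
* Conditional colocalization is single-signal: no stepwise conditioning,
  no Bayesian posterior-probability framework.
* The permutation-enrichment fallback (re-use when the matched pool is
  exhausted within one permutation) slightly underestimates the null
  variance when the non-significant pool is small relative to the
  significant set.
* `pas_disruption` calls motif creation/destruction only when the caller
  supplies allele-resolved hexamer sequence; it does not recompute motifs
  from a genome.
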