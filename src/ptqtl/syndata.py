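"""Synthetic cohort generator for post-transcriptional QTL analysis.

Generates every input the pipeline consumes at desk scale, with the
statistical structure the association models assume, plus ground-truth
records for parameter-recovery tests:

* LD-structured biallelic genotypes for ~80 donors via a haplotype-copying
  model (a small founder-haplotype pool per LD block, per-donor
  recombination), with optional relatedness induced by haplotype sharing
  between donor pairs;
* binomial or beta-binomial editing read counts with logit-scale
  cis-genotype effects, a global-editing latent factor and a batch
  (FACS-sorter) factor;
* multinomial 3'UTR isoform counts with a logistic-normal usage model and
  genotype effects on one isoform's log-odds;
* GWAS summary statistics from an independent cohort drawn from the same
  haplotype pool, with shared, distinct, or absent causal variants;
* site/variant annotations (genomic region, Alu flag, RNA-structure
  category with optional planted enrichment, PAS motif intervals).

Every operation is deterministic given the config (each derives its own
substream from ``config.seed``), so identical configs reproduce identical
datasets regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .apa import IsoformCountTable
from .editing import EditCountMatrix
from .qtlmap import GenotypeMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "GWASSummary",
    "AnnotationSet",
    "simulate_genotypes",
    "simulate_editing_dataset",
    "simulate_apa_dataset",
    "simulate_gwas",
    "simulate_annotations",
    "gene_models",
    "write_dataset",
]

STRUCTURE_CATEGORIES = ("stem", "hairpin loop", "interior loop", "bulge",
                        "multiloop", "exterior")
# baseline probabilities for RNA-structure categories around edit sites;
# stem dominates, as expected for ADAR substrates formed by IRAlu pairs
STRUCTURE_BASELINE = (0.25, 0.10, 0.20, 0.12, 0.10, 0.23)

REGION_CLASSES = ("intron", "3'UTR", "CDS", "5'UTR", "noncoding")
REGION_PROBS = (0.55, 0.30, 0.05, 0.04, 0.06)


@dataclass
class SimConfig:
    """Study conditions of the simulated cohort.

    Defaults emulate the real design: ~80 sorted donors per cell type,
    imputed genotypes at MAF >= 0.01, tens of reads of coverage per edit
    site, a latent global-editing factor and a FACS-sorter batch factor,
    and ~10% of phenotypes carrying a cis effect.
    """

    n_donors: int = 80
    n_variants: int = 2000
    ld_block_size: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_edit_sites: int = 200
    frac_edit_qtl: float = 0.1
    beta_edit: float = 1.0           # logit-scale effect per minor allele
    mean_coverage: float = 50.0
    overdispersion_rho: float = 0.0  # beta-binomial intraclass correlation
    global_factor_sd: float = 0.5    # logit-scale SD of the latent factor
    batch_effect_sd: float = 0.5     # logit-scale SD of per-site batch shifts
    n_apa_genes: int = 150
    isoforms_per_gene: tuple[int, int] = (2, 4)
    beta_apa: float = 1.0            # logistic-scale effect on isoform usage
    frac_apa_qtl: float = 0.1
    frac_related_pairs: float = 0.0
    gwas_scenario: str = "shared"    # shared | distinct | null
    seed: int = 0
    # generator internals
    n_founder_haplotypes: int = 8
    recomb_prob: float = 0.01        # per adjacent-variant founder switch
    gwas_n: int = 5000
    gwas_beta: float = 0.3           # trait SD units per allele; at n=5000
                                     # this clears 5e-8 down to MAF ~0.05
    min_causal_maf: float = 0.05   # eligibility floor for planted cis variants
    gene_length: int = 60_000
    gene_pitch: int = 150_000
    mean_gene_depth: float = 200.0
    apa_noise_sd: float = 0.5        # logistic-normal donor noise

    def validate(self) -> None:
        if self.n_donors < 4 or self.n_variants < 1:
            raise ValueError("degenerate config: need n_donors >= 4 and variants")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("frac_edit_qtl", "frac_apa_qtl", "frac_related_pairs"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValueError("overdispersion_rho must be in [0,1)")
        if self.gwas_scenario not in ("shared", "distinct", "null"):
            raise ValueError("gwas_scenario must be shared|distinct|null")


@dataclass
class GroundTruth:
    """Planted parameters for recovery tests."""

    causal_pairs: pd.DataFrame      # phenotype_id, variant_id, beta
    latent_factor: np.ndarray       # per-donor global-editing factor
    batch: pd.Series                # donor -> batch label
    gwas_causal_variant: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal_pairs": self.causal_pairs.to_dict(orient="records"),
                "latent_factor": list(map(float, self.latent_factor)),
                "batch": self.batch.to_dict(),
                "gwas_causal_variant": self.gwas_causal_variant,
            },
            indent=1,
        )


@dataclass
class GWASSummary:
    """Per-variant marginal summary statistics of a quantitative trait."""

    table: pd.DataFrame  # variant_id, chrom, pos, a1, a2, beta, se, p
    causal_variant: str | None


@dataclass
class AnnotationSet:
    site_annotations: pd.DataFrame     # site_id, region, alu, gene_id
    variant_annotations: pd.DataFrame  # variant_id, structure, distance, maf


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((int(config.seed) % (2**31), stream))


# ---------------------------------------------------------------------------
# genome layout


def gene_models(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene layout shared by all simulation operations.

    Genes are tiled along two chromosomes; each gene carries a TSS/TTS,
    strand, and two introns (for splice-distance profiling). Enough genes
    are laid out to host both the editing sites and the APA genes.
    """
    n_genes = max(config.n_apa_genes, -(-config.n_edit_sites // 3), 1)
    rows = []
    per_chrom = [0, 0]
    for g in range(n_genes):
        c = g % 2
        i = per_chrom[c]
        per_chrom[c] += 1
        start = 10_000 + i * config.gene_pitch
        end = start + config.gene_length - 1
        strand = "+" if g % 4 < 2 else "-"
        tss, tts = (start, end) if strand == "+" else (end, start)
        third = config.gene_length // 3
        introns = [(start + third // 2, start + third),
                   (start + 2 * third, start + 2 * third + third // 2)]
        rows.append(
            {"gene_id": f"GENE{g:04d}", "chrom": f"chr{c + 1}", "start": start,
             "end": end, "strand": strand, "tss": tss, "tts": tts,
             "intron_starts": introns[0][0], "intron_ends": introns[0][1],
             "intron2_start": introns[1][0], "intron2_end": introns[1][1]}
        )
    return pd.DataFrame(rows)


def _chrom_lengths(config: SimConfig) -> dict[str, int]:
    genes = gene_models(config)
    out = {}
    for chrom, sub in genes.groupby("chrom"):
        out[chrom] = int(sub["end"].max()) + 20_000
    return out


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """LD-structured dosages via haplotype copying from founder pools.

    Variants are placed uniformly along the genome and partitioned into
    consecutive LD blocks of ``ld_block_size``. Per block a pool of
    ``n_founder_haplotypes`` founders is drawn so that each variant's
    founder-pool frequency matches a target MAF from ``maf_range``; each
    donor haplotype copies a founder along the block, switching founders
    with probability ``recomb_prob`` per variant. Adjacent variants in a
    block are therefore correlated; blocks are independent. Relatedness:
    ``frac_related_pairs`` of donor pairs share one full haplotype.
    """
    config.validate()
    rng = _rng(config, 1)
    chrom_len = _chrom_lengths(config)
    genes = gene_models(config)
    # variants proportional to chromosome length
    total_len = sum(chrom_len.values())
    positions, chroms = [], []
    remaining = config.n_variants
    for ci, (chrom, clen) in enumerate(sorted(chrom_len.items())):
        k = remaining if ci == len(chrom_len) - 1 else int(
            round(config.n_variants * clen / total_len))
        k = min(k, remaining)
        remaining -= k
        pos = np.sort(rng.choice(np.arange(1, clen + 1), size=k, replace=False))
        positions.append(pos)
        chroms.extend([chrom] * k)
    pos_all = np.concatenate(positions)
    n_var = len(pos_all)

    F = config.n_founder_haplotypes
    lo, hi = config.maf_range
    target = rng.uniform(lo, hi, size=n_var)
    # founder pools and donor haplotypes, block by block
    n_hap = 2 * config.n_donors
    haplotypes = np.zeros((n_hap, n_var), dtype=np.int8)
    founder_store = []
    start = 0
    while start < n_var:
        stop = start
        # blocks never span chromosomes
        chrom0 = chroms[start]
        while (stop < n_var and stop - start < config.ld_block_size
               and chroms[stop] == chrom0):
            stop += 1
        m = stop - start
        founders = np.zeros((F, m), dtype=np.int8)
        for v in range(m):
            k = int(np.clip(round(target[start + v] * F), 1, F - 1))
            carriers = rng.choice(F, size=k, replace=False)
            founders[carriers, v] = 1
        founder_store.append((start, stop, founders))
        choice = rng.integers(0, F, size=n_hap)
        for v in range(m):
            if v > 0:
                switch = rng.random(n_hap) < config.recomb_prob
                if switch.any():
                    choice = np.where(switch, rng.integers(0, F, size=n_hap), choice)
            haplotypes[:, start + v] = founders[choice, v]
        start = stop

    # relatedness: duplicate haplotypes between disjoint donor pairs
    # (monozygotic-twin-like pairs, the worst case for unadjusted tests)
    n_pairs = int(round(config.frac_related_pairs * config.n_donors / 2))
    order = rng.permutation(config.n_donors)
    for p in range(n_pairs):
        a, b = order[2 * p], order[2 * p + 1]
        haplotypes[2 * b] = haplotypes[2 * a]
        haplotypes[2 * b + 1] = haplotypes[2 * a + 1]

    dosage = (haplotypes[0::2] + haplotypes[1::2]).astype(float)
    donors = [f"D{i:03d}" for i in range(config.n_donors)]
    var_pos = pos_all
    gene_id = np.full(n_var, None, dtype=object)
    for g in genes.itertuples(index=False):
        sel = (np.array(chroms) == g.chrom) & (var_pos >= g.start) & (var_pos <= g.end)
        gene_id[sel] = g.gene_id
    variants = pd.DataFrame(
        {"id": [f"rs{i:05d}" for i in range(n_var)], "chrom": chroms,
         "pos": var_pos.astype(int), "ref": "A", "alt": "G", "gene_id": gene_id}
    )
    geno = GenotypeMatrix(donors, variants, dosage,
                          haplotype_pool=(founder_store, config.recomb_prob))
    return geno


def _draw_haplotypes_from_pool(
    geno: GenotypeMatrix, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    founder_store, recomb = geno.haplotype_pool
    n_var = geno.n_variants
    haps = np.zeros((n_hap, n_var), dtype=np.int8)
    F = founder_store[0][2].shape[0]
    for start, stop, founders in founder_store:
        choice = rng.integers(0, F, size=n_hap)
        for v in range(stop - start):
            if v > 0:
                switch = rng.random(n_hap) < recomb
                if switch.any():
                    choice = np.where(switch, rng.integers(0, F, size=n_hap), choice)
            haps[:, start + v] = founders[choice, v]
    return haps


# ---------------------------------------------------------------------------
# editing phenotypes


def _negbin_coverage(rng, mean, shape, size):
    # negative binomial with dispersion "size" parameter 5: realistic
    # RNA-seq depth variability around the mean
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size)


def simulate_editing_dataset(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[EditCountMatrix, GroundTruth]:
    """Editing read counts under the binomial-GLM generative model.

    For each site i and donor j:
        logit(rate_ij) = alpha_i + beta_i * g_j + global_factor_sd * u_j
                         + delta_i * 1[batch_j = "sorterB"]
    with u_j ~ N(0,1) the latent global-editing factor and delta_i ~
    N(0, batch_effect_sd) the per-site batch shift. Coverage is negative
    binomial (size 5) around ``mean_coverage``; edited counts are binomial,
    or beta-binomial with intraclass correlation ``overdispersion_rho``.
    A fraction ``frac_edit_qtl`` of sites receives a cis effect
    ``beta_edit`` from a variant in the same gene within 100 kb.
    """
    config.validate()
    if geno.n_variants == 0:
        raise ValueError("empty genotype matrix")
    rng = _rng(config, 2)
    genes = gene_models(config)
    n_sites = config.n_edit_sites
    site_gene = genes.iloc[np.arange(n_sites) % len(genes)].reset_index(drop=True)
    pos = (site_gene["start"].to_numpy()
           + rng.integers(0, config.gene_length, size=n_sites))
    sites = pd.DataFrame(
        {"id": [f"site{i:04d}" for i in range(n_sites)],
         "chrom": site_gene["chrom"], "pos": pos.astype(int),
         "ref": "A", "alt": "G", "strand": site_gene["strand"],
         "gene_id": site_gene["gene_id"]}
    )

    n_causal = int(round(config.frac_edit_qtl * n_sites))
    causal_rows = []
    beta_site = np.zeros(n_sites)
    g_causal = np.zeros((config.n_donors, n_sites))
    var = geno.variants
    informative = (var["maf"].to_numpy() >= config.min_causal_maf)
    candidates_per_site = []
    for i in range(n_sites):
        in_gene = (var["gene_id"] == sites.loc[i, "gene_id"]).to_numpy()
        near = np.abs(var["pos"].to_numpy() - sites.loc[i, "pos"]) <= 100_000
        candidates_per_site.append(np.flatnonzero(in_gene & near & informative))
    eligible_sites = [i for i in range(n_sites) if len(candidates_per_site[i])]
    if n_causal > 0 and not eligible_sites:
        raise ValueError("no variant available in any cis window for causal sites")
    chosen = rng.choice(eligible_sites, size=min(n_causal, len(eligible_sites)),
                        replace=False)
    for i in chosen:
        vidx = int(rng.choice(candidates_per_site[i]))
        beta_site[i] = config.beta_edit
        g_causal[:, i] = geno.dosage[:, vidx]
        causal_rows.append(
            {"phenotype_id": sites.loc[i, "id"],
             "variant_id": var.loc[vidx, "id"], "beta": config.beta_edit}
        )

    u = rng.standard_normal(config.n_donors)
    batch = pd.Series(
        np.where(rng.permutation(config.n_donors) % 2 == 0, "sorterA", "sorterB"),
        index=geno.donors, name="batch",
    )
    is_b = (batch == "sorterB").to_numpy().astype(float)
    delta = rng.normal(0.0, config.batch_effect_sd, size=n_sites)
    alpha = rng.normal(np.log(0.2 / 0.8), 0.8, size=n_sites)

    logit = (alpha[:, None]
             + beta_site[:, None] * g_causal.T
             + config.global_factor_sd * u[None, :]
             + delta[:, None] * is_b[None, :])
    rate = 1.0 / (1.0 + np.exp(-logit))
    total = _negbin_coverage(rng, config.mean_coverage, 5.0,
                             (n_sites, config.n_donors))
    rho = config.overdispersion_rho
    if rho > 0:
        a = rate * (1.0 - rho) / rho
        b = (1.0 - rate) * (1.0 - rho) / rho
        p = rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))
        edited = rng.binomial(total, p)
    else:
        edited = rng.binomial(total, rate)

    counts = EditCountMatrix(sites, list(geno.donors), edited, total)
    truth = GroundTruth(
        causal_pairs=pd.DataFrame(causal_rows,
                                  columns=["phenotype_id", "variant_id", "beta"]),
        latent_factor=u, batch=batch,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# APA phenotypes


def simulate_apa_dataset(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[IsoformCountTable, GroundTruth]:
    """Multinomial 3'UTR isoform counts with logistic-normal usage.

    Per gene, isoform log-weights are theta_k + N(0, apa_noise_sd) per
    donor; for causal genes a cis variant adds ``beta_apa * dosage`` to
    the first isoform's log-weight. Counts are multinomial given a
    negative-binomial gene depth. Isoform metadata carries the 3'UTR
    span, length, and a PAS hexamer interval at each isoform's 3' end.
    """
    config.validate()
    if geno.n_variants == 0:
        raise ValueError("empty genotype matrix")
    rng = _rng(config, 3)
    genes = gene_models(config).iloc[: config.n_apa_genes].reset_index(drop=True)
    lo, hi = config.isoforms_per_gene
    var = geno.variants
    informative = var["maf"].to_numpy() >= config.min_causal_maf

    iso_rows, counts_rows = [], []
    n_causal = int(round(config.frac_apa_qtl * len(genes)))
    causal_genes = set(rng.choice(len(genes), size=n_causal, replace=False).tolist())
    causal_rows = []
    base_lengths = np.array([400, 1000, 1800, 2800, 4000])
    for gi, g in genes.iterrows():
        m = int(rng.integers(lo, hi + 1))
        if g.strand == "+":
            utr_start = g.end - 3000
            ends = utr_start + base_lengths[:m] + rng.integers(0, 80, size=m)
            starts = np.full(m, utr_start)
        else:
            utr_end = g.start + 3000
            starts = utr_end - base_lengths[:m] - rng.integers(0, 80, size=m)
            ends = np.full(m, utr_end)
        lengths = ends - starts + 1
        theta = rng.normal(0.0, 1.0, size=m)
        eff = np.zeros((config.n_donors, m))
        if gi in causal_genes:
            near = ((np.abs(var["pos"].to_numpy() - starts.min()) <= 25_000)
                    | (np.abs(var["pos"].to_numpy() - ends.max()) <= 25_000))
            cand = np.flatnonzero((var["chrom"] == g.chrom).to_numpy()
                                  & near & informative)
            if len(cand):
                vidx = int(rng.choice(cand))
                eff[:, 0] = config.beta_apa * geno.dosage[:, vidx]
                causal_rows.append(
                    {"phenotype_id": f"{g.gene_id}_P1",
                     "variant_id": var.loc[vidx, "id"], "beta": config.beta_apa}
                )
        logw = (theta[None, :] + eff
                + rng.normal(0.0, config.apa_noise_sd, size=(config.n_donors, m)))
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        depth = _negbin_coverage(rng, config.mean_gene_depth, 5.0, config.n_donors)
        cnt = np.zeros((m, config.n_donors), dtype=int)
        for j in range(config.n_donors):
            cnt[:, j] = rng.multinomial(depth[j], w[j])
        for k in range(m):
            iso_rows.append(
                {"id": f"{g.gene_id}_P{k + 1}", "gene_id": g.gene_id,
                 "chrom": g.chrom, "utr_start": int(starts[k]),
                 "utr_end": int(ends[k]), "strand": g.strand,
                 "length": int(lengths[k]),
                 "pas_start": int(ends[k] - 29) if g.strand == "+" else int(starts[k] + 24),
                 "pas_end": int(ends[k] - 24) if g.strand == "+" else int(starts[k] + 29)}
            )
        counts_rows.append(cnt)

    isoforms = pd.DataFrame(iso_rows)
    counts = np.vstack(counts_rows)
    table = IsoformCountTable(isoforms, list(geno.donors), counts)
    truth = GroundTruth(
        causal_pairs=pd.DataFrame(causal_rows,
                                  columns=["phenotype_id", "variant_id", "beta"]),
        latent_factor=np.zeros(config.n_donors),
        batch=pd.Series(["sorterA"] * config.n_donors, index=geno.donors, name="batch"),
    )
    return table, truth


# ---------------------------------------------------------------------------
# GWAS summaries


def simulate_gwas(
    geno: GenotypeMatrix,
    config: SimConfig,
    qtl_truth: GroundTruth | None = None,
) -> GWASSummary:
    """Marginal GWAS statistics from an independent cohort.

    An independent sample of ``gwas_n`` individuals is drawn from the same
    founder-haplotype pool, so LD matches the QTL cohort. Scenarios:
    ``shared`` — the trait's causal variant is a QTL causal variant;
    ``distinct`` — the causal variant has r^2 < 0.2 with every QTL causal
    variant; ``null`` — no effect, and noise is redrawn until no variant
    reaches p < 5e-8.
    """
    config.validate()
    rng = _rng(config, 4)
    if geno.haplotype_pool is None:
        raise ValueError("genotype matrix lacks its haplotype pool")
    haps = _draw_haplotypes_from_pool(geno, 2 * config.gwas_n, rng)
    G = (haps[0::2] + haps[1::2]).astype(float)
    var = geno.variants
    scenario = config.gwas_scenario

    qtl_causal_ids = []
    if qtl_truth is not None and len(qtl_truth.causal_pairs):
        qtl_causal_ids = qtl_truth.causal_pairs["variant_id"].tolist()

    causal_id = None
    if scenario == "shared":
        if not qtl_causal_ids:
            raise ValueError("shared scenario needs QTL ground truth with causal pairs")
        causal_id = qtl_causal_ids[0]
    elif scenario == "distinct":
        causal_idx = _pick_distinct_variant(geno, qtl_causal_ids, rng)
        causal_id = var.loc[causal_idx, "id"]

    y = rng.standard_normal(config.gwas_n)
    if causal_id is not None:
        g = G[:, geno.variant_index(causal_id)]
        y = y + config.gwas_beta * g

    for attempt in range(50):
        beta, se, p = _marginal_scan(G, y)
        if scenario != "null" or np.nanmin(p) >= 5e-8:
            break
        y = rng.standard_normal(config.gwas_n)  # rejection sampling under the null
    table = pd.DataFrame(
        {"variant_id": var["id"], "chrom": var["chrom"], "pos": var["pos"],
         "a1": var["alt"], "a2": var["ref"], "beta": beta, "se": se, "p": p}
    )
    return GWASSummary(table=table, causal_variant=causal_id)


def _pick_distinct_variant(
    geno: GenotypeMatrix, qtl_causal_ids: list[str], rng: np.random.Generator
) -> int:
    d = geno.dosage
    sd = d.std(axis=0)
    ok = sd > 0
    maf = geno.variants["maf"].to_numpy()
    ok &= maf >= 0.1  # need power at the GWAS sample size
    if qtl_causal_ids:
        for vid in qtl_causal_ids:
            gc = d[:, geno.variant_index(vid)]
            if gc.std() == 0:
                continue
            with np.errstate(invalid="ignore"):
                r = np.array([
                    np.corrcoef(d[:, k], gc)[0, 1] if sd[k] > 0 else 0.0
                    for k in range(d.shape[1])
                ])
            ok &= (r ** 2) < 0.2
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        raise ValueError(
            "distinct scenario impossible: no variant with r^2 < 0.2 to every "
            "QTL causal variant (LD blocks too small or too few variants)"
        )
    return int(rng.choice(idx))


def _marginal_scan(G: np.ndarray, y: np.ndarray):
    n = G.shape[0]
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    sxx = (Gc ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Gc * yc[:, None]).sum(axis=0) / sxx
        resid_ss = (yc ** 2).sum() - beta ** 2 * sxx
        se = np.sqrt(np.maximum(resid_ss, 0) / (n - 2) / sxx)
        t = beta / se
    from scipy import stats as _st

    p = 2.0 * _st.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(p), p, 1.0)
    beta = np.where(np.isfinite(beta), beta, 0.0)
    se = np.where(np.isfinite(se), se, np.nan)
    return beta, se, p


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    sites: pd.DataFrame,
    variants: pd.DataFrame,
    config: SimConfig,
    causal_variants: set[str] | frozenset[str] = frozenset(),
    stem_enrichment: float = 1.0,
) -> AnnotationSet:
    """Region/Alu annotations for sites; structure categories for variants.

    Each site gets exactly one genomic region class and an Alu flag (most
    A-to-I sites fall in Alu repeats). Each variant gets one RNA-structure
    category; for causal variants the probability of "stem" is multiplied
    by ``stem_enrichment`` (renormalized), planting the enrichment the
    permutation test should detect. The variant table also records MAF and
    distance to the nearest edit site, the two matching covariates of the
    permutation null.
    """
    rng = _rng(config, 5)
    region = rng.choice(REGION_CLASSES, size=len(sites), p=REGION_PROBS)
    alu = rng.random(len(sites)) < 0.8
    site_ann = pd.DataFrame(
        {"site_id": sites["id"].to_numpy(), "region": region, "alu": alu,
         "gene_id": sites.get("gene_id", pd.Series([None] * len(sites))).to_numpy()}
    )

    base = np.array(STRUCTURE_BASELINE)
    p_causal = base.copy()
    stem_i = STRUCTURE_CATEGORIES.index("stem")
    p_causal[stem_i] = min(base[stem_i] * stem_enrichment, 0.9)
    scale = (1.0 - p_causal[stem_i]) / (1.0 - base[stem_i])
    for k in range(len(p_causal)):
        if k != stem_i:
            p_causal[k] = base[k] * scale

    site_pos = sites["pos"].to_numpy()
    site_chrom = sites["chrom"].to_numpy()
    cats, dists = [], []
    for v in variants.itertuples(index=False):
        probs = p_causal if v.id in causal_variants else base
        cats.append(rng.choice(STRUCTURE_CATEGORIES, p=probs))
        same = site_pos[site_chrom == v.chrom]
        dists.append(int(np.min(np.abs(same - v.pos))) if len(same) else -1)
    var_ann = pd.DataFrame(
        {"variant_id": variants["id"].to_numpy(), "structure": cats,
         "distance": dists,
         "maf": variants["maf"].to_numpy() if "maf" in variants else np.nan}
    )
    return AnnotationSet(site_annotations=site_ann, variant_annotations=var_ann)


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(
    outdir: str | Path,
    config: SimConfig,
    geno: GenotypeMatrix,
    edits: EditCountMatrix,
    edit_truth: GroundTruth,
    isoforms: IsoformCountTable,
    apa_truth: GroundTruth,
    gwas: GWASSummary | None = None,
    annotations: AnnotationSet | None = None,
) -> None:
    """Write a complete simulated dataset as plain-text files.

    Genotypes as VCF (GT field) and dosage TSV, edit counts as long TSV,
    isoform counts and metadata TSVs, annotations as BED (0-based
    half-open) plus a variant TSV, GWAS summary TSV, ground truth and
    config as JSON.
    """
    from . import io as ptio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ptio.write_vcf(outdir / "genotypes.vcf", geno)
    ptio.write_dosage_tsv(outdir / "dosages.tsv", geno)
    edits.to_long().to_csv(outdir / "edit_counts.tsv", sep="\t", index=False)
    isoforms.isoforms.to_csv(outdir / "isoform_meta.tsv", sep="\t", index=False)
    pd.DataFrame(isoforms.counts, index=isoforms.isoforms["id"],
                 columns=isoforms.donors).to_csv(
        outdir / "isoform_counts.tsv", sep="\t", index_label="isoform_id")
    (outdir / "edit_truth.json").write_text(edit_truth.to_json())
    (outdir / "apa_truth.json").write_text(apa_truth.to_json())
    cfg = asdict(config)
    (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=1))
    if gwas is not None:
        gwas.table.to_csv(outdir / "gwas_summary.tsv", sep="\t", index=False)
    if annotations is not None:
        ptio.write_sites_bed(outdir / "edit_sites.bed", edits.sites)
        annotations.site_annotations.to_csv(
            outdir / "site_annotations.tsv", sep="\t", index=False)
        annotations.variant_annotations.to_csv(
            outdir / "variant_annotations.tsv", sep="\t", index=False)
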