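"""End-to-end orchestration: phenotypes -> covariates -> cis scan -> FDR.

Both pipelines follow the same skeleton: build phenotypes, assemble
covariates (3 genotype MDS axes, optional batch factor, a tuned number of
global phenotype PCs), test every cis variant per phenotype, correct
hierarchically (eigenMT locally, BH globally), and pick one primary
variant per significant phenotype. The edQTL pipeline uses the binomial
GLM on read counts; the apaQTL pipeline the kinship-aware LMM on
normalized poly(A) usage with leave-one-chromosome-out kinship.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import editing, apa
from .qtlmap import (
    GenotypeMatrix,
    KinshipMatrix,
    cis_pairs,
    compute_ibs_kinship,
    eigenmt_meff,
    filter_variants_by_genotype_class,
    fit_binomial_edqtl,
    fit_lmm_apaqtl,
    fit_lmm_null,
    genotype_mds,
    hierarchical_fdr,
    optimize_covariates,
    phenotype_pcs,
    select_primary,
)

__all__ = ["RunConfig", "QTLResult", "run_edqtl_pipeline", "run_apaqtl_pipeline",
           "validate_inputs"]


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults reproduce the standard design."""

    cell_type: str = "progenitor"
    edqtl_window: int = 100_000
    apaqtl_window: int = 25_000
    min_total: int = 10
    min_edited: int = 2
    min_donor_frac: float = 0.85
    pau_min_count: int = 10
    pau_min_donor_frac: float = 0.10
    alpha: float = 0.05
    n_mds: int = 3
    pc_grid: tuple[int, ...] = (0, 1, 2)
    use_batch_covariate: bool = True
    use_loco: bool = True
    robust_edqtl_variance: bool = True
    seed: int = 0
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class QTLResult:
    """Bundle of one pipeline run."""

    associations: pd.DataFrame      # all nominal tests at the chosen PC count
    phenotypes: pd.DataFrame        # p_min, m_eff, p_local, q_global, significant
    primaries: pd.DataFrame         # one row per significant phenotype
    chosen_pcs: int
    pc_counts: dict[int, int]
    manifest: dict
    refit: object = None            # conditional-refit callable for colocalization

    @property
    def n_significant(self) -> int:
        return int(self.phenotypes["significant"].sum())

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        self.primaries.to_csv(outdir / "primaries.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


def _batch_onehot(batch: pd.Series | None, donors: list[str]) -> np.ndarray | None:
    if batch is None:
        return None
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return None
    cols = [
        (batch.reindex(donors) == lev).to_numpy(dtype=float) for lev in levels[1:]
    ]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# edQTL pipeline


def run_edqtl_pipeline(
    geno: GenotypeMatrix,
    counts: editing.EditCountMatrix,
    config: RunConfig | None = None,
    batch: pd.Series | None = None,
) -> QTLResult:
    """Editing-site discovery, binomial cis scan, eigenMT-FDR, primaries.

    Stages: discover sites (coverage/edited thresholds over donors) ->
    edit rates -> covariates (genotype MDS, batch one-hot, tuned global
    editing PCs) -> same-gene cis variants within the window -> genotype
    class filter on each site's supporting donors -> binomial GLM per
    pair -> eigenMT local adjustment + BH -> primary variant per
    significant site.
    """
    if config is None:
        config = RunConfig()
    kept_ids, support = editing.discover_edit_sites(
        counts, config.min_total, config.min_edited, config.min_donor_frac
    )
    manifest = {
        "config_hash": config.config_hash(),
        "cell_type": config.cell_type,
        "n_sites_input": counts.n_sites,
        "n_sites_discovered": len(kept_ids),
    }
    empty = pd.DataFrame(columns=["phenotype_id", "variant_id", "chrom", "pos",
                                  "beta", "se", "p_nominal", "distance"])
    if not kept_ids:
        phen = pd.DataFrame(columns=["phenotype_id", "p_min", "m_eff", "p_local",
                                     "q_global", "significant"])
        return QTLResult(empty, phen, empty, 0, {}, manifest)

    kept = counts.subset_sites(kept_ids)
    rates = editing.compute_edit_rates(kept)
    mds = genotype_mds(geno, config.n_mds)
    bat = _batch_onehot(batch, geno.donors) if config.use_batch_covariate else None
    pairs = cis_pairs(
        kept.sites.rename(columns={"id": "id"}), geno,
        window=config.edqtl_window, same_gene=True,
    )

    def scan(k: int):
        pcs = phenotype_pcs(rates.T, k)
        cov = np.column_stack(
            [c for c in (mds, bat, pcs) if c is not None and c.shape[1] > 0]
        ) if any(c is not None and c.shape[1] > 0 for c in (mds, bat, pcs)) else None
        assoc_rows = []
        phen_rows = []
        for i, sid in enumerate(kept.sites["id"]):
            vidx = pairs.get(sid, np.array([], dtype=int))
            donors_mask = support[sid]
            didx = np.flatnonzero(donors_mask)
            if len(vidx) == 0 or len(didx) == 0:
                continue
            vmask = filter_variants_by_genotype_class(geno, didx, vidx)
            vkeep = vidx[vmask]
            if len(vkeep) == 0:
                continue
            site_pos = int(kept.sites.loc[i, "pos"])
            p_list = []
            for v in vkeep:
                res = fit_binomial_edqtl(
                    kept.edited[i, didx], kept.total[i, didx],
                    geno.dosage[didx, v],
                    None if cov is None else cov[didx],
                    robust=config.robust_edqtl_variance,
                )
                vrow = geno.variants.iloc[v]
                assoc_rows.append(
                    (sid, vrow["id"], vrow["chrom"], int(vrow["pos"]), res.beta,
                     res.se, res.p_nominal, abs(int(vrow["pos"]) - site_pos),
                     res.flag)
                )
                if not np.isnan(res.p_nominal):
                    p_list.append(res.p_nominal)
            if not p_list:
                continue
            meff = eigenmt_meff(geno.dosage[np.ix_(didx, vkeep)])
            phen_rows.append((sid, min(p_list), meff))
        assoc = pd.DataFrame(
            assoc_rows,
            columns=["phenotype_id", "variant_id", "chrom", "pos", "beta", "se",
                     "p_nominal", "distance", "flag"],
        )
        phen = pd.DataFrame(phen_rows, columns=["phenotype_id", "p_min", "m_eff"])
        phen = hierarchical_fdr(phen, alpha=config.alpha)
        return assoc, phen

    cache: dict[int, tuple] = {}

    def count_for_k(k: int) -> int:
        cache[k] = scan(k)
        return int(cache[k][1]["significant"].sum())

    chosen_k, pc_counts = optimize_covariates(count_for_k, config.pc_grid)
    assoc, phen = cache[chosen_k]
    primaries = _collect_primaries(assoc, phen)
    manifest.update(
        {"n_sites_tested": len(phen), "n_associations": len(assoc),
         "chosen_pcs": chosen_k, "pc_counts": pc_counts,
         "n_significant": int(phen["significant"].sum()), "seed": config.seed}
    )

    pcs = phenotype_pcs(rates.T, chosen_k)
    base_cov = [c for c in (mds, bat, pcs) if c is not None and c.shape[1] > 0]

    def refit(phenotype_id: str, extra: np.ndarray) -> float:
        """Conditional p of the phenotype's primary variant given an extra covariate."""
        prow = primaries[primaries["phenotype_id"] == phenotype_id]
        if prow.empty:
            return np.nan
        v = geno.variant_index(prow.iloc[0]["variant_id"])
        i = kept.site_index(phenotype_id)
        didx = np.flatnonzero(support[phenotype_id])
        cov = np.column_stack(base_cov + [np.asarray(extra)[:, None]]) \
            if base_cov else np.asarray(extra)[:, None]
        g_extra = cov[didx, -1]
        g_test = geno.dosage[didx, v]
        if np.ptp(g_extra) == 0 or abs(np.corrcoef(g_extra, g_test)[0, 1]) > 1 - 1e-12:
            return np.nan  # collinear conditional design
        res = fit_binomial_edqtl(
            kept.edited[i, didx], kept.total[i, didx], g_test, cov[didx],
            robust=config.robust_edqtl_variance,
        )
        return res.p_nominal

    result = QTLResult(assoc, phen, primaries, chosen_k, pc_counts, manifest, refit)
    if config.outdir:
        result.write(config.outdir)
    return result


def _collect_primaries(assoc: pd.DataFrame, phen: pd.DataFrame) -> pd.DataFrame:
    rows = []
    sig = phen[phen["significant"]]
    for sid in sig["phenotype_id"]:
        sub = assoc[assoc["phenotype_id"] == sid]
        try:
            best = select_primary(sub)
        except ValueError:
            continue
        rows.append(best)
    if not rows:
        return pd.DataFrame(columns=list(assoc.columns))
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["is_primary"] = True
    return out


# ---------------------------------------------------------------------------
# apaQTL pipeline


def run_apaqtl_pipeline(
    geno: GenotypeMatrix,
    iso_counts: apa.IsoformCountTable,
    config: RunConfig | None = None,
    batch: pd.Series | None = None,
    kinship: KinshipMatrix | None = None,
) -> QTLResult:
    """PAU phenotypes, kinship-aware LMM cis scan, eigenMT-FDR, primaries.

    Stages: PAU -> expression filter + two-isoform rule -> rank-based
    inverse-normal transform -> IBS kinship (leave-one-chromosome-out
    unless disabled or supplied) -> covariates (MDS, batch, tuned PAU
    PCs) -> cis variants within the window of either UTR end -> genotype
    class filter -> EMMAX per pair -> eigenMT + BH -> primaries.
    """
    if config is None:
        config = RunConfig()
    pau = apa.compute_pau(iso_counts)
    filtered = apa.filter_isoforms(
        pau, iso_counts, config.pau_min_count, config.pau_min_donor_frac,
        seed=config.seed,
    )
    normed = apa.normalize_pau(filtered)
    usable = ~normed.flags["degenerate"].to_numpy()
    manifest = {
        "config_hash": config.config_hash(),
        "cell_type": config.cell_type,
        "n_isoforms_input": len(iso_counts.isoforms),
        "n_isoforms_filtered": len(filtered.isoforms),
        "n_isoforms_testable": int(usable.sum()),
    }
    normed = normed.subset(usable)

    mds = genotype_mds(geno, config.n_mds)
    bat = _batch_onehot(batch, geno.donors) if config.use_batch_covariate else None
    phen_meta = normed.isoforms.rename(
        columns={"utr_start": "start", "utr_end": "end"}
    )[["id", "chrom", "start", "end", "gene_id"]]
    pairs = cis_pairs(phen_meta, geno, window=config.apaqtl_window)
    chroms = sorted(geno.variants["chrom"].unique())
    kinships: dict[str | None, KinshipMatrix] = {}
    if kinship is not None:
        kinships = {c: kinship for c in chroms}
    elif config.use_loco and len(chroms) > 1:
        kinships = {c: compute_ibs_kinship(geno, loco_chrom=c) for c in chroms}
    else:
        k0 = compute_ibs_kinship(geno)
        kinships = {c: k0 for c in chroms}

    Y = normed.normalized

    def scan(k: int):
        pcs = phenotype_pcs(Y.T, k)
        cov_blocks = [c for c in (mds, bat, pcs) if c is not None and c.shape[1] > 0]
        cov = np.column_stack(cov_blocks) if cov_blocks else None
        assoc_rows, phen_rows = [], []
        for i, prow in enumerate(normed.isoforms.itertuples(index=False)):
            pid = prow.id
            vidx = pairs.get(pid, np.array([], dtype=int))
            y = Y[i]
            ok = ~np.isnan(y)
            didx = np.flatnonzero(ok)
            if len(vidx) == 0 or len(didx) < 10:
                continue
            vmask = filter_variants_by_genotype_class(geno, didx, vidx)
            vkeep = vidx[vmask]
            if len(vkeep) == 0:
                continue
            K = kinships[prow.chrom]
            Ksub = KinshipMatrix(
                [geno.donors[j] for j in didx],
                K.values[np.ix_(didx, didx)], K.loco_chrom,
            )
            ctx = fit_lmm_null(y[didx],
                               None if cov is None else cov[didx], Ksub)
            anchor = (int(prow.utr_start), int(prow.utr_end))
            p_list = []
            for v in vkeep:
                res, _ = fit_lmm_apaqtl(
                    y[didx], geno.dosage[didx, v],
                    None if cov is None else cov[didx], Ksub, context=ctx,
                )
                vrow = geno.variants.iloc[v]
                dist = min(abs(int(vrow["pos"]) - a) for a in anchor)
                assoc_rows.append(
                    (pid, vrow["id"], vrow["chrom"], int(vrow["pos"]), res.beta,
                     res.se, res.p_nominal, dist, res.flag)
                )
                if not np.isnan(res.p_nominal):
                    p_list.append(res.p_nominal)
            if not p_list:
                continue
            meff = eigenmt_meff(geno.dosage[np.ix_(didx, vkeep)])
            phen_rows.append((pid, min(p_list), meff))
        assoc = pd.DataFrame(
            assoc_rows,
            columns=["phenotype_id", "variant_id", "chrom", "pos", "beta", "se",
                     "p_nominal", "distance", "flag"],
        )
        phen = pd.DataFrame(phen_rows, columns=["phenotype_id", "p_min", "m_eff"])
        phen = hierarchical_fdr(phen, alpha=config.alpha)
        return assoc, phen

    cache: dict[int, tuple] = {}

    def count_for_k(k: int) -> int:
        cache[k] = scan(k)
        return int(cache[k][1]["significant"].sum())

    chosen_k, pc_counts = optimize_covariates(count_for_k, config.pc_grid)
    assoc, phen = cache[chosen_k]
    primaries = _collect_primaries(assoc, phen)
    manifest.update(
        {"n_isoforms_tested": len(phen), "n_associations": len(assoc),
         "chosen_pcs": chosen_k, "pc_counts": pc_counts,
         "n_significant": int(phen["significant"].sum()), "seed": config.seed}
    )

    pcs = phenotype_pcs(Y.T, chosen_k)
    base_cov = [c for c in (mds, bat, pcs) if c is not None and c.shape[1] > 0]
    iso_index = {pid: i for i, pid in enumerate(normed.isoforms["id"])}

    def refit(phenotype_id: str, extra: np.ndarray) -> float:
        prow = primaries[primaries["phenotype_id"] == phenotype_id]
        if prow.empty or phenotype_id not in iso_index:
            return np.nan
        i = iso_index[phenotype_id]
        v = geno.variant_index(prow.iloc[0]["variant_id"])
        y = Y[i]
        didx = np.flatnonzero(~np.isnan(y))
        g_extra = np.asarray(extra)[didx]
        g_test = geno.dosage[didx, v]
        if np.ptp(g_extra) == 0 or abs(np.corrcoef(g_extra, g_test)[0, 1]) > 1 - 1e-12:
            return np.nan
        cov = np.column_stack([c[didx] for c in base_cov] + [g_extra[:, None]]) \
            if base_cov else g_extra[:, None]
        K = kinships[normed.isoforms.loc[i, "chrom"]]
        Ksub = KinshipMatrix([geno.donors[j] for j in didx],
                             K.values[np.ix_(didx, didx)], K.loco_chrom)
        res, _ = fit_lmm_apaqtl(y[didx], g_test, cov, Ksub)
        return res.p_nominal

    result = QTLResult(assoc, phen, primaries, chosen_k, pc_counts, manifest, refit)
    if config.outdir:
        result.write(config.outdir)
    return result


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(
    geno: GenotypeMatrix,
    phenotype_donors: list[str],
    covariate_donors: list[str] | None = None,
    intervals: pd.DataFrame | None = None,
) -> dict:
    """Cross-file sanity report: donor concordance and coordinate checks.

    Fatal (raises) on phenotype donors absent from the genotypes; warns on
    empty BED intervals (start == end) and non-positive variant positions.
    """
    report: dict = {"fatal": [], "warnings": []}
    missing = sorted(set(phenotype_donors) - set(geno.donors))
    if missing:
        report["fatal"].append(f"phenotype donors absent from genotypes: {missing}")
        raise ValueError(report["fatal"][0])
    if covariate_donors is not None:
        miss_cov = sorted(set(phenotype_donors) - set(covariate_donors))
        if miss_cov:
            report["warnings"].append(f"donors missing covariates: {miss_cov}")
    if (geno.variants["pos"] < 1).any():
        report["warnings"].append("variant positions must be 1-based (found < 1)")
    if intervals is not None:
        empty = intervals[intervals["start"] >= intervals["end"]]
        for row in empty.itertuples(index=False):
            report["warnings"].append(
                f"empty interval {row.chrom}:{row.start}-{row.end}"
            )
    for w in report["warnings"]:
        warnings.warn(w)
    report["n_donors"] = geno.n_donors
    report["n_variants"] = geno.n_variants
    return report
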