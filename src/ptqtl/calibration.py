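"""Calibration and recovery studies on synthetic cohorts.

Each function runs one self-contained simulation study — type-I error and
FDR of the editing QTL scan, effect recovery, mixed-model calibration
under relatedness, pi1 / enrichment / colocalization / mediation
behavior — and returns the measured quantity. They power both the
acceptance checks and the reproduction script; every study derives all
randomness from the seed it is given.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import editing, pipeline, poststats, qtlmap, syndata

__all__ = [
    "edqtl_type1_error",
    "edqtl_fdr",
    "edqtl_effect_recovery",
    "eigenmt_oracle_ratio",
    "lmm_vs_ols_alpha",
    "pi1_recovery",
    "enrichment_null_rejection",
    "enrichment_planted_detection",
    "coloc_rate",
    "mediation_forward_recovery",
    "pipeline_determinism",
]


def edqtl_type1_error(seed: int, n_pairs: int = 500, alpha: float = 0.05):
    """Rejection rate of the binomial edQTL test on null site-variant pairs.

    Confounder-free null: no cis effects, no latent factor, no batch
    shifts; each site is tested against one random polymorphic variant.
    """
    cfg = syndata.SimConfig(seed=seed, n_edit_sites=n_pairs, frac_edit_qtl=0.0,
                            global_factor_sd=0.0, batch_effect_sd=0.0)
    geno = syndata.simulate_genotypes(cfg)
    counts, _ = syndata.simulate_editing_dataset(geno, cfg)
    rng = np.random.default_rng(seed)
    rej = n = 0
    i = 0
    while n < n_pairs:
        v = int(rng.integers(geno.n_variants))
        g = geno.dosage[:, v]
        site = i % counts.n_sites
        i += 1
        if i > 5 * n_pairs:
            break
        if np.ptp(g) == 0:
            continue
        res = qtlmap.fit_binomial_edqtl(counts.edited[site], counts.total[site], g)
        if np.isnan(res.p_nominal):
            continue
        rej += res.p_nominal < alpha
        n += 1
    return rej / n, n


def edqtl_fdr(seed: int, n_reps: int = 20, beta: float = 1.5):
    """Empirical FDR of the eigenMT-FDR significant set, 10% non-null sites."""
    false = sig = 0
    for r in range(n_reps):
        cfg = syndata.SimConfig(seed=seed + r, frac_edit_qtl=0.1, beta_edit=beta)
        geno = syndata.simulate_genotypes(cfg)
        counts, truth = syndata.simulate_editing_dataset(geno, cfg)
        res = pipeline.run_edqtl_pipeline(
            geno, counts, pipeline.RunConfig(pc_grid=(0, 1)), batch=truth.batch
        )
        called = set(res.phenotypes.loc[res.phenotypes["significant"],
                                        "phenotype_id"])
        causal = set(truth.causal_pairs["phenotype_id"])
        false += len(called - causal)
        sig += len(called)
    return false / max(sig, 1), sig


def edqtl_effect_recovery(seed: int, n_causal: int = 200, beta: float = 1.0):
    """Mean fitted log-odds effect at planted causal variants (target: beta)."""
    cfg = syndata.SimConfig(seed=seed, n_edit_sites=2 * n_causal,
                            frac_edit_qtl=0.5, beta_edit=beta)
    geno = syndata.simulate_genotypes(cfg)
    counts, truth = syndata.simulate_editing_dataset(geno, cfg)
    rates = editing.compute_edit_rates(counts)
    pcs = qtlmap.phenotype_pcs(rates.T, 1)
    bat = (truth.batch == "sorterB").to_numpy(float)[:, None]
    cov = np.column_stack([bat, pcs])
    betas = []
    for row in truth.causal_pairs.itertuples(index=False):
        i = counts.site_index(row.phenotype_id)
        res = qtlmap.fit_binomial_edqtl(
            counts.edited[i], counts.total[i], geno.dosage_for(row.variant_id),
            cov,
        )
        if not np.isnan(res.beta):
            betas.append(res.beta)
    return float(np.mean(betas)), len(betas)


def eigenmt_oracle_ratio(seed: int, n_donors: int = 200, m: int = 50):
    """m_eff of the windowed estimator over a direct whole-matrix eigen count."""
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 3, (n_donors, m)).astype(float)
    R = np.corrcoef(G, rowvar=False)
    ev = np.sort(np.linalg.eigvalsh(R))[::-1]
    cum = np.cumsum(ev) / ev.sum()
    oracle = int(np.searchsorted(cum, 0.99) + 1)
    return qtlmap.eigenmt_meff(G) / oracle, oracle


def lmm_vs_ols_alpha(seed: int, n_sims: int = 100, tests_per_sim: int = 20,
                     frac_related: float = 0.8, h2: float = 0.9):
    """Type-I error of EMMAX vs naive OLS under twin-pair relatedness.

    The phenotype carries a polygenic background with family covariance
    (normalized kinship), no single-variant effect; each random variant
    tested should be null.
    """
    rej_lmm = rej_ols = n = 0
    for s in range(n_sims):
        cfg = syndata.SimConfig(seed=seed + s, n_donors=80, n_variants=600,
                                frac_related_pairs=frac_related)
        geno = syndata.simulate_genotypes(cfg)
        K = qtlmap.compute_ibs_kinship(geno).values
        rng = np.random.default_rng(seed + s)
        nd = geno.n_donors
        b = np.median(K[~np.eye(nd, dtype=bool)])
        Kn = np.clip((K - b) / (1 - b), 0, None)
        np.fill_diagonal(Kn, 1.0)
        w, U = np.linalg.eigh(h2 * Kn + (1 - h2) * np.eye(nd))
        y = U @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(nd))
        Km = qtlmap.KinshipMatrix(geno.donors, K)
        ctx = qtlmap.fit_lmm_null(y, None, Km)
        ident = qtlmap.KinshipMatrix(geno.donors, np.eye(nd))
        ctx_i = qtlmap.fit_lmm_null(y, None, ident)
        for v in rng.choice(geno.n_variants, tests_per_sim, replace=False):
            g = geno.dosage[:, v]
            if np.ptp(g) == 0:
                continue
            a, _ = qtlmap.fit_lmm_apaqtl(y, g, None, Km, context=ctx)
            o, _ = qtlmap.fit_lmm_apaqtl(y, g, None, ident, context=ctx_i)
            rej_lmm += a.p_nominal < 0.05
            rej_ols += o.p_nominal < 0.05
            n += 1
    return rej_lmm / n, rej_ols / n, n


def pi1_recovery(seed: int, true_pi1: float, n_reps: int = 20, n: int = 5000):
    """Mean pi1 estimate over replicate Beta(0.1,1)/uniform p-value mixtures."""
    ests = []
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        k = int(n * true_pi1)
        p = np.concatenate([rng.beta(0.1, 1, k), rng.uniform(0, 1, n - k)])
        ests.append(1.0 - poststats.estimate_pi0(p))
    return float(np.mean(ests)), n_reps


def _structure_frames(rng, n_sig, n_ns, stem_factor=1.0):
    base = np.array(syndata.STRUCTURE_BASELINE)
    p_sig = base.copy()
    if stem_factor != 1.0:
        p_sig[0] = min(base[0] * stem_factor, 0.9)
        p_sig[1:] = base[1:] * (1 - p_sig[0]) / (1 - base[0])
    def frame(prefix, k, probs):
        return pd.DataFrame(
            {"variant_id": [f"{prefix}{i}" for i in range(k)],
             "structure": rng.choice(syndata.STRUCTURE_CATEGORIES, k, p=probs),
             "maf": rng.uniform(0.05, 0.5, k),
             "distance": rng.integers(1, 800, k)}
        )
    return frame("s", n_sig, p_sig), frame("n", n_ns, base)


def enrichment_null_rejection(seed: int, n_datasets: int = 200,
                              n_perm: int = 200):
    """Rejection rate of the matched-permutation test on null assignments."""
    rej = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in range(n_datasets):
            rng = np.random.default_rng(seed + d)
            sig, ns = _structure_frames(rng, 40, 400)
            out = poststats.structure_enrichment(sig, ns, n_perm=n_perm,
                                                 seed=seed + 10_000 + d)
            p = out.set_index("structure").loc["stem", "p"]
            rej += p < 0.05
    return rej / n_datasets, n_datasets


def enrichment_planted_detection(seed: int, n_datasets: int = 25,
                                 n_perm: int = 200, factor: float = 3.0):
    """Detection rate (p < 0.05) of a planted stem enrichment."""
    det = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in range(n_datasets):
            rng = np.random.default_rng(seed + d)
            sig, ns = _structure_frames(rng, 40, 400, stem_factor=factor)
            out = poststats.structure_enrichment(sig, ns, n_perm=n_perm,
                                                 seed=seed + 10_000 + d)
            det += out.set_index("structure").loc["stem", "p"] < 0.05
    return det / n_datasets, n_datasets


def coloc_rate(seed: int, scenario: str, n_sims: int = 50):
    """Fraction of simulations ending in a colocalized verdict.

    Shared scenario: the GWAS trait's causal variant is a planted edQTL
    variant; distinct: it is in weak LD (r^2 < 0.2) with every edQTL
    variant. Each simulation maps edQTLs, prunes GWAS index variants, and
    refits the QTL conditional on the paired GWAS index dosage.
    """
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_sims):
            # strong, well-covered QTLs: the scenario probes the pairing and
            # conditioning logic, so the QTL signal itself must be detectable
            cfg = syndata.SimConfig(seed=seed + s, n_variants=800,
                                    n_edit_sites=60, frac_edit_qtl=0.15,
                                    beta_edit=2.5, mean_coverage=100.0,
                                    min_causal_maf=0.2,
                                    gwas_scenario=scenario)
            geno = syndata.simulate_genotypes(cfg)
            counts, truth = syndata.simulate_editing_dataset(geno, cfg)
            res = pipeline.run_edqtl_pipeline(
                geno, counts, pipeline.RunConfig(pc_grid=(1,)),
                batch=truth.batch,
            )
            gwas = syndata.simulate_gwas(geno, cfg, qtl_truth=truth)
            index = poststats.gwas_index_variants(gwas.table, geno)
            calls = poststats.conditional_colocalization(
                res.refit, res.primaries[["phenotype_id", "variant_id"]],
                index, geno,
            )
            hits += any(c.verdict == "colocalized" for c in calls)
    return hits / n_sims, n_sims


def mediation_forward_recovery(seed: int, n_sims: int = 100, n: int = 80,
                               effect: float = 0.8):
    """How often the forward model wins on forward-generated triads."""
    wins = 0
    for s in range(n_sims):
        rng = np.random.default_rng(seed + s)
        X = rng.integers(0, 3, n).astype(float)
        M = effect * X + rng.standard_normal(n)
        Y = effect * M + rng.standard_normal(n)
        res = poststats.mediation_triplet(X, M, Y)
        wins += res.best_model == "forward"
    return wins / n_sims, n_sims


def pipeline_determinism(seed: int) -> bool:
    """Byte-identical result tables from two runs of the same config."""
    cfg = syndata.SimConfig(seed=seed, n_donors=60, n_variants=800,
                            n_edit_sites=60, n_apa_genes=40,
                            frac_edit_qtl=0.15, frac_apa_qtl=0.15)
    geno = syndata.simulate_genotypes(cfg)
    counts, truth = syndata.simulate_editing_dataset(geno, cfg)
    table, _ = syndata.simulate_apa_dataset(geno, cfg)
    run_cfg = pipeline.RunConfig(pc_grid=(0, 1), seed=seed)
    blobs = []
    for _ in range(2):
        ed = pipeline.run_edqtl_pipeline(geno, counts, run_cfg, batch=truth.batch)
        ap = pipeline.run_apaqtl_pipeline(geno, table, run_cfg)
        blobs.append(
            ed.associations.to_csv() + ed.phenotypes.to_csv()
            + ed.primaries.to_csv() + ap.associations.to_csv()
            + ap.phenotypes.to_csv() + ap.primaries.to_csv()
        )
    return blobs[0] == blobs[1]
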