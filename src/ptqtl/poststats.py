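"""Downstream statistics on mapped QTLs.

* pi1 sharing: the Storey estimate of the non-null fraction among
  replication p-values of discovery (phenotype, variant) pairs;
* permutation enrichment of significant QTL variants in RNA secondary
  structure categories, with a MAF- and distance-matched null;
* LD-thresholded conditional colocalization with GWAS index variants;
* mediation model comparison for (variant, mediator, expression) triads;
* distance profiling of primary variants to TSS/TTS/splice sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .qtlmap import GenotypeMatrix

__all__ = [
    "pi1_overlap",
    "structure_enrichment",
    "gwas_index_variants",
    "conditional_colocalization",
    "ColocCall",
    "mediation_triplet",
    "MediationResult",
    "distance_profiles",
    "ld_r2",
]


# ---------------------------------------------------------------------------
# pi1 sharing


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey pi0 from the p-value histogram over a lambda grid.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is computed over the
    grid 0.05..0.95 (step 0.05), smoothed with a cubic fit, evaluated at
    the largest lambda, and clamped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_raw = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if p.size < 100:  # too few points for the smoother; use the last grid value
        return float(np.clip(pi0_raw[-1], 0.0, 1.0))
    # cubic smoother, precision-weighted: the estimate at lambda has
    # variance ~ pi0 / (n (1 - lambda)), so the sparse right-hand bins get
    # down-weighted instead of dragging the evaluation point around
    coef = np.polynomial.polynomial.polyfit(
        lambdas, pi0_raw, deg=3, w=np.sqrt(1.0 - lambdas)
    )
    pi0 = np.polynomial.polynomial.polyval(lambdas[-1], coef)
    return float(np.clip(pi0, 0.0, 1.0))


def pi1_overlap(
    discovery_pairs: pd.DataFrame,
    replication: pd.DataFrame,
    min_pairs: int = 50,
) -> float:
    """Fraction of discovery QTL pairs that replicate (pi1 = 1 - pi0).

    ``discovery_pairs`` has columns ``phenotype_id, variant_id`` (the
    primary pairs of the discovery cell type); ``replication`` has columns
    ``phenotype_id, variant_id, p_nominal`` from the other scan. Pairs
    absent from the replication scan are dropped.
    """
    merged = discovery_pairs.merge(
        replication, on=["phenotype_id", "variant_id"], how="inner"
    )
    merged = merged.dropna(subset=["p_nominal"])
    if merged.empty:
        warnings.warn("no matched discovery/replication pairs; pi1 undefined")
        return np.nan
    if len(merged) < min_pairs:
        warnings.warn(f"only {len(merged)} matched pairs; pi1 estimate unstable")
    return 1.0 - estimate_pi0(merged["p_nominal"].to_numpy())


# ---------------------------------------------------------------------------
# structure enrichment with matched permutations


def structure_enrichment(
    significant: pd.DataFrame,
    nonsignificant: pd.DataFrame,
    n_perm: int = 1000,
    match_tol: float = 0.5,
    seed: int = 0,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Permutation enrichment of significant variants in structure categories.

    Both frames need columns ``variant_id, structure, maf, distance``
    (distance from the edit site). Per permutation, one nonsignificant
    variant is drawn without replacement for each significant variant,
    matched on MAF and |distance| within +/-``match_tol`` relative
    tolerance. Per category, ``p`` is the fraction of permutations whose
    in-category count reaches or exceeds the observed count (ties
    included, which keeps the null rejection rate at its nominal level);
    ``p_strict`` uses the strict ">" count and ``p_add_one`` its add-one
    correction (1 + #greater) / (1 + n_perm). Significant variants with
    no eligible match are excluded with a warning.
    """
    if significant.empty or nonsignificant.empty:
        raise ValueError("both variant sets must be nonempty")
    rng = np.random.default_rng(seed)
    if categories is None:
        categories = sorted(
            set(significant["structure"]) | set(nonsignificant["structure"])
        )
    ns_maf = nonsignificant["maf"].to_numpy(dtype=float)
    ns_dist = np.abs(nonsignificant["distance"].to_numpy(dtype=float))
    ns_cat = nonsignificant["structure"].to_numpy()

    eligible: list[np.ndarray] = []
    dropped = 0
    for v in significant.itertuples(index=False):
        maf_ok = np.abs(ns_maf - v.maf) <= match_tol * v.maf
        d = abs(float(v.distance))
        dist_ok = np.abs(ns_dist - d) <= match_tol * max(d, 1.0)
        idx = np.flatnonzero(maf_ok & dist_ok)
        if len(idx) == 0:
            dropped += 1
            continue
        eligible.append(idx)
    if dropped:
        warnings.warn(
            f"{dropped} significant variants had no MAF/distance-matched "
            "nonsignificant variant and were excluded; consider widening match_tol"
        )
    if not eligible:
        return pd.DataFrame(
            {"structure": list(categories), "observed": np.nan, "p": np.nan,
             "p_strict": np.nan, "p_add_one": np.nan}
        )

    obs_counts = {
        c: int((significant["structure"] == c).sum()) for c in categories
    }
    exceed = {c: 0 for c in categories}
    reach = {c: 0 for c in categories}
    cat_codes = pd.Categorical(ns_cat, categories=list(categories)).codes
    n_cat = len(categories)
    for _ in range(n_perm):
        used = np.zeros(len(ns_cat), dtype=bool)
        counts = np.zeros(n_cat, dtype=int)
        for idx in _shuffled(eligible, rng):
            free = idx[~used[idx]]
            pick = int(rng.choice(free)) if len(free) else int(rng.choice(idx))
            used[pick] = True
            code = cat_codes[pick]
            if code >= 0:
                counts[code] += 1
        for k, c in enumerate(categories):
            if counts[k] > obs_counts[c]:
                exceed[c] += 1
            if counts[k] >= obs_counts[c]:
                reach[c] += 1
    rows = []
    for c in categories:
        rows.append(
            (c, obs_counts[c], reach[c] / n_perm, exceed[c] / n_perm,
             (1 + exceed[c]) / (1 + n_perm))
        )
    return pd.DataFrame(
        rows, columns=["structure", "observed", "p", "p_strict", "p_add_one"]
    )


def _shuffled(items: list, rng: np.random.Generator):
    order = rng.permutation(len(items))
    return [items[i] for i in order]


# ---------------------------------------------------------------------------
# GWAS colocalization


def ld_r2(
    geno: GenotypeMatrix,
    variant_a: str,
    variant_b: str,
    donor_idx: np.ndarray | None = None,
) -> float:
    """Squared Pearson correlation of dosages; NaN if either is monomorphic."""
    ga = geno.dosage_for(variant_a)
    gb = geno.dosage_for(variant_b)
    if donor_idx is not None:
        ga, gb = ga[donor_idx], gb[donor_idx]
    if ga.std() == 0 or gb.std() == 0:
        return np.nan
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


def gwas_index_variants(
    gwas: pd.DataFrame,
    geno: GenotypeMatrix,
    p_thresh: float = 5e-8,
    prune_r2: float = 0.2,
) -> list[str]:
    """LD-independent genome-wide significant index variants.

    Greedy prune: significant variants sorted by ascending p (ties broken
    by genomic position); a variant is kept iff its r^2 with every
    already-kept variant is below ``prune_r2``.
    """
    sig = gwas[gwas["p"] < p_thresh].sort_values(["p", "pos"], kind="mergesort")
    kept: list[str] = []
    for v in sig.itertuples(index=False):
        ok = True
        for k in kept:
            r2 = ld_r2(geno, v.variant_id, k)
            if np.isnan(r2) or r2 >= prune_r2:
                ok = False
                break
        if ok:
            kept.append(v.variant_id)
    return kept


@dataclass
class ColocCall:
    gwas_index: str
    qtl_index: str
    phenotype_id: str
    pair_r2: float
    conditional_p: float
    verdict: str  # colocalized | not_colocalized
    collinear: bool = False


def conditional_colocalization(
    refit: Callable[[str, np.ndarray], float],
    qtl_index: pd.DataFrame,
    gwas_index: list[str],
    geno: GenotypeMatrix,
    pair_r2: float = 0.8,
    cond_alpha: float = 0.05,
) -> list[ColocCall]:
    """LD-thresholded conditional colocalization.

    ``qtl_index`` has columns ``phenotype_id, variant_id`` (primary QTL
    variants of significant phenotypes). For each (GWAS index, QTL index)
    pair with r^2 > ``pair_r2``, the QTL model is refit with the GWAS
    index variant's dosage added as a covariate; ``refit(phenotype_id,
    extra_covariate)`` must return the conditional nominal p-value of the
    QTL index variant. The pair is colocalized when the association is no
    longer significant (conditional p >= ``cond_alpha``). Identical
    variants (or perfectly collinear dosages) cannot be conditioned on
    and are called colocalized with the collinear flag.
    """
    calls: list[ColocCall] = []
    for gv in gwas_index:
        g_gwas = geno.dosage_for(gv)
        for q in qtl_index.itertuples(index=False):
            r2 = ld_r2(geno, gv, q.variant_id)
            if np.isnan(r2) or r2 <= pair_r2:
                continue
            g_qtl = geno.dosage_for(q.variant_id)
            same = gv == q.variant_id or np.allclose(
                np.corrcoef(g_gwas, g_qtl)[0, 1] ** 2, 1.0, atol=1e-12
            )
            if same:
                calls.append(
                    ColocCall(gv, q.variant_id, q.phenotype_id, r2, np.nan,
                              "colocalized", collinear=True)
                )
                continue
            p_cond = refit(q.phenotype_id, g_gwas)
            if np.isnan(p_cond):
                calls.append(
                    ColocCall(gv, q.variant_id, q.phenotype_id, r2, np.nan,
                              "colocalized", collinear=True)
                )
                continue
            verdict = "colocalized" if p_cond >= cond_alpha else "not_colocalized"
            calls.append(
                ColocCall(gv, q.variant_id, q.phenotype_id, r2, float(p_cond), verdict)
            )
    return calls


# ---------------------------------------------------------------------------
# mediation model comparison


@dataclass
class MediationResult:
    weights: dict[str, float]  # forward / independent / reactive, sum to 1
    bics: dict[str, float]

    @property
    def best_model(self) -> str:
        return min(self.bics, key=lambda k: self.bics[k])


def _gauss_regression_ll(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    n = y.size
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    rss = float(np.sum((y - Xd @ beta) ** 2))
    rss = max(rss, 1e-12)
    ll = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    return ll, Xd.shape[1] + 1  # slopes + intercept + variance


def mediation_triplet(
    dosage: np.ndarray,
    mediator: np.ndarray,
    expression: np.ndarray,
    covariates: np.ndarray | None = None,
    min_n: int = 30,
) -> MediationResult | None:
    """BIC-weighted comparison of forward / independent / reactive models.

    For a (variant X, mediator M, gene expression Y) triad the three
    causal diagrams are scored by the BIC of their joint Gaussian
    likelihood: forward X->M->Y (M ~ X, Y ~ M), independent X->M and X->Y
    (M ~ X, Y ~ X), reactive X->Y->M (Y ~ X, M ~ Y). Variables are
    residualized on the covariates first. Normalized exp(-deltaBIC/2)
    weights approximate posterior model probabilities.
    """
    X = np.asarray(dosage, dtype=float)
    M = np.asarray(mediator, dtype=float)
    Y = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(X) | np.isnan(M) | np.isnan(Y))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        ok &= ~np.isnan(C).any(axis=1)
    n = int(ok.sum())
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete cases, got {n}")
    X, M, Y = X[ok], M[ok], Y[ok]
    if M.std() == 0 or Y.std() == 0:
        return None
    if covariates is not None:
        C = np.column_stack([np.ones(n), C[ok]])
        for arr in (X, M, Y):
            beta, *_ = np.linalg.lstsq(C, arr, rcond=None)
            arr -= C @ beta
    systems = {
        "forward": ((M, X), (Y, M)),
        "independent": ((M, X), (Y, X)),
        "reactive": ((Y, X), (M, Y)),
    }
    bics = {}
    for name, regs in systems.items():
        ll_tot, k_tot = 0.0, 0
        for y, x in regs:
            ll, k = _gauss_regression_ll(y, x)
            ll_tot += ll
            k_tot += k
        bics[name] = -2.0 * ll_tot + k_tot * np.log(n)
    b0 = min(bics.values())
    raw = {k: np.exp(-(v - b0) / 2.0) for k, v in bics.items()}
    tot = sum(raw.values())
    weights = {k: v / tot for k, v in raw.items()}
    return MediationResult(weights=weights, bics=bics)


# ---------------------------------------------------------------------------
# distance profiling


def distance_profiles(
    primaries: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Signed distances of primary variants to TSS, TTS, nearest splice site.

    ``primaries`` needs ``phenotype_id, variant_id, pos, gene_id`` and
    ``genes`` needs ``gene_id, strand, tss, tts`` plus intron boundary
    columns (``intron_starts, intron_ends, intron2_start, intron2_end``).
    Distances are signed along the direction of transcription (upstream
    negative); the splice distance is the minimum absolute distance over
    all intron boundaries, missing for genes without introns.
    """
    gidx = genes.set_index("gene_id")
    rows = []
    for q in primaries.itertuples(index=False):
        if q.gene_id not in gidx.index:
            continue
        g = gidx.loc[q.gene_id]
        sign = 1 if g["strand"] == "+" else -1
        d_tss = sign * (q.pos - g["tss"])
        d_tts = sign * (q.pos - g["tts"])
        bounds = [g.get(c) for c in
                  ("intron_starts", "intron_ends", "intron2_start", "intron2_end")]
        bounds = [b for b in bounds if b is not None and not pd.isna(b)]
        d_splice = min((abs(q.pos - b) for b in bounds), default=np.nan)
        rows.append((q.phenotype_id, q.variant_id, int(d_tss), int(d_tts), d_splice))
    return pd.DataFrame(
        rows, columns=["phenotype_id", "variant_id", "dist_tss", "dist_tts",
                       "dist_splice"]
    )
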