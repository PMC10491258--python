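"""cis-QTL mapping for post-transcriptional phenotypes.

Two association models are provided:

* a binomial generalized linear model for RNA-editing rates, where the
  response at a site is the per-donor pair (edited reads, unedited reads)
  and the dosage coefficient is the per-minor-allele log-odds of editing;
* an EMMAX-style linear mixed model for normalized poly(A)-usage
  phenotypes, with error covariance sigma_u^2 * K + sigma_e^2 * I built
  from an identity-by-state (IBS) kinship matrix, optionally computed
  leave-one-chromosome-out (LOCO).

Multiple testing follows a hierarchical scheme: per phenotype the minimum
nominal p-value is Bonferroni-adjusted by the effective number of
independent cis variants (eigenvalue-based, "eigenMT"), then
Benjamini-Hochberg is applied across phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "QTLAssociation",
    "VarianceComponents",
    "cis_pairs",
    "filter_variants_by_genotype_class",
    "fit_binomial_edqtl",
    "compute_ibs_kinship",
    "fit_lmm_apaqtl",
    "phenotype_pcs",
    "genotype_mds",
    "optimize_covariates",
    "eigenmt_meff",
    "hierarchical_fdr",
    "select_primary",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Donor x variant dosage matrix with variant metadata.

    ``variants`` is a DataFrame with columns ``id, chrom, pos, ref, alt``
    (1-based positions) plus optional ``gene_id`` and ``maf``; ``dosage``
    has shape (n_donors, n_variants) with values in [0, 2].
    """

    donors: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    haplotype_pool: object | None = None  # founder haplotypes, kept for resimulation

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.donors), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.donors)} donors x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)
        if "maf" not in self.variants.columns:
            self.variants = self.variants.assign(maf=self.compute_maf())

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def compute_maf(self) -> np.ndarray:
        freq = self.dosage.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return int(idx[0])

    def dosage_for(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_index(variant_id)]

    def donor_indices(self, donor_ids: Sequence[str]) -> np.ndarray:
        lookup = {d: i for i, d in enumerate(self.donors)}
        missing = [d for d in donor_ids if d not in lookup]
        if missing:
            raise KeyError(f"donors absent from genotype matrix: {missing[:5]}")
        return np.array([lookup[d] for d in donor_ids], dtype=int)


@dataclass
class KinshipMatrix:
    """Donor x donor IBS similarity used as the random-effect covariance."""

    donors: list[str]
    values: np.ndarray
    loco_chrom: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.donors)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over donors")

    def check_psd(self, tol: float = 1e-6) -> np.ndarray:
        """Eigenvalues after clipping tiny negatives; error if strongly negative."""
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -tol * max(1.0, w[-1]):
            raise ValueError(f"kinship matrix not PSD (min eigenvalue {w[0]:.3g})")
        return np.clip(w, 0.0, None)


@dataclass
class QTLAssociation:
    phenotype_id: str
    variant_id: str
    beta: float
    se: float
    p_nominal: float
    p_local: float = np.nan
    q_global: float = np.nan
    is_primary: bool = False
    n_donors: int = 0
    flag: str = ""


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan


# ---------------------------------------------------------------------------
# cis-window pairing and variant filters


def cis_pairs(
    phenotypes: pd.DataFrame,
    geno: GenotypeMatrix,
    window: int,
    same_gene: bool = False,
) -> dict[str, np.ndarray]:
    """Candidate variant indices per phenotype.

    ``phenotypes`` needs columns ``id, chrom`` and either ``pos`` (single
    anchor, editing sites) or ``start``/``end`` (two anchors, 3'UTR spans:
    a variant is cis if within ``window`` of either end). For editing
    phenotypes with ``same_gene=True`` the variant must additionally fall
    inside the phenotype's ``gene_id`` (the variants table must then carry
    a ``gene_id`` column). Boundaries are inclusive.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out: dict[str, np.ndarray] = {}
    var = geno.variants
    vpos = var["pos"].to_numpy()
    vchrom = var["chrom"].to_numpy()
    for row in phenotypes.itertuples(index=False):
        pid = row.id
        if hasattr(row, "pos") and not pd.isna(getattr(row, "pos", np.nan)):
            anchors = [int(row.pos)]
        elif hasattr(row, "start"):
            anchors = [int(row.start), int(row.end)]
        else:
            warnings.warn(f"phenotype {pid} has no coordinates; skipped")
            continue
        mask = vchrom == row.chrom
        near = np.zeros(len(var), dtype=bool)
        for a in anchors:
            near |= np.abs(vpos - a) <= window
        mask &= near
        if same_gene:
            gene = getattr(row, "gene_id", None)
            if gene is None or pd.isna(gene):
                mask &= False
            else:
                mask &= (var["gene_id"] == gene).to_numpy()
        out[pid] = np.flatnonzero(mask)
    return out


def filter_variants_by_genotype_class(
    geno: GenotypeMatrix,
    donor_idx: np.ndarray | None = None,
    variant_idx: np.ndarray | None = None,
    min_het: int = 2,
    min_hom_minor: int = 2,
) -> np.ndarray:
    """Mask of testable variants on a donor subset.

    A variant is kept iff it has at least ``min_het`` heterozygous donors
    and either no homozygous-minor donors at all or at least
    ``min_hom_minor`` of them. Dosages are hardened to {0,1,2} by rounding
    for class counting only.
    """
    d = geno.dosage
    if donor_idx is not None:
        d = d[donor_idx]
    if variant_idx is not None:
        d = d[:, variant_idx]
    hard = np.round(d)
    freq = np.nanmean(hard, axis=0) / 2.0
    # orient so "minor" is the rarer hardened allele per variant
    minor_count = np.where(freq <= 0.5, hard, 2.0 - hard)
    n_het = (minor_count == 1).sum(axis=0)
    n_hom_minor = (minor_count == 2).sum(axis=0)
    return (n_het >= min_het) & ((n_hom_minor == 0) | (n_hom_minor >= min_hom_minor))


# ---------------------------------------------------------------------------
# binomial GLM (edQTL)


def _irls_binomial(
    X: np.ndarray,
    edited: np.ndarray,
    total: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Binomial-logit IRLS. Returns (beta, covariance, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    # initialize intercept at the pooled empirical logit
    rate = (edited.sum() + 0.5) / (total.sum() + 1.0)
    beta[0] = np.log(rate / (1.0 - rate))
    XtWX = np.eye(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (edited - total * mu)
        w = total * mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtWX = (X * w[:, None]).T @ X
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        # dampen huge steps (quasi-separation)
        norm = np.max(np.abs(step))
        if norm > 20.0:
            step *= 20.0 / norm
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:  # diverging: separation
            return beta, np.full((p, p), np.nan), False
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def fit_binomial_edqtl(
    edited: np.ndarray,
    total: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    min_donors: int = 10,
    robust: bool = False,
) -> QTLAssociation:
    """Test one (editing site, variant) pair with a binomial GLM.

    The response is the per-donor (edited, total - edited) read-count pair;
    ``beta`` is the per-minor-allele change in log-odds of editing; the
    p-value is a Wald test on the dosage coefficient. Donors with zero
    total coverage are dropped. ``robust=True`` swaps the model-based
    variance for a sandwich estimate (guards against overdispersion).
    """
    edited = np.asarray(edited, dtype=float)
    total = np.asarray(total, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    keep = total > 0
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        keep &= ~np.isnan(covariates).any(axis=1)
    keep &= ~np.isnan(dosage)
    n = int(keep.sum())
    if n < min_donors:
        return QTLAssociation("", "", np.nan, np.nan, np.nan, n_donors=n, flag="too_few_donors")
    g = dosage[keep]
    if np.ptp(g) == 0:
        return QTLAssociation("", "", np.nan, np.nan, np.nan, n_donors=n, flag="monomorphic")
    cols = [np.ones(n), g]
    if covariates is not None:
        cols.extend(covariates[keep].T)
    X = np.column_stack(cols)
    beta, cov, converged = _irls_binomial(X, edited[keep], total[keep])
    if converged and abs(beta[1]) > 15.0:
        # log-odds per allele beyond any plausible effect: (quasi-)separation
        return QTLAssociation("", "", float(beta[1]), np.nan, np.nan,
                              n_donors=n, flag="separation")
    if not converged or not np.isfinite(cov[1, 1]) or cov[1, 1] <= 0:
        return QTLAssociation(
            "", "", beta[1] if np.isfinite(beta[1]) else np.nan,
            np.nan, np.nan, n_donors=n, flag="nonconverged",
        )
    if robust:
        # HC3 leverage-adjusted sandwich with a t reference: the model-based
        # normal Wald has a heavy far tail at cohort-scale n when counts are
        # overdispersed (latent factors), and the few homozygous-minor donors
        # are high-leverage points, which matters under min-p + BH
        df = n - X.shape[1]
        if df <= 0:
            return QTLAssociation("", "", float(beta[1]), np.nan, np.nan,
                                  n_donors=n, flag="no_residual_df")
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(total[keep] * mu * (1.0 - mu), 1e-12)
        Xw = X * np.sqrt(w)[:, None]
        h = np.clip(np.einsum("ij,jk,ik->i", Xw, cov, Xw), 0.0, 0.99)
        score = X * ((edited[keep] - total[keep] * mu) / (1.0 - h))[:, None]
        cov = cov @ (score.T @ score) @ cov
        se = float(np.sqrt(cov[1, 1]))
        p = 2.0 * stats.t.sf(abs(beta[1] / se), df=df)
    else:
        se = float(np.sqrt(cov[1, 1]))
        p = 2.0 * stats.norm.sf(abs(beta[1] / se))
    return QTLAssociation("", "", float(beta[1]), se, float(p), n_donors=n)


# ---------------------------------------------------------------------------
# kinship and linear mixed model (apaQTL)


def compute_ibs_kinship(
    geno: GenotypeMatrix,
    loco_chrom: str | None = None,
    min_variants: int = 50,
) -> KinshipMatrix:
    """IBS kinship: K[j,j'] = mean over variants of (2 - |d_j - d_j'|)/2.

    With ``loco_chrom`` set, variants on that chromosome are left out
    (leave-one-chromosome-out), so the random effect does not absorb the
    cis signal being tested.
    """
    mask = np.ones(geno.n_variants, dtype=bool)
    if loco_chrom is not None:
        mask &= (geno.variants["chrom"] != loco_chrom).to_numpy()
    m = int(mask.sum())
    if m == 0:
        raise ValueError("no variants left for kinship computation")
    if m < min_variants:
        warnings.warn(f"only {m} variants for kinship; estimate may be unstable")
    d = np.round(geno.dosage[:, mask])
    # (2 - |d_j - d_j'|)/2 averaged over variants; the double loop is
    # decomposed over dosage-class indicator matrices
    n = geno.n_donors
    ind = [(d == v).astype(float) for v in (0.0, 1.0, 2.0)]
    absdiff = np.zeros((n, n))
    for i, a in enumerate((0.0, 1.0, 2.0)):
        for j, b in enumerate((0.0, 1.0, 2.0)):
            if a == b:
                continue
            absdiff += abs(a - b) * (ind[i] @ ind[j].T)
    K = (2.0 * m - absdiff) / (2.0 * m)
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(geno.donors), K, loco_chrom=loco_chrom)


def _reml_neg_loglik(
    log_lam: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> float:
    lam = np.exp(log_lam)
    w = lam * s + 1.0
    n, p = Xt.shape
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    rss = float(r @ (r / w))
    if rss <= 0:
        return np.inf
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    _, logdet_XtX = np.linalg.slogdet(Xt.T @ Xt)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * rss / (n - p)) + 1.0)
        + np.sum(np.log(w))
        + logdet_XtWX
        - logdet_XtX
    )
    return -ll


@dataclass
class LMMContext:
    """Per-phenotype REML fit reused across all cis variants (EMMAX)."""

    U: np.ndarray  # kinship eigenvectors
    s: np.ndarray  # kinship eigenvalues (clipped >= 0)
    yt: np.ndarray  # rotated phenotype
    Ct: np.ndarray  # rotated null covariates (incl. intercept)
    weights: np.ndarray  # lam*s + 1 at the REML optimum
    vc: VarianceComponents
    flag: str = ""


def fit_lmm_null(
    y: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
) -> LMMContext:
    """Stage 1 of the EMMAX fit: REML variance components under the null.

    The kinship is eigendecomposed once; the variance ratio
    lambda = sigma_u^2 / sigma_e^2 is profiled on the rotated data, and the
    resulting error covariance is frozen for all per-variant tests.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    kinship.check_psd()
    w_eig, U = np.linalg.eigh(kinship.values)
    s = np.clip(w_eig, 0.0, None)
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    C0 = np.column_stack(cols)
    yt = U.T @ y
    Ct = U.T @ C0
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-12.0, 12.0),
        args=(s, yt, Ct),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    flag = ""
    if res.x <= -11.5:
        lam = 0.0
        flag = "ols_boundary"  # sigma_u^2 at zero: collapses to OLS
    w = lam * s + 1.0
    Xw = Ct / w[:, None]
    beta = np.linalg.solve(Ct.T @ Xw, Xw.T @ yt)
    r = yt - Ct @ beta
    sigma_e2 = float(r @ (r / w)) / max(n - C0.shape[1], 1)
    vc = VarianceComponents(sigma_g2=lam * sigma_e2, sigma_e2=sigma_e2)
    return LMMContext(U=U, s=s, yt=yt, Ct=Ct, weights=w, vc=vc, flag=flag)


def fit_lmm_apaqtl(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
    context: LMMContext | None = None,
) -> tuple[QTLAssociation, VarianceComponents]:
    """Stage 2 EMMAX test of one variant against a normalized phenotype.

    Generalized least squares with the REML-estimated error covariance
    sigma_u^2 K + sigma_e^2 I; Wald p-value on the dosage coefficient.
    With K = I this reproduces ordinary least squares exactly.
    """
    if context is None:
        context = fit_lmm_null(y, covariates, kinship)
    g = np.asarray(dosage, dtype=float)
    if np.ptp(g) == 0:
        assoc = QTLAssociation("", "", np.nan, np.nan, np.nan, flag="monomorphic")
        return assoc, context.vc
    gt = context.U.T @ g
    X = np.column_stack([context.Ct, gt])
    w = context.weights
    Xw = X / w[:, None]
    XtWX = X.T @ Xw
    try:
        XtWX_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        assoc = QTLAssociation("", "", np.nan, np.nan, np.nan, flag="singular")
        return assoc, context.vc
    beta = XtWX_inv @ (Xw.T @ context.yt)
    n, p = X.shape
    r = context.yt - X @ beta
    sigma2 = float(r @ (r / w)) / (n - p)
    se = float(np.sqrt(sigma2 * XtWX_inv[-1, -1]))
    b = float(beta[-1])
    tstat = b / se
    pval = 2.0 * stats.t.sf(abs(tstat), df=n - p)
    assoc = QTLAssociation("", "", b, se, float(pval), n_donors=n, flag=context.flag)
    return assoc, context.vc


# ---------------------------------------------------------------------------
# covariates


def phenotype_pcs(phenotypes: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of a donors x phenotypes matrix.

    Missing entries are mean-imputed per phenotype before the SVD; returns
    a (donors, k) score matrix (empty when k <= 0).
    """
    M = np.asarray(phenotypes, dtype=float)
    n = M.shape[0]
    if k <= 0:
        return np.empty((n, 0))
    if k >= min(M.shape):
        raise ValueError("k must be < min(n_donors, n_phenotypes)")
    col_mean = np.nanmean(M, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    M = np.where(np.isnan(M), col_mean[None, :], M)
    M = M - M.mean(axis=0)
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    return U[:, :k] * S[:k]


def genotype_mds(geno: GenotypeMatrix, n_components: int = 3) -> np.ndarray:
    """Population-structure axes: classical scaling of the IBS distance.

    Equivalent to the top principal coordinates of D = 1 - K; used as the
    "MDS of global genotype" covariates.
    """
    K = compute_ibs_kinship(geno, min_variants=1).values
    D2 = (1.0 - K) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    return V[:, order] * np.sqrt(np.clip(w[order], 0.0, None))


def optimize_covariates(
    scan: Callable[[int], int],
    k_grid: Sequence[int],
) -> tuple[int, dict[int, int]]:
    """Choose the phenotype-PC count maximizing QTL discovery.

    ``scan(k)`` must run the full association scan with k phenotype PCs and
    return the number of significant phenotypes at the configured FDR.
    Ties are broken toward the smallest k.
    """
    if len(k_grid) == 0:
        raise ValueError("k_grid must be nonempty")
    counts = {int(k): int(scan(int(k))) for k in k_grid}
    best = max(sorted(counts), key=lambda k: (counts[k], -k))
    return best, counts


# ---------------------------------------------------------------------------
# multiple testing


def eigenmt_meff(
    cis_dosage: np.ndarray,
    window: int = 200,
    var_explained: float = 0.99,
) -> int:
    """Effective number of independent cis tests (eigenMT).

    Variants are taken in consecutive windows of at most ``window``; per
    window the eigenvalues of the variant correlation matrix are counted
    (descending) until their cumulative share reaches ``var_explained``.
    The sum over windows is clamped to [1, M]. Zero-variance variant
    columns are dropped first.
    """
    G = np.asarray(cis_dosage, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("need at least one variant")
    M = G.shape[1]
    sd = G.std(axis=0)
    G = G[:, sd > 0]
    if G.shape[1] == 0:
        return 1
    # exact duplicate columns contribute no independent tests and would
    # otherwise shift the positional window boundaries
    G = np.unique(G, axis=1)
    meff = 0
    for start in range(0, G.shape[1], window):
        block = G[:, start : start + window]
        m = block.shape[1]
        if m == 1:
            meff += 1
            continue
        R = np.corrcoef(block, rowvar=False)
        ev = np.linalg.eigvalsh(R)[::-1]
        ev = np.clip(ev, 0.0, None)
        cum = np.cumsum(ev) / ev.sum()
        meff += int(np.searchsorted(cum, var_explained) + 1)
    return int(min(max(meff, 1), M))


def hierarchical_fdr(
    records: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """eigenMT-FDR: local Bonferroni by m_eff, then BH across phenotypes.

    ``records`` needs columns ``phenotype_id, p_min, m_eff``; returns the
    frame with ``p_local``, ``q_global`` and ``significant`` added.
    """
    out = records.copy()
    out["p_local"] = np.minimum(1.0, out["p_min"] * out["m_eff"])
    ok = out["p_local"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        _, qvals, _, _ = multipletests(out.loc[ok, "p_local"], method="fdr_bh")
        q[np.flatnonzero(ok)] = qvals
    out["q_global"] = q
    out["significant"] = out["q_global"] < alpha
    return out


def select_primary(associations: pd.DataFrame) -> pd.Series:
    """Most significant variant for one phenotype.

    Requires columns ``variant_id, p_nominal, distance, pos``. Ties on the
    nominal p-value break toward the smaller distance to the phenotype
    anchor, then the smaller genomic position.
    """
    a = associations.dropna(subset=["p_nominal"])
    if a.empty:
        raise ValueError("no testable associations")
    a = a.sort_values(
        ["p_nominal", "distance", "pos"], kind="mergesort"
    )
    return a.iloc[0]
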