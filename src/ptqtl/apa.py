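"""Poly(A)-usage (PAU) phenotypes from 3'UTR isoform counts.

PAU of a 3'UTR isoform in a donor is its share of the summed expression
of all 3'UTR isoforms of the gene. Lowly expressed isoforms are filtered,
one of each complementary two-isoform pair is dropped at random (the two
carry the same information), and the surviving phenotypes are
rank-transformed for mixed-model QTL mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IsoformCountTable",
    "PAUTable",
    "compute_pau",
    "filter_isoforms",
    "normalize_pau",
    "classify_utr_change",
    "pas_disruption",
    "CANONICAL_PAS_MOTIFS",
]

# the 12 canonical polyadenylation-signal hexamers (DNA alphabet);
# AATAAA (AAUAAA in RNA) is by far the most frequent in human 3'UTRs
CANONICAL_PAS_MOTIFS = (
    "AATAAA", "ATTAAA", "AGTAAA", "TATAAA", "CATAAA", "GATAAA",
    "AATATA", "AATACA", "AATAGA", "ACTAAA", "AAGAAA", "AATGAA",
)


@dataclass
class IsoformCountTable:
    """Per-isoform per-donor counts with isoform metadata.

    ``isoforms`` needs columns ``id, gene_id, chrom, utr_start, utr_end,
    strand, length`` (1-based inclusive UTR span) and optionally
    ``pas_start, pas_end``; ``counts`` has shape (n_isoforms, n_donors).
    """

    isoforms: pd.DataFrame
    donors: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.isoforms), len(self.donors)):
            raise ValueError("counts must be isoforms x donors")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.isoforms["id"].duplicated().any():
            raise ValueError("isoform ids must be unique")
        if self.isoforms["gene_id"].isna().any():
            raise ValueError("every isoform needs a gene id")
        self.isoforms = self.isoforms.reset_index(drop=True)


@dataclass
class PAUTable:
    """Poly(A)-usage fractions, optionally normalized, with provenance."""

    isoforms: pd.DataFrame
    donors: list[str]
    pau: np.ndarray  # in [0,1] or NaN
    normalized: np.ndarray | None = None
    flags: pd.DataFrame | None = None  # per-isoform provenance

    def subset(self, keep: np.ndarray) -> "PAUTable":
        return PAUTable(
            self.isoforms.loc[keep].reset_index(drop=True),
            list(self.donors),
            self.pau[keep],
            None if self.normalized is None else self.normalized[keep],
            None if self.flags is None else self.flags.loc[keep].reset_index(drop=True),
        )


def compute_pau(table: IsoformCountTable) -> PAUTable:
    """PAU[i,j] = counts[i,j] / sum of the gene's isoform counts in donor j.

    Missing (NaN) where the gene's total in a donor is zero. Per gene and
    donor the defined PAUs sum to one.
    """
    counts = table.counts.astype(float)
    gene_codes, _ = pd.factorize(table.isoforms["gene_id"])
    n_genes = gene_codes.max() + 1 if len(gene_codes) else 0
    totals = np.zeros((n_genes, counts.shape[1]))
    np.add.at(totals, gene_codes, counts)
    denom = totals[gene_codes]
    with np.errstate(divide="ignore", invalid="ignore"):
        pau = np.where(denom > 0, counts / denom, np.nan)
    return PAUTable(table.isoforms.copy(), list(table.donors), pau)


def filter_isoforms(
    pau: PAUTable,
    table: IsoformCountTable,
    min_count: int = 10,
    min_donor_frac: float = 0.10,
    seed: int = 0,
) -> PAUTable:
    """Expression filter plus the two-isoform redundancy rule.

    Keeps isoforms with raw count >= ``min_count`` in at least
    ``min_donor_frac`` of donors. For genes left with exactly two
    isoforms, the two PAU vectors are complementary, so exactly one is
    kept, chosen uniformly at random under ``seed``; the provenance flags
    record the dropped twin.
    """
    rng = np.random.default_rng(seed)
    n_donors = len(pau.donors)
    expressed = (table.counts >= min_count).sum(axis=1) / n_donors >= min_donor_frac
    flags = pd.DataFrame(
        {"id": pau.isoforms["id"], "low_expression": ~expressed,
         "dropped_twin_of": [""] * len(pau.isoforms)}
    )
    keep = expressed.copy()
    for gene, sub in pau.isoforms.groupby("gene_id"):
        idx = sub.index[keep[sub.index]]
        if len(idx) == 2:
            drop = idx[int(rng.integers(2))]
            other = idx[idx != drop][0]
            keep[drop] = False
            flags.loc[drop, "dropped_twin_of"] = pau.isoforms.loc[other, "id"]
    out = pau.subset(keep)
    out.flags = flags.loc[keep].reset_index(drop=True)
    return out


def normalize_pau(
    pau: PAUTable,
    method: str = "inverse_normal",
    min_donors: int = 10,
) -> PAUTable:
    """Normalize PAU phenotypes for Gaussian mixed-model mapping.

    ``inverse_normal`` (default): per isoform, values are mapped to
    standard-normal quantiles of their ranks across donors (average ranks
    for ties, missing excluded), making the transform invariant to any
    monotone rescaling of the input. ``quantile`` maps every isoform onto
    the average sorted profile across isoforms (classical across-sample
    quantile normalization). Isoforms with fewer than ``min_donors``
    non-missing donors, or constant values, are flagged and excluded from
    QTL testing.
    """
    X = pau.pau
    out = np.full_like(X, np.nan, dtype=float)
    degenerate = np.zeros(len(pau.isoforms), dtype=bool)
    if method == "quantile":
        ref = _mean_sorted_profile(X)
    for i in range(X.shape[0]):
        x = X[i]
        ok = ~np.isnan(x)
        m = int(ok.sum())
        if m < min_donors:
            degenerate[i] = True
            continue
        if np.nanstd(x) == 0:
            out[i, ok] = 0.0
            degenerate[i] = True
            continue
        ranks = stats.rankdata(x[ok], method="average")
        if method == "inverse_normal":
            out[i, ok] = stats.norm.ppf((ranks - 0.5) / m)
        elif method == "quantile":
            grid = (ranks - 0.5) / m
            out[i, ok] = np.interp(grid, np.linspace(0, 1, len(ref)), ref)
        else:
            raise ValueError(f"unknown method {method!r}")
    res = PAUTable(pau.isoforms.copy(), list(pau.donors), X.copy(), out, pau.flags)
    if res.flags is None:
        res.flags = pd.DataFrame({"id": res.isoforms["id"]})
    res.flags = res.flags.assign(degenerate=degenerate)
    return res


def _mean_sorted_profile(X: np.ndarray) -> np.ndarray:
    rows = [np.sort(x[~np.isnan(x)]) for x in X if (~np.isnan(x)).sum() > 1]
    if not rows:
        return np.array([0.0, 0.0])
    L = max(len(r) for r in rows)
    grid = np.linspace(0, 1, L)
    interp = [np.interp(grid, np.linspace(0, 1, len(r)), r) for r in rows]
    return np.mean(interp, axis=0)


def classify_utr_change(
    lengths: dict[str, float],
    direction: dict[str, str],
) -> str | None:
    """Label a gene's 3'UTR change from per-isoform up/down calls.

    ``lengths`` maps isoform id -> 3'UTR length; ``direction`` maps
    isoform id -> {"up", "down", "none"}. Lengthening when the longest
    isoform is up, shortening when the shortest is up, ambiguous when
    both are, internal when only middle isoforms are up; None when
    nothing is up.
    """
    up = {k for k, v in direction.items() if v == "up"}
    if not up:
        return None
    longest = max(lengths, key=lambda k: lengths[k])
    shortest = min(lengths, key=lambda k: lengths[k])
    long_up = longest in up
    short_up = shortest in up
    if long_up and short_up:
        return "ambiguous"
    if long_up:
        return "lengthening"
    if short_up:
        return "shortening"
    return "internal"


def pas_disruption(
    variants: pd.DataFrame,
    pas_intervals: pd.DataFrame,
    flanks: dict[str, str] | None = None,
    motifs: tuple[str, ...] = CANONICAL_PAS_MOTIFS,
) -> pd.DataFrame:
    """Flag variants whose span intersects a polyadenylation-signal hexamer.

    ``variants`` needs ``id, chrom, pos, ref, alt``; a variant occupies
    [pos, pos + len(ref) - 1], so indels are matched by interval
    intersection rather than by point position. ``pas_intervals`` needs
    ``chrom, start, end, motif`` (1-based inclusive). When ``flanks``
    supplies the hexamer sequence carrying each allele (keyed by variant
    id as ``"REFSEQ|ALTSEQ"``), the effect column reports whether the
    alternative allele destroys or restores a canonical motif.
    """
    rows = []
    for v in variants.itertuples(index=False):
        v_start = int(v.pos)
        v_end = v_start + max(len(str(v.ref)), 1) - 1
        hit = pas_intervals[
            (pas_intervals["chrom"] == v.chrom)
            & (pas_intervals["start"] <= v_end)
            & (pas_intervals["end"] >= v_start)
        ]
        if hit.empty:
            rows.append((v.id, False, "", ""))
            continue
        motif = str(hit.iloc[0]["motif"])
        effect = ""
        if flanks and v.id in flanks:
            ref_seq, _, alt_seq = flanks[v.id].partition("|")
            ref_has = any(m in ref_seq.upper() for m in motifs)
            alt_has = any(m in alt_seq.upper() for m in motifs)
            if ref_has and not alt_has:
                effect = "destroys"
            elif alt_has and not ref_has:
                effect = "restores"
            else:
                effect = "neutral"
        rows.append((v.id, True, motif, effect))
    return pd.DataFrame(rows, columns=["variant_id", "in_pas", "motif", "effect"])
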