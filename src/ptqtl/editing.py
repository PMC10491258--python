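"""Discovery and quantification of A-to-I RNA-editing phenotypes.

An editing site is observed as an A-to-G mismatch (T-to-C on the minus
strand) between RNA-sequencing reads and the reference genome. The edit
rate of a site in a donor is the fraction of reads supporting the edited
allele. Sites are retained for QTL mapping when enough donors cover them
deeply enough; per-site supporting-donor sets are carried downstream
because the covered donors differ between sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EditCountMatrix",
    "compute_edit_rates",
    "discover_edit_sites",
    "validate_with_dna_reads",
    "compute_aei",
    "motif_profile",
    "overlap_enrichment",
]

SITE_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "strand", "gene_id", "region", "alu"]


@dataclass
class EditCountMatrix:
    """Per-site per-donor (edited, total) read counts.

    ``sites`` is a DataFrame with columns ``id, chrom, pos, ref, alt,
    strand`` plus optional ``gene_id, region, alu``; ``edited`` and
    ``total`` are integer matrices of shape (n_sites, n_donors) with
    0 <= edited <= total.
    """

    sites: pd.DataFrame
    donors: list[str]
    edited: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.edited = np.asarray(self.edited)
        self.total = np.asarray(self.total)
        shape = (len(self.sites), len(self.donors))
        if self.edited.shape != shape or self.total.shape != shape:
            raise ValueError("count matrices must be sites x donors")
        if (self.edited < 0).any() or (self.edited > self.total).any():
            raise ValueError("need 0 <= edited <= total")
        if self.sites["id"].duplicated().any():
            raise ValueError("site ids must be unique")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, site_id: str) -> int:
        idx = self.sites.index[self.sites["id"] == site_id]
        if len(idx) == 0:
            raise KeyError(f"unknown site {site_id!r}")
        return int(idx[0])

    def subset_sites(self, site_ids: list[str]) -> "EditCountMatrix":
        idx = [self.site_index(s) for s in site_ids]
        return EditCountMatrix(
            self.sites.iloc[idx], list(self.donors), self.edited[idx], self.total[idx]
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format table (one row per site x donor), the TSV layout."""
        recs = []
        for i, row in self.sites.iterrows():
            for j, donor in enumerate(self.donors):
                recs.append(
                    (row["id"], row["chrom"], row["pos"], row["ref"], row["alt"],
                     row.get("strand", "+"), donor, int(self.edited[i, j]), int(self.total[i, j]))
                )
        return pd.DataFrame(
            recs,
            columns=["site_id", "chrom", "pos", "ref", "alt", "strand", "donor",
                     "edited", "total"],
        )

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "EditCountMatrix":
        donors = sorted(table["donor"].unique())
        meta_cols = ["site_id", "chrom", "pos", "ref", "alt", "strand"]
        sites = (
            table[meta_cols].drop_duplicates("site_id").rename(columns={"site_id": "id"})
        ).reset_index(drop=True)
        ed = table.pivot(index="site_id", columns="donor", values="edited")
        tot = table.pivot(index="site_id", columns="donor", values="total")
        ed = ed.reindex(index=sites["id"], columns=donors).fillna(0)
        tot = tot.reindex(index=sites["id"], columns=donors).fillna(0)
        return cls(sites, donors, ed.to_numpy(dtype=int), tot.to_numpy(dtype=int))


def compute_edit_rates(counts: EditCountMatrix) -> np.ndarray:
    """Edit rate edited/total per site x donor; NaN where total is zero."""
    total = counts.total.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(total > 0, counts.edited / total, np.nan)
    return rate


def discover_edit_sites(
    counts: EditCountMatrix,
    min_total: int = 10,
    min_edited: int = 2,
    min_donor_frac: float = 0.85,
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Retain sites supported by enough donors; record supporting donors.

    A donor supports a site when total >= ``min_total`` and edited >=
    ``min_edited`` there; the site is retained when the supporting
    fraction of donors is >= ``min_donor_frac`` (all bounds inclusive).
    Returns (retained site ids, {site id -> boolean supporting mask}).
    """
    if min_total <= 0 or min_edited <= 0 or min_donor_frac <= 0:
        raise ValueError("thresholds must be positive")
    if counts.n_sites == 0:
        return [], {}
    support = (counts.total >= min_total) & (counts.edited >= min_edited)
    frac = support.mean(axis=1)
    kept = frac >= min_donor_frac
    ids = counts.sites.loc[kept, "id"].tolist()
    masks = {sid: support[counts.site_index(sid)] for sid in ids}
    return ids, masks


def validate_with_dna_reads(
    site_ids: list[str],
    dna_counts: pd.DataFrame,
    threshold: float = 1.0,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Check candidate sites against DNA-level allele counts.

    ``dna_counts`` has columns ``site_id, donor, ref_reads, alt_reads``
    (e.g. from ATAC-seq reads at the site). Per site, the unedited-allele
    fraction is pooled over donors with depth >= ``min_depth``; verdicts:
    ``validated`` (fraction >= threshold: no genomic evidence for the
    alternative allele), ``suspect_genomic`` otherwise, ``no_coverage``
    when no DNA read covers the site.
    """
    grouped = dna_counts.groupby("site_id")
    rows = []
    for sid in site_ids:
        if sid not in grouped.groups:
            rows.append((sid, np.nan, "no_coverage"))
            continue
        sub = grouped.get_group(sid)
        depth = sub["ref_reads"] + sub["alt_reads"]
        sub = sub[depth >= min_depth]
        denom = float((sub["ref_reads"] + sub["alt_reads"]).sum())
        if denom == 0:
            rows.append((sid, np.nan, "no_coverage"))
            continue
        frac = float(sub["ref_reads"].sum()) / denom
        verdict = "validated" if frac >= threshold else "suspect_genomic"
        rows.append((sid, frac, verdict))
    return pd.DataFrame(rows, columns=["site_id", "unedited_fraction", "verdict"])


def compute_aei(aei_input: pd.DataFrame) -> pd.Series:
    """Alu editing index per sample, in percent.

    ``aei_input`` has columns ``sample, region, a_reads, g_reads`` with
    counts pooled over adenosine positions of each Alu region. The index
    is 100 * sum(G) / sum(A + G) over all regions of the sample — a
    read-weighted pooled ratio, not an average of per-region ratios.
    """
    if len(aei_input) == 0:
        raise ValueError("need at least one covered Alu region")
    out = {}
    for sample, sub in aei_input.groupby("sample"):
        g = float(sub["g_reads"].sum())
        a = float(sub["a_reads"].sum())
        if a + g == 0:
            warnings.warn(f"sample {sample}: zero A+G coverage; AEI missing")
            out[sample] = np.nan
        else:
            out[sample] = 100.0 * g / (a + g)
    return pd.Series(out, name="aei")


_BASES = ("A", "C", "G", "T")


def motif_profile(
    sequences: list[str],
    background: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-position per-base log2 enrichment around edit sites.

    ``sequences`` are flanks of equal odd length centered on the edited
    adenosine (e.g. +/-4 nt). Observed frequencies use a pseudo-count of
    one per cell; enrichment is log2(freq_observed / freq_background).
    Rows are positions relative to the site, columns bases.
    """
    if not sequences:
        raise ValueError("no sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must all have the same length")
    if L % 2 != 1:
        raise ValueError("sequences must have odd length (centered on the site)")
    if background is None:
        background = {b: 0.25 for b in _BASES}
    half = L // 2
    n = len(sequences)
    counts = np.ones((L, len(_BASES)))  # pseudo-count 1 per cell
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for seq in sequences:
        for p, ch in enumerate(seq.upper()):
            if ch in base_idx:
                counts[p, base_idx[ch]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    bg = np.array([background[b] for b in _BASES])
    enrich = np.log2(freq / bg)
    return pd.DataFrame(enrich, index=np.arange(-half, half + 1), columns=list(_BASES))


def overlap_enrichment(
    query: set[str],
    reference_sets: dict[str, set[str]],
    universe: int,
    method: str = "fisher",
) -> pd.DataFrame:
    """Overlap of a query site set with reference sets (2x2 tests).

    For each reference set the 2x2 table is (in both, query only,
    reference only, neither) over a universe of ``universe`` sites;
    p-values are two-sided Fisher exact (or chi-square) and are BH
    adjusted across reference sets.
    """
    rows = []
    for name, ref in reference_sets.items():
        if universe < len(query | ref):
            raise ValueError("universe smaller than the union of sets")
        a = len(query & ref)
        b = len(query - ref)
        c = len(ref - query)
        d = universe - a - b - c
        if len(query) == 0:
            odds, p = 0.0, 1.0
        elif method == "fisher":
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        elif method == "chisq":
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                odds, p = np.nan, 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]])
                odds = (a * d) / (b * c) if b * c > 0 else np.inf
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((name, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows, columns=["reference", "overlap", "query_only", "ref_only", "neither",
                       "odds_ratio", "p"]
    )
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
    else:
        out["q"] = []
    return out
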