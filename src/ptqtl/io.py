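"""Plain-text I/O: VCF, dosage TSV, BED, and the pipeline's result tables.

Coordinate conventions are centralized here: variants and edit sites are
1-based (VCF convention); interval files are 0-based half-open (BED
convention). Conversions happen on read/write, never in analysis code.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qtlmap import GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_sites_bed",
    "read_sites_bed",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path: str | Path, geno: GenotypeMatrix) -> None:
    """Write hardened genotypes as a minimal VCFv4.2 with GT fields."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.donors) + "\n")
        hard = np.round(geno.dosage).astype(int)
        for k, v in enumerate(geno.variants.itertuples(index=False)):
            gts = "\t".join(_GT[int(np.clip(hard[j, k], 0, 2))]
                            for j in range(geno.n_donors))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read biallelic GT dosages from a VCF via cyvcf2.

    Multi-allelic records are skipped (or split into their first ALT when
    ``split_multiallelic``), with a warning either way.
    """
    import warnings

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    rows, dosages = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                          + ("split" if split_multiallelic else "skipped"))
            if not split_multiallelic:
                continue
        gt = np.array(rec.gt_types, dtype=float)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dos = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        rows.append({"id": rec.ID or f"{rec.CHROM}:{rec.POS}", "chrom": rec.CHROM,
                     "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0]})
        dosages.append(dos)
    variants = pd.DataFrame(rows)
    return GenotypeMatrix(donors, variants, np.array(dosages).T)


def write_dosage_tsv(path: str | Path, geno: GenotypeMatrix) -> None:
    df = pd.DataFrame(geno.dosage.T, columns=geno.donors)
    out = pd.concat([geno.variants[["id", "chrom", "pos", "ref", "alt"]], df], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["id", "chrom", "pos", "ref", "alt"]
    donors = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(donors, df[meta], df[donors].to_numpy().T)


def write_sites_bed(path: str | Path, sites: pd.DataFrame) -> None:
    """Edit sites as BED: 0-based half-open single-base intervals."""
    bed = pd.DataFrame(
        {"chrom": sites["chrom"], "start": sites["pos"] - 1, "end": sites["pos"],
         "name": sites["id"], "score": 0,
         "strand": sites.get("strand", pd.Series(["+"] * len(sites)))}
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    return pd.DataFrame(
        {"id": bed["name"], "chrom": bed["chrom"], "pos": bed["start"] + 1,
         "strand": bed["strand"]}
    )
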