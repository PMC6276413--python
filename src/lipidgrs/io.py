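"""Reading and writing the on-disk formats.

Cohort tables travel as plain CSV (one subject per row, header row).
Genotype matrices travel either as a tab-delimited subjects x SNPs matrix
(with an optional ``<stem>.snps.tsv`` annotation sidecar) or as a minimal
VCF: biallelic sites, a single GT FORMAT field, unphased ``0/0``/``0/1``/
``1/1`` calls (``./.`` for missing).  Anything richer than that dialect is
rejected loudly rather than silently reinterpreted.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .synthcohort import GenotypeMatrix

_GT_CODE = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan}
_CODE_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    cohort.to_csv(path, index=True)


def read_cohort_csv(path: str | os.PathLike) -> pd.DataFrame:
    cohort = pd.read_csv(path, index_col="subject_id")
    if cohort.index.duplicated().any():
        dupes = cohort.index[cohort.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject IDs in cohort table: {dupes}")
    return cohort


# ---------------------------------------------------------------------------
# genotype TSV
# ---------------------------------------------------------------------------

def write_genotypes_tsv(gm: GenotypeMatrix, path: str | os.PathLike,
                        write_annotation: bool = True) -> None:
    """Write the subjects x SNPs matrix as TSV (missing as empty cell) and,
    optionally, the SNP annotation as ``<stem>.snps.tsv``."""
    out = gm.genotypes.copy()
    # keep integer rendering (0/1/2) rather than 0.0/1.0/2.0
    out = out.astype("Int64")
    out.to_csv(path, sep="\t", index=True)
    if write_annotation:
        p = Path(path)
        gm.snps.to_csv(p.with_suffix(".snps.tsv"), sep="\t")


def read_genotypes_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    geno = pd.read_csv(path, sep="\t", index_col="subject_id").astype(float)
    bad = set(np.unique(geno.to_numpy()[~np.isnan(geno.to_numpy())])) - {0.0, 1.0, 2.0}
    if bad:
        raise ValueError(f"genotype matrix contains non-genotype values: {sorted(bad)}")
    ann_path = Path(path).with_suffix(".snps.tsv")
    if ann_path.exists():
        snps = pd.read_csv(ann_path, sep="\t", index_col="rsid")
        snps = snps.reindex(geno.columns)
    else:
        snps = pd.DataFrame(
            {"gene": "", "ref": "A", "alt": "G", "chrom": "1",
             "pos": np.arange(1, geno.shape[1] + 1)},
            index=pd.Index(geno.columns, name="rsid"))
    gm = GenotypeMatrix(geno, snps)
    gm.validate()
    return gm


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2: GT-only FORMAT, unphased diploid calls."""
    subjects = list(gm.genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=lipidgrs",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects),
    ]
    for rsid in gm.genotypes.columns:
        ann = gm.snps.loc[rsid]
        calls = [
            _CODE_GT[int(g)] if not np.isnan(g) else "./."
            for g in gm.genotypes[rsid].to_numpy(dtype=float)
        ]
        lines.append("\t".join(
            [str(ann.get("chrom", "1")), str(int(ann.get("pos", 1))), rsid,
             str(ann.get("ref", "A")), str(ann.get("alt", "G")),
             ".", "PASS", ".", "GT"] + calls))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a GT-only VCF into a GenotypeMatrix via cyvcf2.

    Multiallelic sites or phased calls are rejected: the analysis assumes
    biallelic unphased genotypes coded as alternate-allele counts.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols, ann = {}, []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"{var.ID or var.POS}: only biallelic sites are supported "
                f"(ALT={var.ALT})")
        if any(gt[2] for gt in var.genotypes):  # third slot: phased flag
            raise ValueError(f"{var.ID or var.POS}: phased genotypes not supported")
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        g = np.array([a + b if a >= 0 and b >= 0 else np.nan
                      for a, b, *_ in var.genotypes], dtype=float)
        cols[rsid] = g
        ann.append({"rsid": rsid, "gene": "", "ref": var.REF, "alt": var.ALT[0],
                    "chrom": var.CHROM, "pos": var.POS})
    geno = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"))
    gm = GenotypeMatrix(geno, pd.DataFrame(ann).set_index("rsid"))
    gm.validate()
    return gm


def align_cohort_genotypes(cohort: pd.DataFrame, gm: GenotypeMatrix,
                           ) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Exact-string join of cohort and genotype subject IDs; mismatches on
    either side are an error listing the offending IDs."""
    c_ids, g_ids = set(cohort.index), set(gm.genotypes.index)
    if c_ids != g_ids:
        only_c = sorted(c_ids - g_ids)[:10]
        only_g = sorted(g_ids - c_ids)[:10]
        raise ValueError(
            "subject IDs differ between cohort and genotype tables; "
            f"cohort-only={only_c}, genotype-only={only_g}")
    geno = gm.genotypes.loc[cohort.index]
    return cohort, GenotypeMatrix(geno, gm.snps)
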