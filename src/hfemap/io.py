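"""Reading and writing the standard formats the pipeline touches.

Genotypes travel as minimal VCFv4.2 with the two canonical GRCh38 *HFE*
records (chr6:26092913 G>A for p.Cys282Tyr, chr6:26090951 C>G for
p.His63Asp) encoded as separate biallelic sites with unphased diploid GTs.
Count tables and metadata are UTF-8 TSV with a header row; thousands
separators and ``%`` signs, which published tables often carry, are
stripped on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .cohort import C282Y_DOSE, H63D_DOSE, CohortGenotypes, DiagnosisTable
from .errors import FormatError, ValidationError

__all__ = [
    "VariantDef",
    "C282Y",
    "H63D",
    "read_vcf",
    "write_vcf",
    "read_counts_table",
    "write_counts_table",
    "read_region_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantDef:
    label: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


#: Canonical GRCh38 definitions of the two pathogenic HFE sites.
C282Y = VariantDef("C282Y", "chr6", 26092913, "G", "A")
H63D = VariantDef("H63D", "chr6", 26090951, "C", "G")

# genotype class by (C282Y dose, H63D dose)
_CLASS_BY_DOSE = {
    (C282Y_DOSE[c], H63D_DOSE[c]): c
    for c in C282Y_DOSE
}


def write_vcf(cohort: CohortGenotypes, path: str | Path) -> Path:
    """Write a minimal VCFv4.2 file with the two canonical *HFE* records.

    Samples appear in cohort order (the cohort's row order is part of its
    identity); GTs are unphased.  Records are emitted in coordinate order.
    An empty cohort produces a header-only VCF with both site records.
    """
    path = Path(path)
    ids = cohort.individuals["id"].tolist()
    doses = {
        "C282Y": cohort.individuals["genotype_class"].map(C282Y_DOSE).tolist(),
        "H63D": cohort.individuals["genotype_class"].map(H63D_DOSE).tolist(),
    }
    # htslib rejects a FORMAT column when the file carries no samples
    chrom_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if ids:
        chrom_cols += ["FORMAT", *ids]
    lines = [
        "##fileformat=VCFv4.2",
        "##source=hfemap",
        "##contig=<ID=chr6>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "\t".join(chrom_cols),
    ]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    for var in sorted((C282Y, H63D), key=lambda v: v.pos):
        fields = [var.chrom, str(var.pos), var.label, var.ref, var.alt, ".", "PASS",
                  "."]
        if ids:
            fields.append("GT")
            fields.extend(gt[d] for d in doses[var.label])
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _dose_of(genotype: list[int]) -> int | None:
    """ALT-allele dose from a cyvcf2 genotype triple; None if any call missing."""
    alleles = genotype[:-1]  # last entry is the phasing flag
    if any(a < 0 for a in alleles):
        return None
    return sum(1 for a in alleles if a > 0)


def read_vcf(path: str | Path, region_map: dict[str, str]) -> CohortGenotypes:
    """Read the two canonical *HFE* sites into a cohort.

    Every sample must appear in ``region_map``.  Samples with a missing GT
    at either site are excluded and counted in a log summary; samples whose
    two-site calls imply more than two pathogenic alleles (impossible at a
    triallelic locus, e.g. 1/1 plus 0/1) are flagged and excluded with a
    warning.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_doses: dict[str, list[int | None]] = {}
    for record in vcf:
        for var in (C282Y, H63D):
            if (
                record.CHROM == var.chrom
                and record.POS == var.pos
                and record.REF == var.ref
                and var.alt in record.ALT
            ):
                genotypes = record.genotypes or []  # None when the VCF has no samples
                site_doses[var.label] = [_dose_of(g) for g in genotypes]
    for var in (C282Y, H63D):
        if var.label not in site_doses:
            raise FormatError(
                f"VCF is missing the {var.label} site "
                f"({var.chrom}:{var.pos} {var.ref}>{var.alt})"
            )
    unmapped = [s for s in samples if s not in region_map]
    if unmapped:
        raise ValidationError(f"samples without a region label: {unmapped[:5]}...")

    records = []
    n_missing = 0
    for i, sample in enumerate(samples):
        dc = site_doses["C282Y"][i]
        dh = site_doses["H63D"][i]
        if dc is None or dh is None:
            n_missing += 1
            continue
        if dc + dh > 2:
            warnings.warn(
                f"sample {sample}: calls imply {dc + dh} pathogenic alleles; excluded",
                stacklevel=2,
            )
            continue
        records.append((sample, region_map[sample], _CLASS_BY_DOSE[(dc, dh)]))
    if n_missing:
        logger.warning("excluded %d samples with missing GT at either site", n_missing)
    return CohortGenotypes(
        pd.DataFrame(records, columns=["id", "region", "genotype_class"])
    )


def _clean_numeric(series: pd.Series) -> pd.Series:
    """Strip thousands separators and % signs, then coerce to numeric."""
    return pd.to_numeric(
        series.astype(str).str.replace(",", "", regex=False).str.replace(
            "%", "", regex=False
        ).str.strip()
    )


def read_counts_table(path: str | Path) -> DiagnosisTable:
    """Read a TSV with columns ``stratum``, ``count``, ``denominator``.

    Counts that are not multiples of 5 trigger a warning (not an error):
    feasibility-service extracts should arrive rounded.  A count exceeding
    its denominator is a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"stratum", "count", "denominator"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"counts table missing columns: {sorted(missing)}")
    df["count"] = _clean_numeric(df["count"]).astype(int)
    df["denominator"] = _clean_numeric(df["denominator"]).astype(int)
    off_grid = df[df["count"] % 5 != 0]
    if not off_grid.empty:
        warnings.warn(
            f"{len(off_grid)} counts are not multiples of 5 "
            f"(e.g. stratum {off_grid.iloc[0]['stratum']!r})",
            stacklevel=2,
        )
    return DiagnosisTable(df[["stratum", "count", "denominator"]])


def write_counts_table(table: DiagnosisTable, path: str | Path) -> Path:
    path = Path(path)
    table.rows.to_csv(path, sep="\t", index=False)
    return path


def read_region_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (``id``, ``region``) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "region"} <= set(df.columns):
        raise FormatError("region map needs columns: id, region")
    return dict(zip(df["id"], df["region"]))
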