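"""Published aggregate inputs bundled with the package.

These are the public summary tables the analysis runs on — per-group allele
counts from a ~500k-participant biobank, and national EHR diagnosis counts
(ICD-10 E83.1, haemochromatosis) by self-declared ethnicity and by English
region, released rounded to increments of 5.  Individual-level data are
access-controlled and are emulated by :mod:`hfemap.synthetic` instead.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import DiagnosisTable

__all__ = [
    "C282Y_MAC_UKB",
    "UKB_TOTAL_ALLELES",
    "ULTRA_RARE_MAC_TOTAL",
    "DEPRIVATION_DECILE_EXTREMES_PCT",
    "load_group_allele_counts",
    "load_ethnicity_diagnoses",
    "load_regional_diagnoses",
    "load_regional_risk_prevalence",
]

#: Whole-cohort allele count of p.Cys282Tyr and the chromosome total.
C282Y_MAC_UKB = 71_949
UKB_TOTAL_ALLELES = 980_944

#: Summed allele count of the 13 ultra-rare pathogenic *HFE* variants
#: observed at least once (the other catalogued pathogenic variants are
#: absent from the cohort).
ULTRA_RARE_MAC_TOTAL = 201

#: Lowest and highest prevalence across the ten deprivation deciles
#: (white British), in percent.
DEPRIVATION_DECILE_EXTREMES_PCT = (0.154, 0.173)


def _read(name: str) -> pd.DataFrame:
    with resources.files("hfemap.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_group_allele_counts() -> pd.DataFrame:
    """Per-population-group sample sizes and *HFE* minor allele counts.

    Columns: ``group``, ``n`` (individuals), ``mac_c282y``, ``mac_h63d``.
    """
    return _read("ukb_group_allele_counts.tsv")


def load_ethnicity_diagnoses() -> DiagnosisTable:
    """E83.1 diagnosis counts by self-declared ethnicity across NHS England."""
    return DiagnosisTable(_read("nhs_ethnicity_diagnoses.tsv"))


def load_regional_diagnoses() -> DiagnosisTable:
    """E83.1 diagnosis counts among white British by English region."""
    return DiagnosisTable(_read("nhs_region_diagnoses.tsv"))


def load_regional_risk_prevalence() -> pd.DataFrame:
    """Published regional prevalence and combined genetic risk (percent)."""
    return _read("regional_risk_prevalence.tsv")
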