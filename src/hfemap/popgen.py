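"""Allele counting, frequency estimation and Hardy-Weinberg genotype prediction.

Under Hardy-Weinberg equilibrium (HWE) at the triallelic *HFE* locus with
allele frequencies ``p_wt``, ``p_C`` (C282Y) and ``p_H`` (H63D), the six
genotype classes occur with probabilities

    p_wt^2, 2 p_wt p_C, 2 p_wt p_H, p_C^2, 2 p_C p_H, p_H^2.

``p_C^2`` is the predicted frequency of C282Y homozygotes — the major risk
genotype — and ``2 p_C p_H`` that of C282Y/H63D compound heterozygotes.
Squaring the allele frequency is far more precise than counting the rare
observed homozygotes directly, because the ~20-fold more numerous
heterozygotes inform the estimate; this is why regional risk maps are built
from predicted rather than observed genotype frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import C282Y_DOSE, H63D_DOSE, CohortGenotypes
from .display import format_one_in, one_in
from .errors import DegenerateInputError, InvalidFrequencyError, ValidationError

__all__ = [
    "AlleleCounts",
    "HFEFrequencies",
    "GenotypePrediction",
    "TestResult",
    "hwe_class_probabilities",
    "count_alleles",
    "allele_frequency",
    "estimate_frequencies",
    "predict_genotypes",
    "hwe_chisq",
    "compare_frequencies_chisq",
    "aggregate_rare_af",
    "rare_with_c282y_rate",
]

_DOSE = {"C282Y": C282Y_DOSE, "H63D": H63D_DOSE}


@dataclass(frozen=True)
class AlleleCounts:
    """Minor allele count (MAC) out of ``total_alleles`` = 2n chromosomes."""

    stratum: str
    variant: str
    mac: int
    total_alleles: int

    def __post_init__(self) -> None:
        if self.variant not in _DOSE:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if not 0 <= self.mac <= self.total_alleles:
            raise ValidationError(
                f"mac={self.mac} outside [0, total_alleles={self.total_alleles}]"
            )
        if self.total_alleles <= 0:
            raise ValidationError("total_alleles must be positive")


@dataclass(frozen=True)
class HFEFrequencies:
    """Allele frequencies of the triallelic locus; must sum to one."""

    p_c282y: float
    p_h63d: float

    def __post_init__(self) -> None:
        for label, p in (("p_c282y", self.p_c282y), ("p_h63d", self.p_h63d)):
            if not 0.0 <= p <= 1.0:
                raise InvalidFrequencyError(f"{label}={p} outside [0, 1]")
        if self.p_c282y + self.p_h63d > 1.0 + 1e-12:
            raise InvalidFrequencyError("allele frequencies sum to more than 1")

    @property
    def p_wt(self) -> float:
        return 1.0 - self.p_c282y - self.p_h63d


@dataclass(frozen=True)
class GenotypePrediction:
    """HWE-predicted risk-genotype frequencies with 'one in N' renderings."""

    hom_c282y: float
    cmpd_het: float
    hom_h63d: float
    one_in_hom: str
    one_in_cmpd: str


@dataclass(frozen=True)
class TestResult:
    chi2: float
    df: int
    p_value: float
    sided: int  # 1 or 2


def hwe_class_probabilities(p_c282y: float, p_h63d: float) -> dict[str, float]:
    """HWE probabilities of the six genotype classes (sum exactly to 1)."""
    f = HFEFrequencies(p_c282y, p_h63d)  # validates
    pw, pc, ph = f.p_wt, f.p_c282y, f.p_h63d
    return {
        "WT/WT": pw * pw,
        "WT/C282Y": 2 * pw * pc,
        "WT/H63D": 2 * pw * ph,
        "C282Y/C282Y": pc * pc,
        "C282Y/H63D": 2 * pc * ph,
        "H63D/H63D": ph * ph,
    }


def count_alleles(
    cohort: CohortGenotypes, variant: str, stratum: str | None = None
) -> AlleleCounts:
    """Count copies of ``variant`` over a region (or the whole cohort).

    ``mac`` is the sum of allele doses over individuals; ``total_alleles``
    is two chromosomes per individual.
    """
    df = cohort.individuals if stratum is None else cohort.subset(stratum).individuals
    dose = _DOSE[variant]  # KeyError -> caller bug; validated below via AlleleCounts
    mac = int(df["genotype_class"].map(dose).sum())
    return AlleleCounts(
        stratum=stratum or "all",
        variant=variant,
        mac=mac,
        total_alleles=2 * len(df),
    )


def allele_frequency(counts: AlleleCounts) -> float:
    """MAF = MAC / total alleles (reported at 4 decimals in tables)."""
    return counts.mac / counts.total_alleles


def estimate_frequencies(
    cohort: CohortGenotypes, stratum: str | None = None
) -> HFEFrequencies:
    """Estimate both pathogenic allele frequencies from a cohort stratum."""
    return HFEFrequencies(
        p_c282y=allele_frequency(count_alleles(cohort, "C282Y", stratum)),
        p_h63d=allele_frequency(count_alleles(cohort, "H63D", stratum)),
    )


def predict_genotypes(freqs: HFEFrequencies) -> GenotypePrediction:
    """Predicted risk-genotype frequencies: q², 2·p_C·p_H, and H63D homozygotes."""
    hom = freqs.p_c282y**2
    cmpd = 2.0 * freqs.p_c282y * freqs.p_h63d
    return GenotypePrediction(
        hom_c282y=hom,
        cmpd_het=cmpd,
        hom_h63d=freqs.p_h63d**2,
        one_in_hom=format_one_in(one_in(hom)),
        one_in_cmpd=format_one_in(one_in(cmpd)),
    )


def hwe_chisq(hom_ref: int, het: int, hom_alt: int) -> TestResult:
    """Pearson χ² test of HWE for one variant, collapsed to biallelic.

    The third allele is pooled into "other", leaving three genotype counts.
    Expected counts come from the sample allele frequency, so the test has
    one degree of freedom.  Returns the standard upper-tail (two-sided in
    the conventional sense) p-value.
    """
    n = hom_ref + het + hom_alt
    if n <= 0:
        raise DegenerateInputError("no genotypes to test")
    q = (2 * hom_alt + het) / (2 * n)
    p = 1.0 - q
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    if np.any(expected == 0):
        raise DegenerateInputError(
            "an expected genotype count is zero (monomorphic sample)"
        )
    observed = np.array([hom_ref, het, hom_alt], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return TestResult(chi2=chi2, df=1, p_value=float(stats.chi2.sf(chi2, df=1)), sided=2)


def hwe_chisq_for_variant(cohort: CohortGenotypes, variant: str,
                          stratum: str | None = None) -> TestResult:
    """HWE test for one variant directly from a cohort (biallelic collapse)."""
    df = cohort.individuals if stratum is None else cohort.subset(stratum).individuals
    dose = df["genotype_class"].map(_DOSE[variant])
    return hwe_chisq(int((dose == 0).sum()), int((dose == 1).sum()),
                     int((dose == 2).sum()))


def compare_frequencies_chisq(
    a: AlleleCounts, b: AlleleCounts, alternative: str = "a>b"
) -> TestResult:
    """One-sided 2×2 allele-count χ² comparison of two strata.

    The two-sided Pearson χ² (no continuity correction) is halved when the
    observed frequency difference matches ``alternative`` (``"a>b"`` or
    ``"a<b"``); otherwise the one-sided p is one minus that half.
    """
    if alternative not in ("a>b", "a<b"):
        raise ValidationError(f"alternative must be 'a>b' or 'a<b', got {alternative!r}")
    table = np.array(
        [
            [a.mac, a.total_alleles - a.mac],
            [b.mac, b.total_alleles - b.mac],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateInputError("zero margin in 2x2 allele table")
    chi2, p_two, _, _ = stats.chi2_contingency(table, correction=False)
    fa, fb = allele_frequency(a), allele_frequency(b)
    observed_matches = (fa > fb) if alternative == "a>b" else (fa < fb)
    if fa == fb:
        p_one = 0.5
    elif observed_matches:
        p_one = p_two / 2.0
    else:
        p_one = 1.0 - p_two / 2.0
    return TestResult(chi2=float(chi2), df=1, p_value=float(p_one), sided=1)


def aggregate_rare_af(macs: list[int], total_alleles: int) -> float:
    """Combined allele frequency of a set of ultra-rare variants: Σ MAC / total."""
    if total_alleles <= 0:
        raise ValidationError("total_alleles must be positive")
    return sum(macs) / total_alleles


def rare_with_c282y_rate(af_rare: float, p_c282y: float) -> tuple[float, str]:
    """Expected frequency of (ultra-rare variant)/C282Y compound heterozygotes.

    Under HWE this is ``2 · af_rare · p_C``; returned with its "one in N"
    rendering.  Used to show that aggregated ultra-rare pathogenic alleles
    contribute negligibly next to the two common variants.
    """
    for label, p in (("af_rare", af_rare), ("p_c282y", p_c282y)):
        if not 0.0 <= p <= 1.0:
            raise InvalidFrequencyError(f"{label}={p} outside [0, 1]")
    rate = 2.0 * af_rare * p_c282y
    return rate, format_one_in(one_in(rate))
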