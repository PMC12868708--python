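"""Shared domain containers: region definitions, cohort genotypes, diagnosis counts.

The analysis models the two common pathogenic *HFE* missense variants,
p.Cys282Tyr (C282Y) and p.His63Asp (H63D), as three alleles of a single
locus.  Every individual therefore falls into exactly one of six genotype
classes; compound heterozygosity (one C282Y and one H63D allele) is a class
of its own, which is what makes the triallelic treatment convenient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidFrequencyError, ValidationError

__all__ = [
    "GENOTYPE_CLASSES",
    "C282Y_DOSE",
    "H63D_DOSE",
    "RegionSpec",
    "CohortGenotypes",
    "DiagnosisTable",
]

#: The six genotype classes of the triallelic (WT / C282Y / H63D) locus.
GENOTYPE_CLASSES: tuple[str, ...] = (
    "WT/WT",
    "WT/C282Y",
    "WT/H63D",
    "C282Y/C282Y",
    "C282Y/H63D",
    "H63D/H63D",
)

#: Copies of the C282Y allele carried by each genotype class.
C282Y_DOSE: dict[str, int] = {
    "WT/WT": 0,
    "WT/C282Y": 1,
    "WT/H63D": 0,
    "C282Y/C282Y": 2,
    "C282Y/H63D": 1,
    "H63D/H63D": 0,
}

#: Copies of the H63D allele carried by each genotype class.
H63D_DOSE: dict[str, int] = {
    "WT/WT": 0,
    "WT/C282Y": 0,
    "WT/H63D": 1,
    "C282Y/C282Y": 0,
    "C282Y/H63D": 1,
    "H63D/H63D": 2,
}


@dataclass(frozen=True)
class RegionSpec:
    """A region or population group with its pathogenic allele frequencies.

    Parameters
    ----------
    name
        Region / group label (e.g. ``"Birmingham"``).
    p_c282y, p_h63d
        Population frequencies of the two pathogenic alleles; their sum may
        not exceed one (the remainder is the wild-type allele).
    n_individuals
        Cohort size to simulate or that was observed for this region.
    ascertainment
        Probability that a clinically affected person in this region carries
        the diagnostic code in their health record.  This is a modelling
        convenience for emulating under-diagnosis, not an estimate from data.
    """

    name: str
    p_c282y: float
    p_h63d: float
    n_individuals: int
    ascertainment: float = 1.0

    def __post_init__(self) -> None:
        for label, p in (("p_c282y", self.p_c282y), ("p_h63d", self.p_h63d)):
            if not 0.0 <= p <= 1.0:
                raise InvalidFrequencyError(f"{label}={p} outside [0, 1]")
        if self.p_c282y + self.p_h63d > 1.0 + 1e-12:
            raise InvalidFrequencyError(
                f"p_c282y + p_h63d = {self.p_c282y + self.p_h63d} > 1 "
                f"for region {self.name!r}"
            )
        if self.n_individuals < 1:
            raise ValidationError(f"n_individuals must be >= 1, got {self.n_individuals}")
        if not 0.0 <= self.ascertainment <= 1.0:
            raise ValidationError(f"ascertainment={self.ascertainment} outside [0, 1]")

    @property
    def p_wt(self) -> float:
        return 1.0 - self.p_c282y - self.p_h63d


@dataclass
class CohortGenotypes:
    """Per-individual two-site *HFE* genotypes with a region label.

    Wraps a DataFrame with columns ``id``, ``region``, ``genotype_class``;
    row order is meaningful and preserved through I/O round trips.
    """

    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "region", "genotype_class"}
        missing = required - set(self.individuals.columns)
        if missing:
            raise ValidationError(f"cohort frame missing columns: {sorted(missing)}")
        bad = set(self.individuals["genotype_class"]) - set(GENOTYPE_CLASSES)
        if bad:
            raise ValidationError(f"unknown genotype classes: {sorted(bad)}")
        if self.individuals["id"].duplicated().any():
            raise ValidationError("duplicate individual ids in cohort")
        self.individuals = self.individuals.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str]]) -> "CohortGenotypes":
        return cls(pd.DataFrame(records, columns=["id", "region", "genotype_class"]))

    def __len__(self) -> int:
        return len(self.individuals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortGenotypes):
            return NotImplemented
        return self.individuals.equals(other.individuals)

    def regions(self) -> list[str]:
        return sorted(self.individuals["region"].unique())

    def subset(self, region: str) -> "CohortGenotypes":
        df = self.individuals[self.individuals["region"] == region]
        if df.empty:
            raise ValidationError(f"unknown or empty region {region!r}")
        return CohortGenotypes(df.copy())

    def class_counts(self, region: str | None = None) -> pd.Series:
        """Counts of the six genotype classes, over all or one region."""
        df = self.individuals if region is None else self.subset(region).individuals
        return (
            df["genotype_class"].value_counts().reindex(GENOTYPE_CLASSES, fill_value=0)
        )


@dataclass
class DiagnosisTable:
    """Stratified diagnosis counts: (stratum, count, denominator) rows."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"stratum", "count", "denominator"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"diagnosis table missing columns: {sorted(missing)}")
        if (self.rows["count"] < 0).any():
            raise ValidationError("negative diagnosis count")
        if (self.rows["denominator"] <= 0).any():
            raise ValidationError("non-positive denominator")
        bad = self.rows[self.rows["count"] > self.rows["denominator"]]
        if not bad.empty:
            raise ValidationError(
                f"count exceeds denominator for strata: {bad['stratum'].tolist()}"
            )
        self.rows = self.rows.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[tuple[str, int, int]]) -> "DiagnosisTable":
        return cls(pd.DataFrame(records, columns=["stratum", "count", "denominator"]))

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiagnosisTable):
            return NotImplemented
        return self.rows.equals(other.rows)
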