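"""Prevalence arithmetic on stratified diagnosis-count tables.

The raw prevalence of a diagnosis in a stratum is ``100 · count /
denominator`` percent, also rendered as "1 in N" with ``N =
round(denominator / count)``.  Counts released by national EHR feasibility
services arrive rounded to increments of 5 and are used as-is: no
de-rounding correction is applied, and no age or sex standardisation is
performed (strata are opaque labels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort import DiagnosisTable
from .errors import DegenerateInputError, ValidationError

__all__ = ["PrevalenceRecord", "prevalence", "stratified_prevalence", "decile_spread"]


@dataclass(frozen=True)
class PrevalenceRecord:
    stratum: str
    count: int
    denominator: int
    prevalence_pct: float  # full precision; round only for display
    one_in: int | None  # None when count == 0


def prevalence(count: int, denominator: int, stratum: str = "all") -> PrevalenceRecord:
    """Raw prevalence of a stratum: percent and "1 in N"."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if count < 0 or count > denominator:
        raise ValidationError(f"count={count} outside [0, denominator={denominator}]")
    return PrevalenceRecord(
        stratum=stratum,
        count=count,
        denominator=denominator,
        prevalence_pct=100.0 * count / denominator,
        one_in=round(denominator / count) if count > 0 else None,
    )


def stratified_prevalence(table: DiagnosisTable) -> list[PrevalenceRecord]:
    """Prevalence per stratum, sorted by raw prevalence descending.

    Ties break by stratum name, so the ranking is independent of input
    row order.
    """
    if len(table) == 0:
        raise ValidationError("empty diagnosis table")
    records = [
        prevalence(int(r["count"]), int(r["denominator"]), str(r["stratum"]))
        for _, r in table.rows.iterrows()
    ]
    return sorted(records, key=lambda r: (-r.prevalence_pct, r.stratum))


def decile_spread(prevalences_pct: Sequence[float]) -> int:
    """Max-over-min prevalence spread across deciles, as percent excess.

    ``(max/min − 1) · 100`` rounded to the nearest integer; e.g. deciles
    ranging 0.154%–0.173% differ by a factor of only 12%.
    """
    if len(prevalences_pct) < 2:
        raise ValidationError("need at least two deciles")
    lo, hi = min(prevalences_pct), max(prevalences_pct)
    if lo <= 0:
        raise DegenerateInputError("minimum decile prevalence is zero")
    return round((hi / lo - 1.0) * 100.0)
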