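"""Flagging likely under-diagnosis: genetic risk versus observed prevalence.

Where diagnosis rates track the underlying genetics, the ratio of combined
genetic risk to raw diagnosis prevalence should be roughly constant across
regions.  Regions whose ratio is well above the norm have fewer diagnoses
than their gene pool predicts — candidate areas of under-diagnosis.  The
interpretation assumes penetrance is uniform across regions (environmental
modifiers such as dietary iron are a known caveat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "DiscrepancyRecord",
    "risk_prevalence_ratio",
    "rank_discrepancies",
    "pearson_correlation",
]


@dataclass(frozen=True)
class DiscrepancyRecord:
    region: str
    prevalence_pct: float
    risk_pct: float
    ratio: float | None  # None when prevalence is zero
    flagged: bool = False


def risk_prevalence_ratio(risk_pct: float, prevalence_pct: float) -> float | None:
    """Ratio of genetic risk to observed prevalence (both in percent).

    Computed at full precision; display at 2 decimals.  Zero prevalence
    yields the undefined sentinel ``None`` with a warning.
    """
    if prevalence_pct < 0 or risk_pct < 0:
        raise ValidationError("percentages must be non-negative")
    if prevalence_pct == 0:
        warnings.warn("zero prevalence: ratio undefined", stacklevel=2)
        return None
    return risk_pct / prevalence_pct


def make_record(region: str, prevalence_pct: float, risk_pct: float) -> DiscrepancyRecord:
    return DiscrepancyRecord(
        region=region,
        prevalence_pct=prevalence_pct,
        risk_pct=risk_pct,
        ratio=risk_prevalence_ratio(risk_pct, prevalence_pct),
    )


def rank_discrepancies(
    records: Sequence[DiscrepancyRecord], top_k: int = 2
) -> list[DiscrepancyRecord]:
    """Sort highest ratio first and flag the top-k as likely under-diagnosed.

    Undefined ratios sort last; ties break by region name so the ranking is
    stable across runs.
    """
    if not records:
        raise ValidationError("need at least one record")
    ordered = sorted(
        records,
        key=lambda r: (r.ratio is None, -(r.ratio or 0.0), r.region),
    )
    return [
        DiscrepancyRecord(
            region=r.region,
            prevalence_pct=r.prevalence_pct,
            risk_pct=r.risk_pct,
            ratio=r.ratio,
            flagged=(i < top_k and r.ratio is not None),
        )
        for i, r in enumerate(ordered)
    ]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation between prevalence and risk vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in one of the vectors")
    return float(np.corrcoef(x, y)[0, 1])
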