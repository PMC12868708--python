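"""Penetrance-weighted combined genetic risk of haemochromatosis per region.

The combined risk is the penetrance-weighted sum over the two risk
genotypes:

    risk = pen_hom · p_C²  +  pen_cmpd · 2 · p_C · p_H

where ``pen_hom`` and ``pen_cmpd`` are the cumulative incidences of
clinical iron overload to age 80 for C282Y homozygotes and C282Y/H63D
compound heterozygotes.  The default penetrances (0.56 and 0.06) are the
male values; female penetrance is lower and no consensus figure exists, so
a female model must be supplied explicitly.  Simple heterozygotes and H63D
homozygotes carry zero risk in this model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .display import format_one_in, one_in
from .errors import ValidationError
from .popgen import HFEFrequencies, predict_genotypes

__all__ = [
    "PenetranceModel",
    "MALE_PENETRANCE",
    "RegionalRisk",
    "combined_risk",
    "risk_table",
    "solve_p_c282y",
]


@dataclass(frozen=True)
class PenetranceModel:
    """Cumulative-incidence penetrances for the two risk genotypes."""

    pen_hom_c282y: float = 0.56
    pen_cmpd_het: float = 0.06
    label: str = "male, cumulative to age 80"

    def __post_init__(self) -> None:
        for name, p in (
            ("pen_hom_c282y", self.pen_hom_c282y),
            ("pen_cmpd_het", self.pen_cmpd_het),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.pen_cmpd_het > self.pen_hom_c282y:
            warnings.warn(
                "compound-heterozygote penetrance exceeds homozygote penetrance",
                stacklevel=2,
            )

    def by_class(self) -> dict[str, float]:
        """Per-genotype-class penetrance; classes not listed have zero risk."""
        return {
            "WT/WT": 0.0,
            "WT/C282Y": 0.0,
            "WT/H63D": 0.0,
            "C282Y/C282Y": self.pen_hom_c282y,
            "C282Y/H63D": self.pen_cmpd_het,
            "H63D/H63D": 0.0,
        }


#: Male cumulative incidence to age 80 — the default model for risk maps.
MALE_PENETRANCE = PenetranceModel()


@dataclass(frozen=True)
class RegionalRisk:
    region: str
    risk: float
    risk_pct: float
    one_in: str
    penetrance_label: str


def combined_risk(
    freqs: HFEFrequencies,
    pen: PenetranceModel = MALE_PENETRANCE,
    region: str = "all",
) -> RegionalRisk:
    """Penetrance-weighted combined genetic risk for one region."""
    g = predict_genotypes(freqs)
    risk = pen.pen_hom_c282y * g.hom_c282y + pen.pen_cmpd_het * g.cmpd_het
    return RegionalRisk(
        region=region,
        risk=risk,
        risk_pct=100.0 * risk,
        one_in=format_one_in(one_in(risk)),
        penetrance_label=pen.label,
    )


def risk_table(
    freqs_by_region: dict[str, HFEFrequencies],
    pen: PenetranceModel = MALE_PENETRANCE,
) -> list[RegionalRisk]:
    """Combined risk for every region, sorted descending (ties by name)."""
    if not freqs_by_region:
        raise ValidationError("need at least one region")
    rows = [combined_risk(f, pen, region=name) for name, f in freqs_by_region.items()]
    return sorted(rows, key=lambda r: (-r.risk, r.region))


def solve_p_c282y(
    risk: float, p_h63d: float, pen: PenetranceModel = MALE_PENETRANCE
) -> float:
    """Invert the combined-risk formula for ``p_C`` at fixed ``p_H``.

    Solves ``pen_hom · p² + 2 · pen_cmpd · p_H · p − risk = 0`` for the
    positive root.  Useful for reconstructing the allele frequency implied
    by a published regional risk figure.
    """
    if risk < 0:
        raise ValidationError("risk must be non-negative")
    a = pen.pen_hom_c282y
    b = 2.0 * pen.pen_cmpd_het * p_h63d
    if a == 0:
        if b == 0:
            raise ValidationError("penetrances are both zero; risk is not invertible")
        return risk / b
    return (-b + math.sqrt(b * b + 4.0 * a * risk)) / (2.0 * a)
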