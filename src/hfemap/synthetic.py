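"""Synthetic cohorts, diagnosis registries, PC clouds and IBD segment lists.

Individual-level genotype and health-record data of the kind this analysis
runs on are access-controlled, so every downstream stage is exercised on
synthetic data with the same statistical structure:

* genotypes drawn per region from the six-class triallelic HWE multinomial;
* diagnosis counts driven by genotype penetrance and a region-specific
  ascertainment probability, optionally rounded to increments of 5 the way
  national EHR feasibility services release counts;
* isotropic Gaussian clouds in the top-2 principal-component plane, one per
  population group, plus uniform background noise;
* pairwise IBD segments with planted community structure, lengths confined
  to the (3, 30) cM window the sharing graph is built from.

All generators are deterministic functions of their inputs and a seed.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GENOTYPE_CLASSES, CohortGenotypes, DiagnosisTable, RegionSpec
from .errors import ValidationError
from .popgen import hwe_class_probabilities
from .risk import PenetranceModel

__all__ = [
    "PCGroup",
    "simulate_genotypes",
    "simulate_diagnoses",
    "simulate_pc_cloud",
    "simulate_ibd_segments",
    "round_to_nearest_5",
]


def simulate_genotypes(specs: Sequence[RegionSpec], seed: int) -> CohortGenotypes:
    """Draw per-region genotype classes from the triallelic HWE multinomial.

    Individual ids are ``<region>-<i>``; rows are grouped by region in the
    order given.  Reproducible: equal (specs, seed) give identical cohorts.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        probs = hwe_class_probabilities(spec.p_c282y, spec.p_h63d)
        counts = rng.multinomial(spec.n_individuals, list(probs.values()))
        classes = np.repeat(list(GENOTYPE_CLASSES), counts)
        rng.shuffle(classes)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{spec.name}-{i}" for i in range(spec.n_individuals)],
                    "region": spec.name,
                    "genotype_class": classes,
                }
            )
        )
    return CohortGenotypes(pd.concat(frames, ignore_index=True))


def round_to_nearest_5(count: int) -> int:
    """Round to the nearest multiple of 5, halves away from zero (2.5 -> 5)."""
    return int(5 * np.floor(count / 5 + 0.5))


def simulate_diagnoses(
    cohort: CohortGenotypes,
    penetrance: PenetranceModel,
    specs: Sequence[RegionSpec],
    round_to_5: bool = False,
    seed: int = 0,
) -> DiagnosisTable:
    """Simulate per-region diagnosis counts from genotypes.

    Each individual is coded with probability
    ``penetrance(genotype_class) × ascertainment(region)``: only C282Y
    homozygotes and C282Y/H63D compound heterozygotes have non-zero
    penetrance in this model.  With ``round_to_5`` the released counts are
    rounded to the nearest increment of 5, emulating EHR feasibility-service
    output, so |released − true| ≤ 2.5.
    """
    by_name = {s.name: s for s in specs}
    missing = set(cohort.regions()) - set(by_name)
    if missing:
        raise ValidationError(f"cohort regions not covered by specs: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    pen = penetrance.by_class()
    records = []
    for region in cohort.regions():
        df = cohort.subset(region).individuals
        p_code = df["genotype_class"].map(pen).to_numpy() * by_name[region].ascertainment
        count = int((rng.random(len(df)) < p_code).sum())
        if round_to_5:
            count = round_to_nearest_5(count)
        records.append((region, count, len(df)))
    return DiagnosisTable.from_records(records)


@dataclass(frozen=True)
class PCGroup:
    """A population group's Gaussian cloud in the top-2 PC plane."""

    label: str
    centroid: tuple[float, float]
    spread: float
    n: int

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValidationError(f"spread must be > 0, got {self.spread}")
        if self.n < 0:
            raise ValidationError("group size must be non-negative")


def simulate_pc_cloud(
    groups: Sequence[PCGroup],
    noise_n: int = 0,
    noise_box: tuple[float, float, float, float] = (-10.0, 10.0, -10.0, 10.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled 2-D points: one isotropic Gaussian per group plus uniform noise.

    Returns a frame with columns ``id``, ``pc1``, ``pc2``, ``label``; noise
    points carry the label ``"noise"``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for g in groups:
        xy = rng.normal(loc=g.centroid, scale=g.spread, size=(g.n, 2))
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{g.label}-{i}" for i in range(g.n)],
                    "pc1": xy[:, 0],
                    "pc2": xy[:, 1],
                    "label": g.label,
                }
            )
        )
    if noise_n:
        x0, x1, y0, y1 = noise_box
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"noise-{i}" for i in range(noise_n)],
                    "pc1": rng.uniform(x0, x1, noise_n),
                    "pc2": rng.uniform(y0, y1, noise_n),
                    "label": "noise",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _uniform_lengths(rng: np.random.Generator, size: int) -> np.ndarray:
    # open-interval support: resample the measure-zero endpoint hits
    out = rng.uniform(3.0, 30.0, size)
    while np.any((out <= 3.0) | (out >= 30.0)):
        bad = (out <= 3.0) | (out >= 30.0)
        out[bad] = rng.uniform(3.0, 30.0, bad.sum())
    return out


def simulate_ibd_segments(
    communities: Sequence[tuple[str, int]],
    within_rate: float,
    between_rate: float,
    length_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise IBD segments with planted community structure.

    For each unordered pair of individuals the number of shared segments is
    Poisson with mean ``within_rate`` (same community) or ``between_rate``
    (different communities); lengths are drawn from ``length_law`` (default
    uniform on the open interval (3, 30) cM).  Returns a frame with columns
    ``id_a``, ``id_b``, ``length_cm``, ``truth_a``, ``truth_b`` — the truth
    columns carry the planted labels for evaluation and are not consumed by
    the graph builder.
    """
    if not within_rate > between_rate >= 0:
        raise ValidationError("require within_rate > between_rate >= 0")
    law = length_law or _uniform_lengths
    rng = np.random.default_rng(seed)
    ids, labels = [], []
    for label, n in communities:
        ids.extend(f"{label}-{i}" for i in range(n))
        labels.extend([label] * n)
    n_tot = len(ids)
    ia, ib = np.triu_indices(n_tot, k=1)
    lab = np.asarray(labels)
    rates = np.where(lab[ia] == lab[ib], within_rate, between_rate)
    n_segs = rng.poisson(rates)
    pair_idx = np.repeat(np.arange(len(ia)), n_segs)
    lengths = law(rng, len(pair_idx))
    idarr = np.asarray(ids)
    return pd.DataFrame(
        {
            "id_a": idarr[ia[pair_idx]],
            "id_b": idarr[ib[pair_idx]],
            "length_cm": lengths,
            "truth_a": lab[ia[pair_idx]],
            "truth_b": lab[ib[pair_idx]],
        }
    )
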