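import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hfemap.cohort import RegionSpec
from hfemap.errors import InvalidFrequencyError, ValidationError
from hfemap.popgen import hwe_class_probabilities
from hfemap.risk import PenetranceModel
from hfemap.synthetic import (
    PCGroup,
    round_to_nearest_5,
    simulate_diagnoses,
    simulate_genotypes,
    simulate_ibd_segments,
    simulate_pc_cloud,
)


class TestGenotypeSimulation:
    @pytest.mark.parametrize(
        "p_c,p_h,expected_class",
        [(1.0, 0.0, "C282Y/C282Y"), (0.0, 0.0, "WT/WT"), (0.0, 1.0, "H63D/H63D")],
    )
    def test_degenerate_frequencies(self, p_c, p_h, expected_class):
        cohort = simulate_genotypes([RegionSpec("X", p_c, p_h, 50)], seed=0)
        assert set(cohort.individuals["genotype_class"]) == {expected_class}
        assert len(cohort) == 50

    def test_reproducible_for_equal_seeds(self, british_spec):
        a = simulate_genotypes([british_spec], seed=42)
        b = simulate_genotypes([british_spec], seed=42)
        c = simulate_genotypes([british_spec], seed=43)
        assert a == b
        assert a != c

    def test_invalid_frequency_sum_rejected(self):
        with pytest.raises(InvalidFrequencyError):
            RegionSpec("X", 0.6, 0.5, 10)

    def test_class_proportions_follow_the_multinomial(self):
        """Chi-square goodness of fit should reject at roughly the nominal rate."""
        probs = list(hwe_class_probabilities(0.078, 0.151).values())
        rng = np.random.default_rng(7)
        n, reps, rejections = 2000, 500, 0
        for _ in range(reps):
            counts = rng.multinomial(n, probs)
            _, p = stats.chisquare(counts, n * np.asarray(probs))
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_sampled_cohort_matches_expected_composition(self, british_spec):
        cohort = simulate_genotypes([british_spec], seed=3)
        counts = cohort.class_counts("Britain")
        probs = hwe_class_probabilities(0.078, 0.151)
        _, p = stats.chisquare(
            counts[list(probs)], british_spec.n_individuals * np.array(list(probs.values()))
        )
        assert p > 0.001


class TestDiagnosisSimulation:
    def test_zero_ascertainment_gives_zero_counts(self, british_spec):
        spec = RegionSpec("Britain", 0.078, 0.151, 10_000, ascertainment=0.0)
        cohort = simulate_genotypes([spec], seed=1)
        table = simulate_diagnoses(cohort, PenetranceModel(), [spec], seed=2)
        assert (table.rows["count"] == 0).all()

    def test_full_penetrance_counts_homozygotes_exactly(self):
        spec = RegionSpec("X", 0.3, 0.1, 5000, ascertainment=1.0)
        cohort = simulate_genotypes([spec], seed=5)
        pen = PenetranceModel(pen_hom_c282y=1.0, pen_cmpd_het=0.0)
        table = simulate_diagnoses(cohort, pen, [spec], round_to_5=False, seed=6)
        n_hom = int((cohort.individuals["genotype_class"] == "C282Y/C282Y").sum())
        assert int(table.rows["count"].iloc[0]) == n_hom

    def test_uncovered_region_rejected(self, british_spec):
        cohort = simulate_genotypes([british_spec], seed=1)
        other = RegionSpec("Elsewhere", 0.01, 0.01, 10)
        with pytest.raises(ValidationError):
            simulate_diagnoses(cohort, PenetranceModel(), [other], seed=0)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True)
    def test_rounding_to_5_never_moves_more_than_2_5(self, count):
        assert abs(round_to_nearest_5(count) - count) <= 2.5
        assert round_to_nearest_5(count) % 5 == 0


class TestPCCloud:
    def test_single_group_without_noise(self):
        pc = simulate_pc_cloud([PCGroup("A", (0, 0), 1.0, 30)], seed=0)
        assert set(pc["label"]) == {"A"}
        assert len(pc) == 30

    def test_noise_points_labelled_noise(self):
        pc = simulate_pc_cloud([PCGroup("A", (0, 0), 1.0, 10)], noise_n=5, seed=0)
        assert (pc["label"] == "noise").sum() == 5

    def test_bit_identical_across_runs(self):
        groups = [PCGroup("A", (0, 0), 0.5, 20), PCGroup("B", (3, 3), 0.5, 20)]
        a = simulate_pc_cloud(groups, noise_n=4, seed=9)
        b = simulate_pc_cloud(groups, noise_n=4, seed=9)
        assert a.equals(b)

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(ValidationError):
            PCGroup("A", (0, 0), 0.0, 5)


class TestIBDSegments:
    def test_lengths_strictly_inside_window(self):
        segs = simulate_ibd_segments([("a", 20), ("b", 20)], 2.0, 0.1, seed=0)
        assert ((segs["length_cm"] > 3) & (segs["length_cm"] < 30)).all()

    def test_zero_between_rate_keeps_communities_disjoint(self):
        segs = simulate_ibd_segments([("a", 15), ("b", 15)], 1.5, 0.0, seed=1)
        assert (segs["truth_a"] == segs["truth_b"]).all()

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValidationError):
            simulate_ibd_segments([("a", 5)], 0.1, 0.2, seed=0)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_ibd_segments([("a", 10), ("b", 10)], 1.0, 0.1, seed=4)
        b = simulate_ibd_segments([("a", 10), ("b", 10)], 1.0, 0.1, seed=4)
        assert a.equals(b)
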