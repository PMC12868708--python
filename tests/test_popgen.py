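import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import chi2_2x2_oracle, hwe_chi2_oracle

from hfemap.display import format_frequency_as_one_in, format_one_in, one_in
from hfemap.errors import DegenerateInputError, ValidationError
from hfemap.popgen import (
    AlleleCounts,
    HFEFrequencies,
    aggregate_rare_af,
    allele_frequency,
    compare_frequencies_chisq,
    count_alleles,
    estimate_frequencies,
    hwe_chisq,
    hwe_class_probabilities,
    predict_genotypes,
    rare_with_c282y_rate,
)
from hfemap.synthetic import simulate_genotypes

# small valid frequency pairs for property tests
freq_pairs = st.tuples(
    st.floats(0, 0.5), st.floats(0, 0.5)
).filter(lambda t: t[0] + t[1] <= 1.0)


class TestAlleleCounting:
    def test_hand_counted_macs(self, tiny_cohort):
        c = count_alleles(tiny_cohort, "C282Y", "Demo")
        assert (c.mac, c.total_alleles) == (3, 6)
        h = count_alleles(tiny_cohort, "H63D", "Demo")
        assert (h.mac, h.total_alleles) == (0, 6)
        assert count_alleles(tiny_cohort, "H63D", "Other").mac == 1

    def test_whole_cohort_stratum(self, tiny_cohort):
        c = count_alleles(tiny_cohort, "C282Y")
        assert (c.stratum, c.mac, c.total_alleles) == ("all", 3, 8)

    def test_unknown_stratum_errors(self, tiny_cohort):
        with pytest.raises(ValidationError):
            count_alleles(tiny_cohort, "C282Y", "Atlantis")

    @pytest.mark.parametrize(
        "mac,total,expected",
        [
            (63_763, 817_560, 0.0780),  # large European-heritage group
            (34, 4_342, 0.0078),  # Afro-Caribbean group
            (0, 100, 0.0),
        ],
    )
    def test_allele_frequency_reported_values(self, mac, total, expected):
        f = allele_frequency(AlleleCounts("s", "C282Y", mac, total))
        assert round(f, 4) == expected


class TestGenotypePrediction:
    def test_major_risk_genotype_from_maf(self):
        pred = predict_genotypes(HFEFrequencies(0.0780, 0.1510))
        assert round(pred.hom_c282y, 5) == 0.00608
        assert pred.one_in_hom == "164"
        assert pred.cmpd_het == pytest.approx(2 * 0.0780 * 0.1510)

    def test_zero_frequency_has_no_finite_one_in(self):
        pred = predict_genotypes(HFEFrequencies(0.0, 0.1))
        assert pred.hom_c282y == 0.0
        assert pred.one_in_hom == "inf"

    @given(freq_pairs)
    @settings(derandomize=True)
    def test_six_class_probabilities_sum_to_one(self, pair):
        probs = hwe_class_probabilities(*pair)
        assert math.isclose(sum(probs.values()), 1.0, abs_tol=1e-12)

    def test_parameter_recovery_within_three_se(self, british_spec):
        cohort = simulate_genotypes([british_spec], seed=11)
        est = estimate_frequencies(cohort, "Britain")
        n_alleles = 2 * british_spec.n_individuals
        for p_true, p_hat in [
            (british_spec.p_c282y, est.p_c282y),
            (british_spec.p_h63d, est.p_h63d),
        ]:
            se = math.sqrt(p_true * (1 - p_true) / n_alleles)
            assert abs(p_hat - p_true) <= 3 * se


class TestHWETest:
    def test_exact_hwe_counts_give_zero_statistic(self):
        res = hwe_chisq(25, 50, 25)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_longhand_formula(self):
        res = hwe_chisq(30, 40, 30)
        assert res.chi2 == pytest.approx(hwe_chi2_oracle(30, 40, 30))

    @given(
        st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
    )
    @settings(derandomize=True, max_examples=50)
    def test_oracle_equivalence_on_random_counts(self, a, b, c):
        assert hwe_chisq(a, b, c).chi2 == pytest.approx(hwe_chi2_oracle(a, b, c))

    def test_monomorphic_sample_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            hwe_chisq(100, 0, 0)


class TestRegionComparison:
    def test_identical_tables_give_half_p(self):
        a = AlleleCounts("a", "C282Y", 20, 200)
        b = AlleleCounts("b", "C282Y", 20, 200)
        res = compare_frequencies_chisq(a, b, "a>b")
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_matches_2x2_oracle(self):
        a = AlleleCounts("a", "C282Y", 20, 200)
        b = AlleleCounts("b", "C282Y", 10, 200)
        res = compare_frequencies_chisq(a, b, "a>b")
        assert res.chi2 == pytest.approx(chi2_2x2_oracle(20, 180, 10, 190))
        assert res.p_value < 0.5  # direction matches

    def test_swapping_samples_maps_p_to_one_minus_p(self):
        a = AlleleCounts("a", "C282Y", 20, 200)
        b = AlleleCounts("b", "C282Y", 10, 200)
        p_ab = compare_frequencies_chisq(a, b, "a>b").p_value
        p_ba = compare_frequencies_chisq(b, a, "a>b").p_value
        assert p_ab + p_ba == pytest.approx(1.0)

    def test_chi2_scales_with_sample_size(self):
        a = AlleleCounts("a", "C282Y", 200, 2000)
        b = AlleleCounts("b", "C282Y", 100, 2000)
        a2 = AlleleCounts("a", "C282Y", 400, 4000)
        b2 = AlleleCounts("b", "C282Y", 200, 4000)
        chi_1 = compare_frequencies_chisq(a, b).chi2
        chi_2 = compare_frequencies_chisq(a2, b2).chi2
        assert chi_2 == pytest.approx(2 * chi_1, rel=1e-6)


class TestRareVariantAggregation:
    def test_combined_ultra_rare_frequency(self):
        af = aggregate_rare_af([100, 60, 41], 980_944)
        assert af == pytest.approx(201 / 980_944)
        assert f"{af:.1e}" == "2.0e-04"

    def test_empty_list_gives_zero(self):
        assert aggregate_rare_af([], 1000) == 0.0

    def test_single_mac_consistent_with_allele_frequency(self):
        counts = AlleleCounts("s", "C282Y", 7, 1000)
        assert aggregate_rare_af([7], 1000) == allele_frequency(counts)

    def test_rare_with_c282y_compound_het_rate(self):
        af_rare = 201 / 980_944
        p_c = 71_949 / 980_944
        rate, formatted = rare_with_c282y_rate(af_rare, p_c)
        assert rate == pytest.approx(2 * af_rare * p_c)
        assert formatted == "33k"
        # linearity in the rare-variant frequency
        assert rare_with_c282y_rate(2 * af_rare, p_c)[0] == pytest.approx(2 * rate)
        assert rare_with_c282y_rate(0.0, p_c)[0] == 0.0


class TestOneInFormatting:
    @pytest.mark.parametrize(
        "freq,expected",
        [
            (0.006084, "164"),
            (1 / 849, "849"),
            (0.00037, "2.7k"),
            (6.13e-5, "16k"),
            (5.3e-6, "190k"),
            (1.6e-7, "6.2 M"),  # 6,250,000 -> round-half-even at 2 sig figs
            (0.0, "inf"),
        ],
    )
    def test_formatting_conventions(self, freq, expected):
        assert format_frequency_as_one_in(freq) == expected

    def test_round_to_nearest(self):
        assert one_in(0.006084) == 164
        assert format_one_in(None) == "inf"
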