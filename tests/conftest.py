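import pytest

from hfemap.cohort import CohortGenotypes, RegionSpec


@pytest.fixture
def tiny_cohort() -> CohortGenotypes:
    """Three hand-countable individuals: 3 C282Y copies, 1 H63D copy."""
    return CohortGenotypes.from_records(
        [
            ("s1", "Demo", "C282Y/C282Y"),
            ("s2", "Demo", "WT/C282Y"),
            ("s3", "Demo", "WT/WT"),
            ("s4", "Other", "WT/H63D"),
        ]
    )


@pytest.fixture
def british_spec() -> RegionSpec:
    """Study-scale allele frequencies for a simulated region."""
    return RegionSpec("Britain", p_c282y=0.078, p_h63d=0.151, n_individuals=10_000)
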