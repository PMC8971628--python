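import pytest

from famvar.core.pedigree import Member, Pedigree, make_groups
from famvar.synth import SimulationConfig, simulate_pedigree, simulate_variant_set


@pytest.fixture(scope="session")
def template_pedigree() -> Pedigree:
    return simulate_pedigree(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def template_groups(template_pedigree):
    return make_groups(template_pedigree)


@pytest.fixture(scope="session")
def default_variant_set(template_pedigree):
    """2,000 background variants plus the planted driver (seed 0)."""
    config = SimulationConfig(seed=0)
    records, truth = simulate_variant_set(template_pedigree, config)
    return records, truth


@pytest.fixture(scope="session")
def small_variant_set(template_pedigree):
    config = SimulationConfig(seed=1, n_background_variants=200)
    records, truth = simulate_variant_set(template_pedigree, config)
    return records, truth


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Member("DAD", "male", "unaffected", 1),
            Member("MOM", "female", "unaffected", 1),
            Member("KID", "female", "affected", 2, "DAD", "MOM"),
        ]
    )


@pytest.fixture
def six_member_pedigree() -> Pedigree:
    """Three generations, six members, mixed statuses."""
    return Pedigree(
        [
            Member("F", "male", "affected", 1),
            Member("M", "female", "unaffected", 1),
            Member("S1", "male", "affected", 2, "F", "M"),
            Member("S2", "female", "unaffected", 2, "F", "M"),
            Member("H", "male", "unaffected", 1),
            Member("K", "female", "affected", 3, "H", "S2"),
        ]
    )
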