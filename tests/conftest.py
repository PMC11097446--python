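import pytest

from hapharm.pedigree import assign_cohorts, equivalent_complete_generations
from hapharm.simulate import SimConfig, simulate_dataset


def cohort_table(ds):
    """Cohort assignment for a synthetic dataset (BP = founders)."""
    t = equivalent_complete_generations(ds.ped)
    return assign_cohorts(t, ds.ped.founders())


@pytest.fixture(scope="session")
def clean_ds():
    """Three-generation dataset without planted errors or lethals."""
    cfg = SimConfig(
        seed=11,
        n_founders=12,
        n_generations=3,
        families_per_generation=5,
        offspring_range=(5, 9),
        n_blocks=30,
        adi_rate=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def adi_ds():
    """Dataset with random (non-heritable) Allele-Drop-In errors."""
    cfg = SimConfig(
        seed=7,
        n_founders=12,
        n_generations=3,
        families_per_generation=5,
        offspring_range=(5, 9),
        n_blocks=40,
        adi_rate=0.004,
        adi_heritable_fraction=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def heritable_adi_ds():
    """Dataset where every Allele-Drop-In event is transmissible."""
    cfg = SimConfig(
        seed=19,
        n_founders=16,
        n_generations=3,
        families_per_generation=7,
        offspring_range=(6, 12),
        n_blocks=120,
        adi_rate=0.01,
        adi_heritable_fraction=1.0,
    )
    return simulate_dataset(cfg)
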