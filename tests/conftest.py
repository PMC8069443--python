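import numpy as np
import pytest

from woodlact import (
    BreedProfile,
    WoodParameters,
    default_breed_profiles,
    schedule_full,
    simulate_herd,
)

FULL_GRID = np.array(schedule_full().dims, dtype=float)


def tiny_profiles(n_animals=8, **dispersion):
    """Two small breed profiles for fast herd-level tests."""
    base = dict(animal_cv=0.2, shape_sd_b=0.05, shape_sd_c=0.001, noise_cv=0.1)
    base.update(dispersion)
    return [
        BreedProfile(
            breed="Alpha",
            n_animals=n_animals,
            milk_params=WoodParameters(900.0, 0.20, 0.0045),
            fat_params=WoodParameters(900.0 * 0.040, 0.17, 0.0042),
            protein_params=WoodParameters(900.0 * 0.033, 0.18, 0.0043),
            **base,
        ),
        BreedProfile(
            breed="Beta",
            n_animals=n_animals,
            milk_params=WoodParameters(2400.0, 0.26, 0.0052),
            fat_params=WoodParameters(2400.0 * 0.034, 0.23, 0.0049),
            protein_params=WoodParameters(2400.0 * 0.033, 0.24, 0.0050),
            **base,
        ),
    ]


@pytest.fixture(scope="session")
def default_herd():
    """One default 465-animal herd, shared across tests."""
    return simulate_herd(default_breed_profiles(), master_seed=20260919)


@pytest.fixture
def small_herd():
    return simulate_herd(tiny_profiles(), master_seed=11)


@pytest.fixture
def noiseless_herd():
    profiles = tiny_profiles(
        n_animals=4, animal_cv=0.0, shape_sd_b=0.0, shape_sd_c=0.0, noise_cv=0.0
    )
    return simulate_herd(profiles, master_seed=5)
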