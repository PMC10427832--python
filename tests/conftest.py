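import numpy as np
import pytest

from avianiche.data_prep import prepare_dataset
from avianiche.synthetic_data import (
    GeneratorConfig,
    TraitGeneratorConfig,
    generate_dataset,
    simulate_traits,
)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The standard fixture: 15 species / 5 families / 250 sites, seed 1."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def prepared(fixture_dataset):
    ds, traits = fixture_dataset
    prep, scaler, kept = prepare_dataset(ds)
    return prep, scaler, kept


@pytest.fixture(scope="session")
def small_survey():
    """A fast-fitting survey: 6 species, 100 sites, 3 vegetation classes."""
    cfg = GeneratorConfig(
        n_species=6, n_sites=100, n_veg_categories=3,
        detection_gamma=(0.0, -0.2, 0.2), seed=7,
    )
    return generate_dataset(cfg, n_families=2)


@pytest.fixture()
def trait_config():
    fam = {f"sp{i:02d}": f"fam{i % 3 + 1}" for i in range(1, 10)}
    return TraitGeneratorConfig(family_assignment=fam, seed=3)


@pytest.fixture()
def traits(trait_config):
    return simulate_traits(trait_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
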