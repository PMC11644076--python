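import pandas as pd
import pytest

from rhizoscreen.simulate import (
    SimulationConfig,
    TraitSpec,
    generate_dataset,
    wheat_screen_preset,
)
from rhizoscreen.traits import derive_traits


def small_config(seed: int = 3, **overrides) -> SimulationConfig:
    """A 12-genotype x 4-treatment x 3-block config for fast tests."""
    base = wheat_screen_preset(seed=seed)
    kwargs = dict(n_genotypes=12, n_blocks=3, traits=base.traits, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_plants() -> pd.DataFrame:
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_traits(small_plants) -> pd.DataFrame:
    return derive_traits(small_plants)


def noise_free_config(seed: int = 0) -> SimulationConfig:
    """All variance components zero, all multipliers 1."""
    base = wheat_screen_preset(seed=seed)
    traits = {
        name: TraitSpec(
            mean=s.mean,
            multipliers={t: 1.0 for t in base.treatments},
            integer=s.integer,
        )
        for name, s in base.traits.items()
    }
    return SimulationConfig(n_genotypes=4, n_blocks=2, traits=traits, seed=seed)
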