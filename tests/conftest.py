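import numpy as np
import pandas as pd
import pytest

from fammod import Lineage, PlantedModule, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_meta():
    """Eight archaeal genomes over three phyla, four of them DPANN."""
    return pd.DataFrame(
        {
            "genome_id": [f"g{i}" for i in range(1, 9)],
            "domain": ["archaea"] * 8,
            "phylum": ["Pace", "Pace", "Woese", "Woese", "Thermo", "Thermo", "Thermo", "Thermo"],
            "is_dpann": [True, True, True, True, False, False, False, False],
        }
    )


@pytest.fixture
def noise_free_config():
    """Three DPANN-only planted modules, no background, no noise."""
    lineages = (
        Lineage("Pace", is_dpann=True),
        Lineage("Woese", is_dpann=True),
        Lineage("Aenigma", is_dpann=True),
        Lineage("Thermoplasma", is_dpann=False),
    )
    modules = tuple(
        PlantedModule(size=s, carrier_lineages=(lineages[i].name,))
        for i, s in enumerate((25, 25, 25))
    )
    return SimConfig(
        lineages=lineages,
        n_genomes_per_lineage=15,
        n_background_families=0,
        planted_modules=modules,
        flip_noise=0.0,
        seed=7,
    )


@pytest.fixture
def noise_free_dataset(noise_free_config):
    return simulate_dataset(noise_free_config)
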