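import numpy as np
import pytest

from gsmix import ChainSettings, encode_design
from gsmix.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def poly_population():
    """Small population with purely polygenic + cage genetics."""
    cfg = SimulationConfig(
        n_families=18, fixed_family_size=11, n_markers=40,
        n_burnin_generations=10, burnin_population=60,
        n_qtl=0, h2_qtl=0.0, h2_polygenic=0.4, cage_fraction=0.15,
    )
    return cfg, simulate_population(cfg, seed=11)


@pytest.fixture(scope="session")
def qtl_population():
    """Marker-determined genetics: 20 QTLs explaining half the variance."""
    cfg = SimulationConfig(
        n_families=40, fixed_family_size=11, n_markers=200,
        n_burnin_generations=30, burnin_population=120,
        n_qtl=20, h2_qtl=0.5, h2_polygenic=0.0, cage_fraction=0.2,
    )
    return cfg, simulate_population(cfg, seed=41)


@pytest.fixture(scope="session")
def qtl_encoding(qtl_population):
    _, pop = qtl_population
    sub = pop.panel.subset_animals(list(pop.phenotypes.animal_ids))
    return encode_design(sub, "dosage-centered")


@pytest.fixture
def short_chain():
    return ChainSettings(800, 300, 5, seed=3)
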