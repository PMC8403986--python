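import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dcstoich import GeneratorConfig, SpeciesSpec, Stoichiometry, default_components


@pytest.fixture
def components():
    return default_components()


@pytest.fixture
def dc_stoichiometry():
    """The theoretical fully-loaded complex: 1 APC, 3 AXIN1, 3+3 kinases, 13 β-catenin."""
    return Stoichiometry({"APC": 1, "AXIN1": 3, "CK1a": 3, "GSK3b": 3, "bcat": 13})


@pytest.fixture
def elution_grid():
    return np.arange(2.0, 3.5, 0.01)


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(noise_sd_rel=0.0, seed=0)


@pytest.fixture
def monodisperse_species(dc_stoichiometry):
    return [SpeciesSpec(dc_stoichiometry, peak_center=2.7, peak_width=0.12, total_mass_loaded=2e-5)]
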