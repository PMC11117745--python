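import numpy as np
import pytest

from semprep.synthdata import CohortSpec, generate_section


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale cohort conditions shared across tests."""
    return CohortSpec(n_sections=3, section_size=256, seed=7)


@pytest.fixture(scope="session")
def sections(desk_spec):
    """Five seeded synthetic sections (nuclear, lectin, truth)."""
    gen = np.random.default_rng(desk_spec.seed)
    return [generate_section(desk_spec, gen, f"s{i}") for i in range(5)]
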