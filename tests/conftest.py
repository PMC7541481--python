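import numpy as np
import pytest

from cyrpipe.photocycle import PhotocycleModel
from cyrpipe.synthetic import DEFAULT_TEMPLATES, CladeTemplate, ScaffoldSpec


@pytest.fixture
def model() -> PhotocycleModel:
    """Default photocycle model (550 nm ground state, K/M/O chain)."""
    return PhotocycleModel()


@pytest.fixture
def scaffold_spec() -> ScaffoldSpec:
    return ScaffoldSpec(seed=42)


@pytest.fixture
def two_clade_templates() -> list[CladeTemplate]:
    """A proton-pump clade and a chloride-pump clade, well separated."""
    return [
        CladeTemplate("CyR", "DTD", divergence=0.1),
        CladeTemplate("CyHR", "TSD", divergence=0.1),
    ]


@pytest.fixture
def all_templates() -> list[CladeTemplate]:
    return list(DEFAULT_TEMPLATES)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
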