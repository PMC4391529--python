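import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from osmoomics import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """Small, fast study conditions: defaults scaled down where possible."""
    return SimulationConfig(
        seed=7,
        n_genes=60,
        n_spots=60,
        ortholog_identity_levels=(0.5, 0.7, 0.9, 1.0),
        decoy_count=5,
        protein_length=200,
    )


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes=60,
        probe_noise_sd=0.0,
        n_spots=60,
        spot_cv=0.0,
        peak_cv=0.0,
        ortholog_identity_levels=(0.6, 0.8, 1.0),
        decoy_count=5,
        protein_length=200,
    )
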