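import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bachbpred.seqio import ProteinRecord
from bachbpred.synthgen import SynthConfig, default_profiles, generate_dataset


@pytest.fixture(scope="session")
def separable_dataset():
    """Small, strongly separated 4-class dataset (binary + subfamily labels)."""
    config = SynthConfig(
        profiles=tuple(default_profiles()),
        n_per_class={"nonHbL": 60, "sHb": 20, "flavoHb": 25, "trHb": 15},
        seed=42,
        separation=6.0,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def domain_dataset():
    """Separable dataset with flavoHb split into its three domain subgroups."""
    config = SynthConfig(
        profiles=tuple(default_profiles(include_domains=True)),
        n_per_class=25,
        seed=42,
        separation=6.0,
    )
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_record():
    return ProteinRecord(id="P1", description="toy globin", sequence="MKVLAEHGAC")
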