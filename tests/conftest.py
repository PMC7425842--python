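import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kinerr import (
    FrequencySet,
    MarkerFrequencies,
    STRPanel,
    builtin_panel,
    generate_frequency_set,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_marker(name: str, freqs, start: int = 8) -> MarkerFrequencies:
    """Marker with integer repeat-count labels starting at ``start``."""
    labels = tuple(str(start + i) for i in range(len(freqs)))
    return MarkerFrequencies(name, labels, tuple(freqs))


def make_freqset(*markers: MarkerFrequencies) -> FrequencySet:
    panel = STRPanel("toy", tuple(m.marker for m in markers))
    return FrequencySet("toy-pop", panel, {m.marker: m for m in markers})


@pytest.fixture
def marker4() -> MarkerFrequencies:
    """Four-allele marker used for exhaustive LR enumeration."""
    return make_marker("M4", (0.1, 0.2, 0.3, 0.4))


@pytest.fixture
def toy_pc_freqs() -> FrequencySet:
    """One biallelic 50/50 locus: the worked parent-child example."""
    return make_freqset(make_marker("L1", (0.5, 0.5)))


@pytest.fixture
def toy2_freqs() -> FrequencySet:
    """Two-locus toy panel (3 + 2 alleles) for exact-vs-MC checks."""
    return make_freqset(
        make_marker("L1", (0.2, 0.3, 0.5)), make_marker("L2", (0.4, 0.6))
    )


@pytest.fixture(scope="session")
def freqs15() -> FrequencySet:
    return generate_frequency_set(builtin_panel("identifiler15"), seed=11)


@pytest.fixture(scope="session")
def freqs21() -> FrequencySet:
    return generate_frequency_set(builtin_panel("globalfiler21"), seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
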