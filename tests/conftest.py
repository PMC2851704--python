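import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metaconcord import (
    build_corpus_records,
    reference_agreement_corpus,
)
from metaconcord.simulate import SimulationConfig, simulate_corpus

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_corpus():
    """Synthetic corpus engineered to the published agreement pattern."""
    return reference_agreement_corpus()


@pytest.fixture(scope="session")
def reference_records(reference_corpus):
    return build_corpus_records(reference_corpus)


@pytest.fixture(scope="session")
def default_corpus_5000():
    """One large default-config corpus shared by the calibration and
    stratification checks (generation dominates their runtime)."""
    return simulate_corpus(SimulationConfig(n_reviews=5000, seed=42))


@pytest.fixture(scope="session")
def default_corpus_records(default_corpus_5000):
    return build_corpus_records(default_corpus_5000.outcomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
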