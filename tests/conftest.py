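import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from subseqseed.tables import example_tables, make_random_tables

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_tables():
    """The packaged worked-example tables (k=6, d=5)."""
    return example_tables()


@pytest.fixture()
def small_tables():
    """A small random table set handy for fast unit tests."""
    return make_random_tables(k=4, d=5, rng_seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
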