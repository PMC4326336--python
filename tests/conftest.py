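import pytest
from hypothesis import HealthCheck, settings

import offtarget as ot

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def builtin_pams():
    return ot.builtin_pams()


@pytest.fixture(scope="session")
def ngg(builtin_pams):
    return builtin_pams[0]


@pytest.fixture(scope="session")
def small_genome():
    """A deterministic 10 kb random genome shared across index/query tests."""
    return ot.synth_genome(10_000, num_chroms=2, gc_bias=0.5, rng_seed=1)


@pytest.fixture(scope="session")
def small_index(small_genome, builtin_pams):
    return ot.build_index(small_genome, builtin_pams)
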