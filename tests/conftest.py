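import pytest

from behavframe import get_taxonomy, make_benchmark_fixture, profiles_from_seconds


@pytest.fixture(scope="session")
def benchmark():
    """The fixed 6-video synthetic benchmark bundle."""
    return make_benchmark_fixture()


@pytest.fixture(scope="session")
def benchmark_profiles(benchmark):
    """Per-video activity-type class profiles of the benchmark bundle."""
    return profiles_from_seconds(benchmark.seconds, get_taxonomy("T2"))
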