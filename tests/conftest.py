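import numpy as np
import pytest

from ipindex.engine import AgeMode, default_config
from ipindex.reliability import roc_analysis
from ipindex.synthetic import standard_benchmark

BENCHMARK_SEED = 0


@pytest.fixture(scope="session")
def adult_cfg():
    return default_config(AgeMode.ADULT)


@pytest.fixture(scope="session")
def benchmark():
    """The seeded 20 x 30-min standard benchmark (generated once)."""
    return standard_benchmark(BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_streams(benchmark):
    return [stream for stream, _ in benchmark]


@pytest.fixture(scope="session")
def severe_roc(benchmark_streams):
    return roc_analysis(benchmark_streams, event_class="severe")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
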