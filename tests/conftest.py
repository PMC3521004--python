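import numpy as np
import pytest

from curliscan.pipeline import evaluate_against_truth, run_benchmark_pipeline
from curliscan.synthetic import SimParams, benchmark

BENCH_SEED = 1


@pytest.fixture(scope="session")
def bench():
    """The standard synthetic study: 10 genomes, five operon classes, a
    two-tier divergence ladder and one split genus (fixed seed)."""
    return benchmark(SimParams(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def bench_run(bench):
    """Full pipeline run over the standard study (computed once)."""
    return run_benchmark_pipeline(bench)


@pytest.fixture(scope="session")
def bench_metrics(bench, bench_run):
    return evaluate_against_truth(bench_run, bench)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
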