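import pytest

from svds.pipeline import RunConfig, run_benchmark
from svds.synth import SynthConfig, generate_genome

#: seed of the default synthetic benchmark used by the end-to-end checks
BENCHMARK_SEED = 7


@pytest.fixture(scope="session")
def benchmark():
    """Full default-scale benchmark run (report, artifacts), computed once."""
    return run_benchmark(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        n_chromosomes=2,
        chrom_length=300_000,
        n_genes=24,
        n_enhancers=40,
        n_neutral_svs=150,
        n_cohort_svs=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_genome(small_config)
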