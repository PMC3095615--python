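import numpy as np
import pytest

from mirseek.config import PipelineConfig
from mirseek.synthetic_data import SimConfig, build_genome, simulate_reads


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated study: genome with 10 planted MIR loci, a 60-copy
    repeat family and 100 background reads."""
    cfg = SimConfig(
        genome_len=30_000, n_scaffolds=2, n_planted=10, repeat_copies=60,
        background_reads=100, seed=11,
    )
    genome, truth = build_genome(cfg)
    reads = simulate_reads(genome, truth, cfg)
    return cfg, genome, truth, reads


@pytest.fixture(scope="session")
def small_report(small_bundle):
    """Discovery report for the shared bundle (computed once per session)."""
    from mirseek.pipeline import discover

    _, genome, _, reads = small_bundle
    return discover(reads, genome)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
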