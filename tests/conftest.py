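import numpy as np
import pytest

from isforge.simulate import (
    SimConfig,
    naive_align,
    simulate_enrichment_reads,
    simulate_genome,
    simulate_insertions,
    simulate_plasmid,
)


def _library(cfg: SimConfig) -> dict:
    genome = simulate_genome(cfg.genome_len, cfg.gc, cfg.seed)
    plasmid, marker = simulate_plasmid(cfg.seed)
    truth = simulate_insertions(
        genome, cfg.n_insertions, cfg.pwm, cfg.tsd_len, cfg.seed, cfg.min_site_separation
    )
    reads = simulate_enrichment_reads(genome, plasmid, marker, truth, cfg)
    alignments = naive_align(reads, [plasmid, genome])
    return {
        "config": cfg,
        "genome": genome,
        "plasmid": plasmid,
        "marker": marker,
        "truth": truth,
        "reads": reads,
        "alignments": alignments,
    }


@pytest.fixture(scope="session")
def error_free_library() -> dict:
    """250 sites x 4 error-free reads (1,000 reads): junction truth is exact."""
    return _library(
        SimConfig(genome_len=150_000, n_insertions=250, reads_per_site=4, error_rate=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_library() -> dict:
    """100 sites x 3 reads at 5% error: the recovery-benchmark condition."""
    return _library(
        SimConfig(genome_len=100_000, n_insertions=100, reads_per_site=3, error_rate=0.05, seed=42)
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
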