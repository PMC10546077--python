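"""Shared fixtures: a small simulated trio reused across test modules."""

import numpy as np
import pytest

from oystrio import synthio


@pytest.fixture(scope="session")
def small_cfg():
    return synthio.SimConfig(
        seed=1234,
        genome_length=60_000,
        long_read_length_mean=4_000,
        coverage_long=3.0,
        coverage_short=0.0,
    )


@pytest.fixture(scope="session")
def small_trio(small_cfg):
    """(ancestor, genome_a, genome_b, trio, reads, truth) at 60 kb."""
    rng = np.random.default_rng(small_cfg.seed)
    ancestor = synthio.random_genome(small_cfg.genome_length, rng)
    genome_a, genome_b, truth = synthio.evolve_pair(ancestor, small_cfg)
    trio, truth = synthio.make_trio(genome_a, genome_b, small_cfg, truth)
    reads, truth = synthio.simulate_reads(trio.offspring, truth, small_cfg)
    return ancestor, genome_a, genome_b, trio, reads, truth
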