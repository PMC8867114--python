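"""Shared fixtures: one seeded synthetic dataset reused across the suite."""

import numpy as np
import pytest

from peakscape import PipelineConfig, consensus_pipeline
from peakscape.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def sim():
    """Default study conditions at seed 7 (tags included)."""
    return simulate_dataset(SimConfig(), seed=7)


@pytest.fixture(scope="session")
def final_peaks(sim, cfg):
    """Consensus peak lists for both factors plus their reports."""
    out = {}
    for factor in ("A", "B"):
        reps = sim.peaks[factor]
        final, report = consensus_pipeline(reps[0], reps[1:], sim.blacklist, cfg)
        out[factor] = (final, report)
    return out


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=2_000):
    """Random half-open intervals on a small genome (shared test helper)."""
    from peakscape import GenomicInterval

    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, max_pos)))
    return out
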