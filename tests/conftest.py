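import numpy as np
import pandas as pd
import pytest

from lavapipe.simulate import SimulationConfig, generate_toy_genome, simulate_alignments


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact study-shaped simulation used across tests."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def toy(small_config):
    return generate_toy_genome(small_config)


@pytest.fixture(scope="session")
def clean_alignments(toy):
    """Alignments with no planted duplicates or multimappers, so counts can be
    compared exactly against the ground truth."""
    cfg = SimulationConfig(seed=11, dup_rate=0.0, multimap_rate=0.0)
    records, truth = simulate_alignments(toy, cfg)
    return records, truth


def make_alignment_table(rows):
    """Rows of (read_id, mate, chrom, start, end, strand[, n_hits, sample, candidates])."""
    full = []
    for r in rows:
        r = list(r)
        if len(r) == 6:
            r += [1, "S1", "."]
        elif len(r) == 7:
            r += ["S1", "."]
        elif len(r) == 8:
            r += ["."]
        full.append(r)
    return pd.DataFrame(
        full,
        columns=[
            "read_id",
            "mate",
            "chrom",
            "start",
            "end",
            "strand",
            "n_hits",
            "sample",
            "candidates",
        ],
    )
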