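import numpy as np
import pytest

from aperates.blocks import filter_blocks
from aperates.phylo import BRANCHES
from aperates.simulate import SimulationConfig, generate_dataset
from aperates.sites import count_family


@pytest.fixture(scope="session")
def clock_dataset():
    """A 2,000-family strict-clock dataset at the default branch rates.

    Families are 500 residues long; no episodic shifts.  Shared between
    the mean-tree recovery check and the false-positive-rate check.
    """
    cfg = SimulationConfig(
        n_families=2000, length_min=500, length_max=500, seed=20210920
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def clock_counts(clock_dataset):
    """Filtered + classified per-family counts for the clock dataset."""
    _, data = clock_dataset
    counts = []
    for fam, _truth in data:
        fa = filter_blocks(fam.msa)
        if fa.L:
            counts.append(count_family(fa))
    return counts


@pytest.fixture(scope="session")
def clock_totals(clock_counts):
    return {b: sum(fc.n[b] for fc in clock_counts) for b in BRANCHES}
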