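import numpy as np
import pytest

from isoarch.config import SimulationConfig
from isoarch.regions import RegionSet
from isoarch.simulate import simulate_isochore_structure


@pytest.fixture(scope="session")
def small_config():
    """A compact genome: fast to simulate, large enough to be non-trivial."""
    return SimulationConfig(seed=11, n_chromosomes=2, chromosome_length=10_000_000)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_isochore_structure(small_config)


@pytest.fixture
def toy_genome():
    return {"chr1": 10_000, "chr2": 8_000}


def random_region_set(genome, n, rng, max_len=500, name="rs"):
    """Non-overlapping random intervals on each chromosome (test helper)."""
    intervals = {}
    for chrom, L in genome.items():
        starts = np.sort(
            rng.choice(np.arange(0, L - max_len, max_len), size=n, replace=False)
        )
        lens = rng.integers(1, max_len, n)
        intervals[chrom] = np.stack([starts, starts + lens], axis=1)
    return RegionSet(name, genome, intervals)
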