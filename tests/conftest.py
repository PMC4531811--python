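import numpy as np
import pytest

from sumoscape.genome_model import GeneModel, GenomicInterval
from sumoscape.signal_io import ReadSet, StrandedCoverage, build_coverage
from sumoscape.synthetic_data import SimConfig, generate_genome


def make_readset(intervals, sample_id="s", condition="C", replicate=1):
    return ReadSet.from_intervals(sample_id, condition, replicate, intervals)


def uniform_coverage(chrom_sizes, value, bin_size=50, total_reads=1e7, strands=("+",)):
    """Coverage with a constant `value` tags per bp on the given strands."""
    counts = {}
    for c, L in chrom_sizes.items():
        n = int(np.ceil(L / bin_size))
        counts[c] = {
            "+": np.full(n, value * bin_size if "+" in strands else 0.0),
            "-": np.full(n, value * bin_size if "-" in strands else 0.0),
        }
    return StrandedCoverage(counts, bin_size, dict(chrom_sizes), total_reads)


@pytest.fixture
def plus_gene():
    return GeneModel("gA", "chr1", "+", 10_000, 20_000)


@pytest.fixture
def minus_gene():
    return GeneModel("gB", "chr1", "-", 40_000, 52_000)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale scenario for unit tests (fast; same structure)."""
    return SimConfig.small(seed=11)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    genes, truth = generate_genome(small_config)
    return small_config, genes, truth


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def default_scenario(default_config):
    genes, truth = generate_genome(default_config)
    return default_config, genes, truth
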