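import numpy as np
import pytest

from vmiap.sim import ChromosomeSpec, GenomeSpec, default_genome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def genome():
    return default_genome()


@pytest.fixture
def small_genome():
    """One-chromosome genome for fast Mendelian simulations."""
    chrom = ChromosomeSpec("chr4", 50_000_000, 0.5)
    markers = {"chr4": np.arange(1_000_000, 50_000_000, 5_000_000, dtype=np.int64)}
    return GenomeSpec(
        chromosomes=[chrom],
        marker_positions=markers,
        modifier_locus=("chr4", 26_000_000),
    )
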