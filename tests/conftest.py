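import numpy as np
import pytest

from tadmeqtl.core import GenomicInterval, TADRecord
from tadmeqtl.simulate import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimConfig(n_chroms=2, n_tads=30, chrom_length=36_000_000,
                    n_meqtls=5_000, n_samples=30, n_genes=200,
                    n_driver_meqtls={"oncogene": 30, "TSG": 60}, seed=11)
    return simulate_dataset(cfg)


def make_tad(chrom, start, end, category5=None, cell_line="test"):
    return TADRecord(GenomicInterval(chrom, start, end),
                     cell_line=cell_line, category5=category5)
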