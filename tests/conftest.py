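import numpy as np
import pytest
import scipy.sparse as sp

import chicflow as cf
from chicflow.matrix import ContactMatrix


@pytest.fixture(scope="session")
def small_sim_cfg():
    """Desk-scale simulation config: 2 x 6 Mb chromosomes, small library."""
    return cf.SimulationConfig(
        chrom_lengths={"chrS1": 6_000_000, "chrS2": 6_000_000},
        library_size=60_000,
        capture_fold=1.0,
        d_max=3_000_000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fmap(small_sim_cfg):
    fmap, _ = cf.planted_fragment_map(small_sim_cfg)
    return fmap


def make_matrix(dense, chrom_lengths, resolution=9000, **kw):
    """ContactMatrix from a dense upper-triangular array (helper)."""
    grid = cf.BinGrid(chrom_lengths, resolution)
    assert dense.shape == (grid.n_bins, grid.n_bins)
    return ContactMatrix(grid=grid, counts=sp.csr_matrix(np.triu(dense)), **kw)
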