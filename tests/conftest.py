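import numpy as np
import pytest

from covqc import CovDataTable, GenomicRegion, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Two regions x three samples on the full depth grid, hand-built."""
    regions = [
        GenomicRegion("chr1", 100, 200, "GENEA_ex1"),
        GenomicRegion("chr2", 500, 650, "GENEB_ex2"),
    ]
    depths = (5, 10, 50, 100, 250, 500)
    counts = np.array(
        [
            [  # region 0, length 100
                [100, 100, 98, 95, 60, 10],
                [100, 100, 100, 100, 100, 100],
                [100, 90, 80, 70, 60, 50],
            ],
            [  # region 1, length 150
                [150, 150, 150, 150, 150, 0],
                [150, 150, 120, 100, 80, 20],
                [150, 140, 130, 120, 110, 100],
            ],
        ],
        dtype=np.int64,
    )
    return CovDataTable(regions, ["S01", "S02", "S03"], depths, counts)


@pytest.fixture
def tiny_world():
    """A small consistent simulated world: targets, profiles, covdata, truth."""
    cfg = SimulationConfig(
        n_samples=4, n_genes=4, exons_per_gene=2, n_drops=4, seed=7
    )
    return simulate_dataset(cfg)
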