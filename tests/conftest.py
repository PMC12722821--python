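"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from troplip import simdata
from troplip.io_formats import CellDataset


@pytest.fixture(scope="session")
def spiked_sc():
    """Single-cell dataset with a 19-gene set spiked down (−1) in SCT."""
    cfg = simdata.SimConfig(
        n_genes=600,
        clusters={
            "VCT": {"Ctrl": 250, "PE": 250},
            "SCT": {"Ctrl": 500, "PE": 500},
            "EVT": {"Ctrl": 150, "PE": 150},
        },
        spike_table=[simdata.SpikeSpec("CHOL_BIOSYNTH", 19, -1.0, ("SCT",))],
        seed=42,
    )
    cells, truth = simdata.simulate_single_cell_dataset(cfg)
    catalog = simdata.make_gene_set_catalog(cfg)
    return cfg, cells, truth, catalog


@pytest.fixture(scope="session")
def spiked_bulk():
    """Bulk 4-vs-4 dataset with an up-spiked set and an active regulon."""
    cfg = simdata.SimConfig(
        n_genes=600,
        spike_table=[
            simdata.SpikeSpec("UP_SET", 25, 1.0),
            simdata.SpikeSpec("DOWN_SET", 25, -1.0),
        ],
        regulon_spec=[
            simdata.RegulonSpec("TF_ACT", 12, activation_frac=0.75,
                                responsive_frac=0.8, log2fc=2.0, active=True),
            simdata.RegulonSpec("TF_IDLE", 12, activation_frac=0.75,
                                active=False),
        ],
        seed=11,
    )
    bulk, truth = simdata.simulate_bulk_dataset(cfg)
    regulons = simdata.make_regulon_table(cfg)
    catalog = simdata.make_gene_set_catalog(cfg)
    return cfg, bulk, truth, regulons, catalog


@pytest.fixture()
def toy_cells():
    """Hand-sized dataset: 3 genes × 6 cells, one cluster, two conditions."""
    counts = sp.csr_matrix(np.array([
        [1, 2, 3, 4, 5, 6],
        [9, 8, 7, 6, 5, 4],
        [0, 0, 0, 0, 0, 0],
    ]))
    meta = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(6)],
        "sample_id": ["s1", "s1", "s2", "s3", "s3", "s4"],
        "cluster": ["SCT"] * 6,
        "condition": ["Ctrl", "Ctrl", "Ctrl", "PE", "PE", "PE"],
    })
    return CellDataset(counts, ["g1", "g2", "g3"], meta)
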