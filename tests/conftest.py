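import numpy as np
import pandas as pd
import pytest

from anchorscreen import BulkSimConfig, CountMatrix, ScSimConfig, simulate_bulk, simulate_sc


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 6 samples, one dataset, 3 timepoints x 2 replicates."""
    samples = [f"S{i}" for i in range(6)]
    meta = pd.DataFrame({
        "dataset": "DS1",
        "timepoint": [0, 0, 1, 1, 2, 2],
        "timepoint_label": ["P0", "P0", "P7", "P7", "P14", "P14"],
        "replicate": ["R1", "R2"] * 3,
    }, index=pd.Index(samples, name="sample"))
    counts = np.array([
        [10, 12, 11, 9, 2, 3],
        [5, 6, 5, 7, 6, 5],
        [1, 0, 2, 1, 8, 9],
    ])
    return CountMatrix(gene_ids=["MKRN3", "FLAT", "UP"], sample_ids=samples,
                       counts=counts, sample_meta=meta)


@pytest.fixture
def small_bulk():
    """One small simulated bulk dataset plus its ground truth."""
    cfg = BulkSimConfig(n_genes=200, n_pos_corr=15, n_neg_corr=15, seed=7)
    cm, truth = simulate_bulk(cfg)
    return cfg, cm, truth


@pytest.fixture
def small_cells():
    cfg = ScSimConfig(n_cells=600, seed=11)
    cells, truth = simulate_sc(cfg)
    return cfg, cells, truth
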