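import numpy as np
import pandas as pd
import pytest

from germmap.io import CellSet
from germmap.synth import SynthParams, simulate_timecourse


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_cellset():
    counts = np.array([[5, 0, 0], [0, 0, 1], [2, 3, 4]])
    meta = pd.DataFrame(
        {
            "time_h": [0.0, 12.0, 24.0],
            "sample": ["PSC", "PreME", "EB"],
            "cluster": ["a", "a", "b"],
        }
    )
    return CellSet(counts, ["c1", "c2", "c3"], ["g1", "g2", "g3"], meta=meta)


@pytest.fixture(scope="session")
def small_timecourse():
    """A reduced branching time course for module-level tests."""
    params = SynthParams(
        n_genes=120,
        n_cells_per_cluster=50,
        n_lineages=4,
        timepoints_h=(0, 12, 24, 30, 36, 42, 44, 52, 60),
        seed=11,
    )
    cells, emb, tree = simulate_timecourse(params)
    return params, cells, emb, tree
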