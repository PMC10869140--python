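import numpy as np
import pytest

from slomap import (
    SimulationConfig,
    integrate_joint,
    simulate_hto,
    simulate_multimodal,
)


@pytest.fixture(scope="session")
def hto_singlets():
    """300 hashed cells, 3 hashtags, no doublets, strong signal:background."""
    return simulate_hto(n_cells=300, n_hashtags=3, doublet_rate=0.0,
                        mu_signal=1000.0, mu_background=5.0, seed=0)


@pytest.fixture(scope="session")
def multimodal():
    """Default two-assay simulation (3 types x 100 cells/type/assay, 3-sigma)."""
    cfg = SimulationConfig(seed=0)
    reference, query, truth = simulate_multimodal(cfg)
    return reference, query, truth


@pytest.fixture(scope="session")
def joint_embedding(multimodal):
    reference, query, truth = multimodal
    emb = integrate_joint(reference, query)
    labels = truth.table.set_index("cell_id").loc[emb.cell_ids, "label"].to_numpy()
    return emb, labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
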