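import numpy as np
import pytest

from oncotraj import preprocess
from oncotraj.sim import SimConfig, simulate_single_cells


@pytest.fixture(scope="session")
def world():
    """One default-structure synthetic dataset shared across tests."""
    cfg = SimConfig(n_genes=800, n_cells=600, seed=5)
    adata, truth = simulate_single_cells(cfg)
    logn = preprocess.normalize_log(adata)
    return cfg, adata, truth, logn


@pytest.fixture(scope="session")
def pca_world(world):
    """PC scores of the shared dataset, ready for trajectory work."""
    cfg, adata, truth, logn = world
    hvg = preprocess.select_hvg(logn, n_hvg=600)
    scaled = preprocess.scale_genes(logn[:, hvg].copy())
    pcs, ev = preprocess.run_pca(scaled, n_components=20)
    return pcs, ev


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
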