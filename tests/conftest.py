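import numpy as np
import pytest

from ccre_atlas import simulate


def pseudobulk(X, subclass_of_cell):
    """Subclass-by-peak aggregate counts (dense)."""
    n_sub = int(subclass_of_cell.max()) + 1
    out = np.zeros((n_sub, X.shape[1]))
    for s in range(n_sub):
        rows = np.nonzero(subclass_of_cell == s)[0]
        out[s] = np.asarray(X[rows].sum(axis=0)).ravel()
    return out


@pytest.fixture(scope="session")
def small_atlas():
    """A small planted atlas shared across tests (read-only)."""
    cfg = simulate.SimulationConfig(
        n_subclasses=10,
        n_cells_per_subclass=100,
        n_peaks=600,
        n_genes=200,
        n_modules=5,
        n_links=40,
        seed=42,
    )
    X, expression, truth = simulate.make_atlas(cfg)
    return cfg, X, expression, truth


@pytest.fixture(scope="session")
def grn_truth_medium():
    """Planted signed network at the reference conditions (20 TFs, 200 genes)."""
    cfg = simulate.GrnConfig(n_tfs=20, n_targets=200, n_cells=500, noise_sd=0.3, seed=7)
    truth, expression = simulate.make_grn_truth(cfg)
    return cfg, truth, expression
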