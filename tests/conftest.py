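import numpy as np
import pytest

from cellstate import (
    CellStateModel,
    ExpressionMatrix,
    ModelConfig,
    SimulationConfig,
    simulate_atlas,
)

ATLAS_CFG = SimulationConfig(
    n_states=5, cells_per_state=80, n_genes=400, markers_per_state=8, seed=7
)


@pytest.fixture(scope="session")
def atlas_and_markers():
    return simulate_atlas(ATLAS_CFG)


@pytest.fixture(scope="session")
def atlas(atlas_and_markers):
    return atlas_and_markers[0]


@pytest.fixture(scope="session")
def marker_map(atlas_and_markers):
    return atlas_and_markers[1]


@pytest.fixture(scope="session")
def atlas_cfg():
    return ATLAS_CFG


@pytest.fixture(scope="session")
def model(atlas):
    return CellStateModel(atlas, ModelConfig(seed=0))


@pytest.fixture(scope="session")
def fitted(model):
    """Calibrated results on the full 400-gene panel."""
    return model.fit()


def make_matrix(values, layer_tag="raw_counts", cell_prefix="c", gene_prefix="g"):
    values = np.asarray(values)
    cells = [f"{cell_prefix}{i}" for i in range(values.shape[0])]
    genes = [f"{gene_prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, cells, genes, layer_tag)
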