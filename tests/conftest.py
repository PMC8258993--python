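import warnings

import numpy as np
import pytest

from murkscreen import PairedLayers, SimulationConfig, preprocess, simulate_dataset

# size-factor warnings on sparse toy data are expected noise in tests
warnings.filterwarnings("ignore", message="cells with zero layer total")


@pytest.fixture(scope="session")
def boosted_dataset():
    """Default boosted simulation shared by detector tests (seed 1)."""
    cfg = SimulationConfig(seed=1)
    layers, cells, genes = simulate_dataset(cfg)
    return cfg, layers, cells, genes


@pytest.fixture(scope="session")
def boosted_imputed(boosted_dataset):
    _, layers, cells, genes = boosted_dataset
    imputed, graph = preprocess(layers)
    return imputed, graph, cells, genes


def toy_layers(U, S, stage="raw_counts"):
    U = np.asarray(U)
    S = np.asarray(S)
    return PairedLayers(
        U=U,
        S=S,
        cell_ids=[f"c{i}" for i in range(U.shape[0])],
        gene_ids=[f"g{j}" for j in range(U.shape[1])],
        stage=stage,
    )
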