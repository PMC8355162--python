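import numpy as np
import pandas as pd
import pytest

from cardiomir.expression import GeneExpressionMatrix
from cardiomir.simulate import SimulationConfig, simulate_knowledge_bases, simulate_transfection_counts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_genes=300, frac_targets_per_mirna=0.1, ppi_n_edges=400,
                            go_set_sizes={"cell_division": 40, "actin_cytoskeleton": 50,
                                          "oxidative_stress": 25, "hippo_canonical": 8,
                                          "hippo_noncanonical": 9})


@pytest.fixture(scope="session")
def small_experiment(small_config):
    matrix, truth = simulate_transfection_counts(small_config)
    predictions, homology, ppi, compartments = simulate_knowledge_bases(small_config, truth)
    return {
        "config": small_config,
        "matrix": matrix,
        "truth": truth,
        "predictions": predictions,
        "homology": homology,
        "ppi": ppi,
        "compartments": compartments,
    }


@pytest.fixture()
def tiny_matrix() -> GeneExpressionMatrix:
    counts = pd.DataFrame(
        {
            "cel-miR-67": [1000, 10, 0, 400],
            "miR-106b": [500, 20, 5, 400],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    lengths = pd.Series([2000, 500, 1000, 1000], index=counts.index)
    libs = pd.Series([2e6, 2e6], index=counts.columns)
    return GeneExpressionMatrix(counts=counts, lengths_bp=lengths, control="cel-miR-67",
                                library_sizes=libs)
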