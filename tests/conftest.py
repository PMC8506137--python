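import numpy as np
import pandas as pd
import pytest

from dysmod import SimulationConfig, simulate_expression
from dysmod.coexpression import ModulePartition


def partition_from_truth(truth) -> ModulePartition:
    """ModulePartition built directly from planted ground truth."""
    genes = sorted(truth.module_of)
    labels = pd.Series([truth.module_of[g] for g in genes],
                       index=pd.Index(genes, name="gene"))
    return ModulePartition(labels, cut_height=float("nan"), min_module_size=0)


@pytest.fixture(scope="session")
def block_dataset():
    """Two planted 30-gene modules plus background, powered groups."""
    cfg = SimulationConfig(n_genes=120, module_sizes=(30, 30),
                           group_sizes=(8, 8, 8), factor_loading=0.9,
                           noise_sd=0.4, de_effect=2.0,
                           de_fraction_per_module=(1.0, 0.0),
                           background_de_fraction=0.0, seed=7)
    dataset, truth = simulate_expression(cfg)
    return cfg, dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
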