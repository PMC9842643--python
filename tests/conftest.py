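"""Shared fixtures: one moderately sized synthetic experiment feeds most
module tests, so the expensive generation/fit work happens once."""

import numpy as np
import pytest

from barfit.error_model import fit_noise_model
from barfit.inference import SGrid, fit_experiment
from barfit.mean_fitness import mean_fitness_series
from barfit.processing import process_experiment
from barfit.synthetic import SimConfig, build_experiment

#: per-gene true fitness of the shared experiment (1/generation)
S_TRUE = np.array([0.05, 0.02, 0.0, 0.0, -0.03, 0.0, 0.0, 0.1, 0.0, 0.0, -0.02, 0.0])


@pytest.fixture(scope="session")
def s_true_map():
    """gene id -> true fitness for the shared experiment."""
    return {f"g{i:04d}": S_TRUE[i] for i in range(len(S_TRUE))}


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(
        n_genes=len(S_TRUE),
        barcodes_per_gene=10,
        n_intergenic=8000,
        s_values=S_TRUE,
        n_replicates=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def experiment(sim_config):
    tables, truth, pool = build_experiment(sim_config)
    return {"tables": tables, "truth": truth, "pool": pool, "config": sim_config}


@pytest.fixture(scope="session")
def processed(experiment):
    genes, intergenic = process_experiment(
        experiment["tables"][0], experiment["pool"], merge_errors=False
    )
    return genes, intergenic


@pytest.fixture(scope="session")
def noise_model(processed):
    _, intergenic = processed
    return fit_noise_model(
        intergenic, n_boot=100, rng=np.random.default_rng(0)
    )


@pytest.fixture(scope="session")
def xbar(processed):
    _, intergenic = processed
    return mean_fitness_series(intergenic, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def grid():
    return SGrid(-0.15, 0.15, 5e-4)


@pytest.fixture(scope="session")
def fitted(processed, noise_model, xbar, grid):
    genes, _ = processed
    df, curves = fit_experiment(
        genes, noise_model, xbar, grid=grid, return_curves=True
    )
    return df, curves
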