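import numpy as np
import pytest

import goclust as gc


@pytest.fixture(scope="session")
def planted_dataset():
    """Small simulated dataset with clean planted structure (fixed seed)."""
    config = gc.SimulationConfig(I=12, K=60, n_blocks=6, rho_within=0.9, r=1, seed=11)
    return gc.simulate_dataset(config)


@pytest.fixture(scope="session")
def unstructured_dataset():
    """Expression with no correlation structure, annotations from its tree."""
    config = gc.SimulationConfig(
        I=10, K=120, n_blocks=6, rho_within=0.0, rho_between=0.0, r=1, seed=21
    )
    return gc.simulate_dataset(config)


@pytest.fixture()
def toy_expression():
    """5 genes x 4 samples with two anti-correlated pairs and one odd gene."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    values = np.vstack([x, 2 * x + 1, -x, -3 * x + 2, [1.0, 3.0, 2.0, 4.0]])
    return gc.ExpressionMatrix(
        [f"g{k}" for k in range(5)], [f"s{i}" for i in range(4)], values
    )


@pytest.fixture()
def toy_annotation():
    """6 genes x 4 functions, all genes annotated, all functions >= 2 genes."""
    values = np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 1, 1, 0],
            [0, 0, 1, 1],
            [1, 0, 0, 1],
            [0, 0, 1, 1],
        ]
    )
    return gc.AnnotationMatrix(
        [f"g{k}" for k in range(6)], [f"f{j}" for j in range(4)], values
    )


def random_coexp_matrix(rng, n_genes=12, n_funcs=6):
    """Random single-column-per-function T_coexp with no zero rows/cols."""
    from goclust.decompose import CoexpAnnotationMatrix

    while True:
        values = (rng.random((n_genes, n_funcs)) < 0.4).astype(int)
        if (values.sum(1) > 0).all() and (values.sum(0) > 0).all():
            break
    cols = [(f"f{j}", 1) for j in range(n_funcs)]
    return CoexpAnnotationMatrix([f"g{k}" for k in range(n_genes)], cols, values)
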