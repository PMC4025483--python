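import numpy as np
import pytest

import eigenmet as em


@pytest.fixture(scope="session")
def expr_bundle():
    """Moderate-size planted expression simulation plus its decomposition."""
    spec = em.ExpressionSimSpec(n_genes=5000, seed=11)
    matrix, truth = em.generate_expression(spec)
    decomp = em.decompose(matrix)
    return spec, matrix, truth, decomp


@pytest.fixture(scope="session")
def metab_bundle():
    """Default metabolome simulation, normalized and baseline-rescaled."""
    spec = em.MetabolomeSimSpec(seed=7)
    tc, truth = em.generate_metabolome(spec)
    scaled = em.relative_to_baseline(em.normalize_to_standard(tc), "0-2h")
    return spec, tc, truth, scaled


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(3)
    values = rng.uniform(1.0, 10.0, size=(6, 4))
    return em.ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(6)],
        stage_labels=["t0", "t1", "t2", "t3"],
        values=values,
    )
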