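import numpy as np
import pytest

from otgrn import ExpressionDataset


def feasible_coupling(rng, n1, n2, p=None, q=None, iters=500):
    """Random transport plan with prescribed marginals (Sinkhorn scaling)."""
    p = np.full(n1, 1.0 / n1) if p is None else p
    q = np.full(n2, 1.0 / n2) if q is None else q
    T = rng.random((n1, n2)) + 0.1
    for _ in range(iters):
        T *= (p / T.sum(axis=1))[:, None]
        T *= (q / T.sum(axis=0))[None, :]
    return T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """3 genes, 3 time points, 5/6/4 cells, positive values."""
    m = 3
    sizes = [5, 6, 4]
    mats = [rng.random((m, n)) * 5 for n in sizes]
    return ExpressionDataset(
        gene_names=["g1", "g2", "g3"],
        times=np.array([0.0, 1.0, 2.0]),
        matrices=mats,
        cell_ids=[[f"t{k}_c{j}" for j in range(n)] for k, n in enumerate(sizes)],
    )
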