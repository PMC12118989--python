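"""Expression transforms and cost/structure matrices for the transport solver.

The inter-time cost matrix compares cells across two cohorts in feature space;
the intra-time structure matrices are geodesic distances on a symmetrized
k-nearest-neighbor graph within each cohort (so that the Gromov-Wasserstein
term can preserve global geometry such as branching).  All three matrices are
normalized so their maximum entry equals one.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist
from sklearn.neighbors import kneighbors_graph

from .io import ExpressionDataset


@dataclasses.dataclass
class CostInputs:
    """Inputs of one pairwise fused-GW problem between cohorts at (t, t~)."""

    D: np.ndarray          # n(t) x n(t~) inter-time cost, max-normalized
    S_source: np.ndarray   # n(t) x n(t) geodesic structure, max-normalized
    S_target: np.ndarray   # n(t~) x n(t~)
    p: np.ndarray          # source marginal, sums to 1
    q: np.ndarray          # target marginal, sums to 1
    k_neighbors: int


def log_transform(dataset: ExpressionDataset) -> ExpressionDataset:
    """Apply log(x+1) elementwise; errors if the dataset is already transformed."""
    if dataset.transformed:
        raise ValueError("dataset is already log-transformed")
    return ExpressionDataset(
        gene_names=list(dataset.gene_names),
        times=dataset.times.copy(),
        matrices=[np.log1p(x) for x in dataset.matrices],
        cell_ids=[list(c) for c in dataset.cell_ids],
        branch_labels=dataset.branch_labels,
        cell_weights=dataset.cell_weights,
        pseudotime=dataset.pseudotime,
        transformed=True,
    )


def _normalize_max(M: np.ndarray) -> np.ndarray:
    mx = M.max() if M.size else 0.0
    return M / mx if mx > 0 else M


def inter_cost_matrix(X_source, X_target, metric: str = "euclidean") -> np.ndarray:
    """Pairwise distances between cell columns of two cohorts, max-normalized."""
    Xs, Xt = np.asarray(X_source, float), np.asarray(X_target, float)
    if Xs.shape[0] != Xt.shape[0]:
        raise ValueError("gene dimensions differ between the two cohorts")
    if metric == "euclidean":
        D = cdist(Xs.T, Xt.T, metric="euclidean")
    elif metric == "cosine":
        for name, X in (("source", Xs), ("target", Xt)):
            norms = np.linalg.norm(X, axis=0)
            if np.any(norms == 0):
                c = int(np.flatnonzero(norms == 0)[0])
                raise ValueError(f"zero-norm {name} cell {c} under the cosine metric")
        D = cdist(Xs.T, Xt.T, metric="cosine")  # 1 - cosine similarity
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return _normalize_max(D)


def default_k(n_source: int, n_target: int) -> int:
    """Neighbor count for the structure graphs: max(1, floor(min{50, 0.2 n, 0.2 n~}))."""
    return max(1, math.floor(min(50.0, 0.2 * n_source, 0.2 * n_target)))


def intra_structure_matrix(X, k: int) -> np.ndarray:
    """Geodesic distance matrix of the symmetrized kNN graph of one cohort.

    Euclidean edge weights; the graph is mutualized by union (an edge exists
    if either endpoint lists the other as a neighbor), which keeps it better
    connected.  Unreachable pairs receive the largest finite geodesic before
    the matrix is max-normalized.
    """
    X = np.asarray(X, float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("structure matrix needs at least 2 cells")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n - 1)
    G = kneighbors_graph(X.T, n_neighbors=k, mode="distance")
    G = G.maximum(G.T)  # union symmetrization
    S = shortest_path(G, method="D", directed=False)
    finite = np.isfinite(S)
    if not finite.all():
        S[~finite] = S[finite].max()
    np.fill_diagonal(S, 0.0)
    S = 0.5 * (S + S.T)
    return _normalize_max(S)


def compute_marginals(dataset: ExpressionDataset, k_source: int, k_target: int,
                      mode: str = "uniform"):
    """Marginal weight vectors (p, q) for the cohorts at two time indices.

    ``uniform`` weights every cell equally.  ``branch_reweighed`` gives every
    branch a total mass equal to its average proportion across the two time
    points, split uniformly among that branch's cells at each time point --
    compensating for disproportionate branch representation.
    """
    n_s = dataset.matrices[k_source].shape[1]
    n_t = dataset.matrices[k_target].shape[1]
    if mode == "uniform":
        return np.full(n_s, 1.0 / n_s), np.full(n_t, 1.0 / n_t)
    if mode != "branch_reweighed":
        raise ValueError(f"unknown marginal mode {mode!r}")
    if dataset.branch_labels is None:
        raise ValueError("branch_reweighed marginals require branch labels")
    lab_s = np.asarray(dataset.branch_labels[k_source])
    lab_t = np.asarray(dataset.branch_labels[k_target])
    branches = list(dict.fromkeys(list(lab_s) + list(lab_t)))
    p = np.zeros(n_s)
    q = np.zeros(n_t)
    for b in branches:
        cs, ct = lab_s == b, lab_t == b
        prop = 0.5 * (cs.sum() / n_s + ct.sum() / n_t)
        if cs.sum() == 0 or ct.sum() == 0:
            warnings.warn(f"branch {b!r} has no cells at one of the two time points; "
                          "its mass is assigned only where the branch is present")
        if cs.sum():
            p[cs] = prop / cs.sum()
        if ct.sum():
            q[ct] = prop / ct.sum()
    return p / p.sum(), q / q.sum()


def build_cost_inputs(dataset: ExpressionDataset, k_source: int, k_target: int,
                      metric: str = "euclidean",
                      marginal_mode: str = "uniform") -> CostInputs:
    """Assemble all fused-GW inputs for one consecutive pair of cohorts."""
    Xs, Xt = dataset.matrices[k_source], dataset.matrices[k_target]
    kk = default_k(Xs.shape[1], Xt.shape[1])
    p, q = compute_marginals(dataset, k_source, k_target, marginal_mode)
    return CostInputs(
        D=inter_cost_matrix(Xs, Xt, metric),
        S_source=intra_structure_matrix(Xs, kk),
        S_target=intra_structure_matrix(Xt, kk),
        p=p, q=q, k_neighbors=kk,
    )
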