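"""Scoring predicted weight matrices against signed ground-truth networks.

Self-loops are excluded everywhere.  Unsigned metrics rank off-diagonal
entries by absolute weight; signed metrics first zero every prediction whose
sign contradicts the true sign of a true edge (predictions on non-edges are
untouched, since no true sign exists for them) and then score as unsigned.
AUPRC is computed in average-precision form over the forced total order
(ties broken by stable index order); AUROC uses rank averaging over tied
blocks, equivalent to the trapezoidal area.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.stats import rankdata

from .io import GroundTruthNetwork


@dataclasses.dataclass
class EvalReport:
    auprc: float
    auroc: float
    signed_auprc: float
    signed_auroc: float
    auprc_ratio: float
    signed_auprc_ratio: float
    early_precision: float
    ep_ratio: float
    random_baseline: float
    n_true_edges: int
    n_possible_edges: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def __str__(self):
        return "\n".join(f"{k}: {v:.6g}" if isinstance(v, float) else f"{k}: {v}"
                         for k, v in self.to_dict().items())


def _offdiag_flat(M):
    m = M.shape[0]
    mask = ~np.eye(m, dtype=bool)
    return M[mask]  # row-major stable index order


def average_precision(scores, labels) -> float:
    """AP over the descending-score ranking, ties broken by stable input order."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    lab = np.asarray(labels, bool)[order]
    P = lab.sum()
    if P == 0:
        raise ValueError("no positive labels")
    tp = np.cumsum(lab)
    ranks = np.arange(1, lab.size + 1)
    return float(np.sum((tp[lab] / ranks[lab])) / P)


def auroc_score(scores, labels) -> float:
    """Mann-Whitney AUROC with tied scores averaged over their block."""
    lab = np.asarray(labels, bool)
    P = int(lab.sum())
    Ng = lab.size - P
    if P == 0 or Ng == 0:
        raise ValueError("AUROC needs both positives and negatives")
    r = rankdata(scores)  # average ranks over ties
    return float((r[lab].sum() - P * (P + 1) / 2) / (P * Ng))


def random_baseline(truth: GroundTruthNetwork) -> float:
    """Edge density over ordered off-diagonal pairs (the random-classifier AUPRC)."""
    m = len(truth.gene_names)
    n_true = truth.n_edges
    if n_true == 0:
        raise ValueError("ground truth has no edges")
    return n_true / (m * m - m)


def _signed_weights(weights, truth_adj):
    w = np.asarray(weights, float).copy()
    mism = (truth_adj != 0) & (np.sign(w) != truth_adj) & (w != 0)
    w[mism] = 0.0
    return w


def symmetrize_undirected(weights) -> np.ndarray:
    """Max-|weight| over both directions (optional undirected evaluation)."""
    w = np.asarray(weights, float)
    pick = np.abs(w) >= np.abs(w.T)
    return np.where(pick, w, w.T)


def evaluate(weights, truth: GroundTruthNetwork, gene_names=None,
             undirected: bool = False) -> EvalReport:
    """Score an m x m predicted weight matrix against the signed ground truth.

    ``gene_names`` (defaulting to the truth's) must match the truth exactly;
    a mismatch raises with the symmetric difference.  Early precision uses
    k = min(#true edges, #nonzero predictions).
    """
    w = np.asarray(weights, float)
    if gene_names is not None:
        sym = set(gene_names) ^ set(truth.gene_names)
        if sym:
            raise ValueError(f"gene sets differ between prediction and truth: {sorted(sym)}")
        order = [list(gene_names).index(g) for g in truth.gene_names]
        w = w[np.ix_(order, order)]
    if w.shape != truth.adjacency.shape:
        raise ValueError("weight matrix shape does not match the ground truth")
    if undirected:
        w = symmetrize_undirected(w)
    adj = truth.adjacency
    baseline = random_baseline(truth)
    m = adj.shape[0]

    labels = _offdiag_flat(np.abs(adj) > 0)
    scores = _offdiag_flat(np.abs(w))
    auprc = average_precision(scores, labels)
    auroc = auroc_score(scores, labels)

    ws = _signed_weights(w, adj)
    s_scores = _offdiag_flat(np.abs(ws))
    signed_auprc = average_precision(s_scores, labels)
    signed_auroc = auroc_score(s_scores, labels)

    # early precision on the unsigned ranking
    n_true = int(labels.sum())
    n_pred = int(np.count_nonzero(scores))
    k = min(n_true, n_pred)
    if k > 0:
        order = np.argsort(-scores, kind="stable")[:k]
        ep = float(labels[order].sum() / k)
    else:
        ep = 0.0
    return EvalReport(
        auprc=auprc, auroc=auroc,
        signed_auprc=signed_auprc, signed_auroc=signed_auroc,
        auprc_ratio=auprc / baseline, signed_auprc_ratio=signed_auprc / baseline,
        early_precision=ep, ep_ratio=ep / baseline,
        random_baseline=baseline,
        n_true_edges=n_true, n_possible_edges=m * m - m,
    )
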