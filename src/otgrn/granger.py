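"""Granger-causal GRN inference by per-interval elastic-net regression.

For each pair of consecutive time points the velocities of the cells observed
at t_{k+1} are regressed, gene by gene, on the *projected* velocities of the
previous cohort carried onto the same cells (couplings pair past and present
states because no cell is observed twice).  The elastic-net penalty keeps the
per-interval coefficient matrices sparse; the global network is their sum.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import numpy as np
from sklearn.linear_model import ElasticNet

from .velocity import VelocityField


@dataclasses.dataclass
class GrangerGRN:
    gene_names: list
    A_intervals: List[np.ndarray]   # rows = targets, columns = regulators
    A_global: np.ndarray            # exact elementwise sum of A_intervals
    interval_times: List[tuple]
    lam: float
    ratio_r: float
    fit_report: List[dict]
    stimulus_index: Optional[int] = None

    def edge_weights(self) -> np.ndarray:
        """Weight of edge g1 -> g2 at [g1, g2] (transpose of the coefficient layout)."""
        return self.A_global.T


def fit_interval_regression(outcome: np.ndarray, predictor: np.ndarray,
                            lam: float, ratio_r: float,
                            stimulus_index: Optional[int] = None,
                            max_iter: int = 10000) -> np.ndarray:
    """Elastic-net fit of current velocities on projected past velocities.

    Both matrices are m x n over the same cells.  Per target gene g2 the
    objective is

        1/(2n) * sum_c (v_{g2,c} - sum_{g1} A[g2,g1] vhat_{g1,c})^2
        + lam * (ratio_r * ||A[g2,:]||_1 + (1 - ratio_r)/2 * ||A[g2,:]||_2^2)

    with no intercept (velocities are deliberately not mean-centered: their
    signs determine activation vs inhibition).  ``lam=0`` reduces to ordinary
    least squares, ``ratio_r=0`` to ridge (both solved in closed form).  A
    stimulus gene is predictor-only: its target row stays zero.
    """
    outcome = np.asarray(outcome, float)
    predictor = np.asarray(predictor, float)
    if outcome.shape != predictor.shape:
        raise ValueError("outcome and predictor must have identical m x n shapes")
    m, n = outcome.shape
    if n < 2:
        raise ValueError("need at least 2 cells for the regression")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    X = predictor.T  # n x m design
    A = np.zeros((m, m))
    for g2 in range(m):
        if stimulus_index is not None and g2 == stimulus_index:
            continue
        y = outcome[g2]
        if lam == 0:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        elif ratio_r == 0:
            # ridge closed form under the 1/(2n) data scaling
            G = X.T @ X / n + lam * np.eye(m)
            coef = np.linalg.solve(G, X.T @ y / n)
        else:
            en = ElasticNet(alpha=lam, l1_ratio=ratio_r, fit_intercept=False,
                            max_iter=max_iter, tol=1e-8)
            en.fit(X, y)
            coef = en.coef_
        A[g2] = coef
    return A


def aggregate_global(A_intervals: List[np.ndarray]) -> np.ndarray:
    """Elementwise sum of the per-interval matrices (signs preserved)."""
    if len(A_intervals) == 0:
        raise ValueError("no interval matrices to aggregate")
    out = np.zeros_like(A_intervals[0])
    for A in A_intervals:
        out = out + A
    return out


def fit_granger(field: VelocityField, lam: float = 1.0,
                ratio_r: float = 0.5) -> GrangerGRN:
    """Run the per-interval regressions over a velocity field and aggregate."""
    if not field.normalized:
        raise ValueError("velocities must be normalized before the regression")
    A_intervals, reports, interval_times = [], [], []
    for k in range(len(field.times) - 1):
        A = fit_interval_regression(field.velocities[k + 1], field.projected[k],
                                    lam, ratio_r, stimulus_index=field.stimulus_index)
        resid = field.velocities[k + 1] - A @ field.projected[k]
        n = field.velocities[k + 1].shape[1]
        reports.append({
            "interval": (float(field.times[k]), float(field.times[k + 1])),
            "rss_per_cell": float(np.sum(resid ** 2)) / n,
            "nonzero": int(np.count_nonzero(np.abs(A) > 1e-12)),
        })
        A_intervals.append(A)
        interval_times.append((field.times[k], field.times[k + 1]))
    return GrangerGRN(gene_names=list(field.gene_names), A_intervals=A_intervals,
                      A_global=aggregate_global(A_intervals),
                      interval_times=interval_times, lam=lam, ratio_r=ratio_r,
                      fit_report=reports, stimulus_index=field.stimulus_index)


def combine_branches(matrices: List[np.ndarray], rule: str = "sum") -> np.ndarray:
    """Combine per-branch weight matrices into one.

    ``sum`` adds elementwise; ``maxabs`` takes, per entry, the signed value of
    largest absolute value across branches (ties go to the lowest branch index).
    """
    if len(matrices) == 0:
        raise ValueError("no branch matrices to combine")
    stack = np.stack([np.asarray(M, float) for M in matrices])
    if rule == "sum":
        return stack.sum(axis=0)
    if rule == "maxabs":
        pick = np.argmax(np.abs(stack), axis=0)  # first max -> lowest branch index
        return np.take_along_axis(stack, pick[None], axis=0)[0]
    raise ValueError(f"unknown combine rule {rule!r}")
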