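"""Per-cell, per-gene velocities from transport couplings.

A cell's forward velocity is the finite difference between its barycentric
descendant prediction and its observed state; the backward velocity uses the
transposed coupling of the previous interval.  Interior time points combine
both through the non-uniform-spacing centered difference.  Velocities are
normalized per gene to unit pooled standard deviation so that correlations
across genes are unit-free.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import numpy as np

from .coupling import CouplingSequence, barycentric_project
from .io import ExpressionDataset

STIMULUS_GENE = "stimulus"


@dataclasses.dataclass
class VelocityField:
    """Velocities per time point plus interval-projected velocities.

    ``velocities[k]`` is m x n(t_k): v(x^{t_k, c}, t_k).
    ``projected[k]`` is m x n(t_{k+1}): the velocities at t_k carried onto the
    cells observed at t_{k+1} (column-normalized coupling average), which is
    what pairs past and present velocities for the Granger regression.
    """

    gene_names: list
    times: np.ndarray
    velocities: List[np.ndarray]
    projected: List[np.ndarray]
    normalized: bool = False
    gene_sds: Optional[np.ndarray] = None
    zero_sd_genes: Optional[list] = None
    stimulus_index: Optional[int] = None
    stimulus_time_index: Optional[int] = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


def compute_velocities(dataset: ExpressionDataset,
                       couplings: CouplingSequence) -> VelocityField:
    """Finite-difference velocities: forward at t_1, centered inside, backward at t_N."""
    N = dataset.n_times
    if len(couplings) != N - 1:
        raise ValueError(f"need {N - 1} consecutive couplings, got {len(couplings)}")
    X = dataset.matrices
    t = dataset.times
    # descendant / ancestor predictions per interval
    fwd = []   # fwd[k]: m x n(t_k), prediction of each t_k cell at t_{k+1}
    bwd = []   # bwd[k]: m x n(t_{k+1}), prediction of each t_{k+1} cell at t_k
    for k, T in enumerate(couplings.couplings):
        fwd.append(barycentric_project(T, X[k + 1]))
        bwd.append(barycentric_project(T.T, X[k]))
    v = []
    for k in range(N):
        if k < N - 1:
            dt_f = t[k + 1] - t[k]
            v_forward = (fwd[k] - X[k]) / dt_f
        if k > 0:
            dt_b = t[k] - t[k - 1]
            v_backward = (X[k] - bwd[k - 1]) / dt_b
        if k == 0:
            v.append(v_forward)
        elif k == N - 1:
            v.append(v_backward)
        else:
            span = t[k + 1] - t[k - 1]
            v.append((t[k] - t[k - 1]) / span * v_forward
                     + (t[k + 1] - t[k]) / span * v_backward)
    projected = [project_velocity(T, v[k]) for k, T in enumerate(couplings.couplings)]
    return VelocityField(gene_names=list(dataset.gene_names), times=t.copy(),
                         velocities=v, projected=projected)


def project_velocity(T: np.ndarray, v_source: np.ndarray) -> np.ndarray:
    """Carry source-cohort velocities onto target cells.

    For target cell c~: v_hat = sum_c (T[c, c~] / sum_d T[d, c~]) v(x^{t,c}, t)
    -- the column-normalized coupling average.
    """
    cols = T.sum(axis=0)
    if np.any(cols == 0):
        raise ValueError("coupling has a zero column; cannot project velocities")
    W = T / cols[None, :]
    return v_source @ W


def normalize_velocities(field: VelocityField) -> VelocityField:
    """Scale each gene to unit pooled standard deviation (population convention).

    The pool is all cells at all time points.  Means are deliberately not
    subtracted: velocity signs carry the activation/inhibition information.
    Zero-SD genes are left untouched and recorded; a stimulus gene keeps its
    unit magnitude.
    """
    if field.normalized:
        raise ValueError("velocity field is already normalized")
    pooled = np.concatenate(field.velocities, axis=1)
    sds = pooled.std(axis=1)  # population SD (divide by count)
    scale = np.ones_like(sds)
    zero = sds == 0
    nz = ~zero
    scale[nz] = 1.0 / sds[nz]
    if field.stimulus_index is not None:
        scale[field.stimulus_index] = 1.0
    return VelocityField(
        gene_names=list(field.gene_names),
        times=field.times.copy(),
        velocities=[v * scale[:, None] for v in field.velocities],
        projected=[v * scale[:, None] for v in field.projected],
        normalized=True,
        gene_sds=sds,
        zero_sd_genes=[field.gene_names[i] for i in np.flatnonzero(zero)],
        stimulus_index=field.stimulus_index,
        stimulus_time_index=field.stimulus_time_index,
    )


def add_stimulus_gene(field: VelocityField, stimulus_time_index: int) -> VelocityField:
    """Append an artificial gene with velocity 1 at the stimulus time, 0 elsewhere.

    The stimulus gene is predictor/source-only downstream and bypasses SD
    normalization.  Its projection onto any interval is exact: a coupling
    average of a constant is that constant.
    """
    N = len(field.times)
    if not 0 <= stimulus_time_index < N:
        raise ValueError(f"stimulus_time_index {stimulus_time_index} out of range")
    if field.stimulus_index is not None:
        raise ValueError("field already carries a stimulus gene")
    vel = [np.vstack([v, np.full((1, v.shape[1]),
                                 1.0 if k == stimulus_time_index else 0.0)])
           for k, v in enumerate(field.velocities)]
    proj = [np.vstack([v, np.full((1, v.shape[1]),
                                  1.0 if k == stimulus_time_index else 0.0)])
            for k, v in enumerate(field.projected)]
    sds = None
    if field.gene_sds is not None:
        sds = np.append(field.gene_sds, 1.0)
    return VelocityField(
        gene_names=list(field.gene_names) + [STIMULUS_GENE],
        times=field.times.copy(),
        velocities=vel,
        projected=proj,
        normalized=field.normalized,
        gene_sds=sds,
        zero_sd_genes=field.zero_sd_genes,
        stimulus_index=len(field.gene_names),
        stimulus_time_index=stimulus_time_index,
    )


def project_onto_embedding(field: VelocityField, coords: List[np.ndarray],
                           dataset: ExpressionDataset) -> List[np.ndarray]:
    """Project velocities onto user-supplied 2-D coordinates per cell.

    ``coords[k]`` is n(t_k) x 2.  The displacement of each cell in embedding
    space is estimated by regressing the embedding onto expression locally is
    overkill at this scale; instead we use the finite-difference displacement
    of the embedded barycentric predictions, i.e. delta_embed ~ J v with J the
    least-squares linear map from expression to embedding fitted per time point.
    """
    out = []
    for k in range(len(field.times)):
        X = dataset.matrices[k]  # m x n
        Y = np.asarray(coords[k], float)  # n x 2
        Xc = X - X.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=0, keepdims=True)
        J, *_ = np.linalg.lstsq(Xc.T, Yc, rcond=None)  # m x 2
        v = field.velocities[k][:X.shape[0], :]
        out.append(v.T @ J)  # n x 2 arrows
    return out
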