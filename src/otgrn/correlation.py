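"""OT-weighted time-lagged correlation across genes (the "Corr" GRN method).

The evidence that gene g1 regulates gene g2 is the coupling-weighted product
of g1's velocity at one time with g2's velocity ``lag`` steps later, averaged
over the time course:

    C[g1, g2] = 1/(N - lag) * sum_k  v_{g1}(t_k)  T^{t_k, t_{k+lag}}  v_{g2}(t_{k+lag})^T

A positive entry suggests activation of g2 by g1 (g1's change precedes a
same-direction change of g2), a negative entry inhibition.  With velocities
normalized to unit standard deviation the matrix is unit-free.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import numpy as np
import pandas as pd

from .coupling import CouplingSequence, compose_couplings
from .velocity import VelocityField


@dataclasses.dataclass
class CorrelationGRN:
    """Aggregated and per-interval time-lagged correlation matrices."""

    gene_names: list
    C: np.ndarray
    per_interval: List[np.ndarray]
    interval_times: List[tuple]
    lag: int
    stimulus_index: Optional[int] = None


def lagged_correlation(field: VelocityField, couplings: CouplingSequence,
                       lag: int = 1) -> CorrelationGRN:
    """Compute the OT-weighted lagged correlation matrix and its interval terms.

    For ``lag > 1`` the joint plan across the lag is the composition of the
    consecutive couplings (Markov-kernel chaining).  A stimulus gene, if
    present, is kept as a source (row) but removed as a target (column).
    """
    N = len(field.times)
    if lag >= N:
        raise ValueError(f"lag must be < number of time points ({N})")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if not field.normalized:
        raise ValueError("velocities must be normalized before correlation")
    per_interval = []
    interval_times = []
    for k in range(N - lag):
        T = compose_couplings(couplings.couplings[k:k + lag])
        Ck = field.velocities[k] @ T @ field.velocities[k + lag].T
        if field.stimulus_index is not None:
            Ck[:, field.stimulus_index] = 0.0  # stimulus is source-only
        per_interval.append(Ck)
        interval_times.append((field.times[k], field.times[k + lag]))
    C = sum(per_interval) / (N - lag)
    return CorrelationGRN(gene_names=list(field.gene_names), C=C,
                          per_interval=per_interval, interval_times=interval_times,
                          lag=lag, stimulus_index=field.stimulus_index)


def interval_correlation(grn: CorrelationGRN, k_start: int, k_end: int) -> np.ndarray:
    """Average of the per-interval matrices for k in [k_start, k_end)."""
    if not 0 <= k_start < k_end <= len(grn.per_interval):
        raise ValueError(f"empty or out-of-range interval [{k_start}, {k_end})")
    return sum(grn.per_interval[k_start:k_end]) / (k_end - k_start)


def in_out_degree(C, gene_names=None, top_fraction=None) -> pd.Series:
    """Incoming over outgoing absolute correlation weight per gene.

    deg(g) = sum_{g~ != g} |C[g~, g]|  /  sum_{g~ != g} |C[g, g~]|.
    Values below 1 suggest a regulator (transcription-factor-like), above 1 a
    target.  A zero denominator with nonzero numerator yields +inf; 0/0 yields
    NaN.  ``top_fraction`` optionally keeps only the largest-|entry| fraction
    of off-diagonal entries before forming the ratio.
    """
    C = np.asarray(C, float).copy()
    m = C.shape[0]
    np.fill_diagonal(C, 0.0)
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        off = np.abs(C[~np.eye(m, dtype=bool)])
        k = int(np.ceil(top_fraction * off.size))
        thresh = np.sort(off)[::-1][k - 1] if k >= 1 else np.inf
        C[np.abs(C) < thresh] = 0.0
    absC = np.abs(C)
    incoming = absC.sum(axis=0)
    outgoing = absC.sum(axis=1)
    deg = np.empty(m)
    for g in range(m):
        if outgoing[g] == 0:
            deg[g] = np.nan if incoming[g] == 0 else np.inf
        else:
            deg[g] = incoming[g] / outgoing[g]
    index = gene_names if gene_names is not None else range(m)
    return pd.Series(deg, index=index, name="in_out_degree")
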