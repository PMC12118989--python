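"""Model/Results interface wiring the pipeline end to end.

:class:`VelocityGRN` is built from an :class:`~otgrn.io.ExpressionDataset`
plus hyperparameters; :meth:`VelocityGRN.fit` runs

    log transform -> cost/structure matrices -> entropic fused-GW couplings
    -> finite-difference velocities -> per-gene normalization
    -> (optional stimulus gene) -> correlation or Granger regression
    -> (optional branch combination)

and returns a :class:`GRNResults` carrying the signed weight matrix, the
per-interval decomposition, diagnostics and a ``summary()`` table.  Couplings
and velocities are cached on the model, so fitting both methods on the same
model solves the transport problems once.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .coupling import CouplingSequence, solve_coupling_sequence
from .correlation import CorrelationGRN, in_out_degree, lagged_correlation
from .evaluation import EvalReport, evaluate
from .granger import GrangerGRN, combine_branches, fit_granger
from .io import ExpressionDataset, GroundTruthNetwork, RunConfig, write_edge_list
from .preprocess import build_cost_inputs, log_transform
from .velocity import (STIMULUS_GENE, VelocityField, add_stimulus_gene,
                       compute_velocities, normalize_velocities)


class VelocityGRN:
    """Gene-velocity GRN model over time-stamped single-cell cohorts.

    Parameters mirror :class:`~otgrn.io.RunConfig`; keyword overrides win
    over the supplied config.  ``stimulus_time`` is matched against the
    dataset's time stamps (an integer that matches no time stamp is taken as
    a time-point index).
    """

    def __init__(self, dataset: ExpressionDataset, config: Optional[RunConfig] = None,
                 log1p: Optional[bool] = None, **overrides):
        if config is None:
            config = RunConfig()
        if overrides:
            config = dataclasses.replace(config, **overrides)
        self.config = config
        self.raw_dataset = dataset
        if log1p is None:
            log1p = not dataset.transformed
        self.dataset = log_transform(dataset) if log1p and not dataset.transformed else dataset
        self._cache = {}

    # -- pipeline -----------------------------------------------------------
    def _stimulus_index(self, times) -> Optional[int]:
        st = self.config.stimulus_time
        if st is None:
            return None
        close = np.flatnonzero(np.isclose(times, st))
        if close.size:
            return int(close[0])
        if float(st).is_integer() and 0 <= int(st) < len(times):
            return int(st)
        raise ValueError(f"stimulus time {st!r} matches no time point in {times}")

    def _run_pipeline(self, ds: ExpressionDataset):
        cfg = self.config
        costs = [build_cost_inputs(ds, k, k + 1, metric=cfg.metric,
                                   marginal_mode=cfg.marginal_mode)
                 for k in range(ds.n_times - 1)]
        couplings = solve_coupling_sequence(costs, alpha=cfg.alpha,
                                            epsilon=cfg.epsilon, gw_loss=cfg.gw_loss)
        field = normalize_velocities(compute_velocities(ds, couplings))
        stim = self._stimulus_index(ds.times)
        if stim is not None:
            field = add_stimulus_gene(field, stim)
        return couplings, field

    def _branch_datasets(self):
        if self.config.branch_mode == "split" and self.dataset.branch_labels is not None:
            return {b: self.dataset.subset_branch(b)
                    for b in self.dataset.branch_names()}
        return {None: self.dataset}

    def _pipeline(self, branch):
        if branch not in self._cache:
            self._cache[branch] = self._run_pipeline(self._branch_datasets()[branch])
        return self._cache[branch]

    # -- fitting ------------------------------------------------------------
    def fit(self, method: str = "corr", lag: Optional[int] = None,
            lam: Optional[float] = None, ratio_r: Optional[float] = None) -> "GRNResults":
        cfg = self.config
        lag = cfg.lag if lag is None else lag
        lam = cfg.lam if lam is None else lam
        ratio_r = cfg.ratio_r if ratio_r is None else ratio_r
        if method not in ("corr", "granger"):
            raise ValueError(f"unknown method {method!r}; use 'corr' or 'granger'")

        branch_weights = {}
        raw = {}
        per_interval = None
        interval_times = None
        gene_names = None
        for branch in self._branch_datasets():
            couplings, field = self._pipeline(branch)
            if method == "corr":
                grn = lagged_correlation(field, couplings, lag=lag)
                weights = grn.C  # already oriented regulator -> target
                intervals = grn.per_interval
                itimes = grn.interval_times
            else:
                grn = fit_granger(field, lam=lam, ratio_r=ratio_r)
                weights = grn.A_global.T  # edge g1 -> g2 lives at A[g2, g1]
                intervals = [A.T for A in grn.A_intervals]
                itimes = grn.interval_times
            raw[branch] = grn
            branch_weights[branch] = weights
            if gene_names is None:
                gene_names = grn.gene_names
            if branch is None:
                per_interval = intervals
                interval_times = itimes

        if None in branch_weights:
            weights = branch_weights[None]
            branch_weights = None
        else:
            weights = combine_branches(list(branch_weights.values()),
                                       rule=cfg.combine_rule)
        params = {"method": method, "alpha": cfg.alpha, "epsilon": cfg.epsilon,
                  "lag": lag, "lam": lam, "ratio_r": ratio_r,
                  "metric": cfg.metric, "marginal_mode": cfg.marginal_mode,
                  "branch_mode": cfg.branch_mode, "combine_rule": cfg.combine_rule,
                  "gw_loss": cfg.gw_loss, "stimulus_time": cfg.stimulus_time}
        return GRNResults(model=self, method=method, gene_names=list(gene_names),
                          weights=weights, per_interval=per_interval,
                          interval_times=interval_times, params=params,
                          branch_weights=branch_weights, raw=raw)

    @property
    def couplings(self) -> CouplingSequence:
        """Couplings of the combined (or only) pipeline."""
        return self._pipeline(next(iter(self._branch_datasets())))[0]

    @property
    def velocity_field(self) -> VelocityField:
        return self._pipeline(next(iter(self._branch_datasets())))[1]


@dataclasses.dataclass
class GRNResults:
    """Inferred signed GRN: ``weights[g1, g2]`` is the evidence that g1 regulates g2."""

    model: VelocityGRN
    method: str
    gene_names: list
    weights: np.ndarray
    per_interval: Optional[List[np.ndarray]]
    interval_times: Optional[List[tuple]]
    params: dict
    branch_weights: Optional[dict] = None
    raw: Optional[dict] = None

    # -- views --------------------------------------------------------------
    def weight_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.gene_names, columns=self.gene_names)

    def edge_frame(self, top_fraction: float = 1.0) -> pd.DataFrame:
        excl = [STIMULUS_GENE] if STIMULUS_GENE in self.gene_names else ()
        return write_edge_list(self.weights, self.gene_names, top_fraction,
                               out_path=None, exclude_targets=excl)

    def to_edge_list(self, path, top_fraction: float = 1.0,
                     interval: str = "global") -> pd.DataFrame:
        excl = [STIMULUS_GENE] if STIMULUS_GENE in self.gene_names else ()
        return write_edge_list(self.weights, self.gene_names, top_fraction,
                               out_path=path, interval=interval, exclude_targets=excl)

    def interval_matrix(self, k: int) -> np.ndarray:
        if self.per_interval is None:
            raise ValueError("no per-interval decomposition available (split branch mode)")
        return self.per_interval[k]

    def in_out_degree(self, top_fraction=None) -> pd.Series:
        return in_out_degree(self.weights, gene_names=self.gene_names,
                             top_fraction=top_fraction)

    # -- scoring ------------------------------------------------------------
    def evaluate(self, truth: GroundTruthNetwork, undirected: bool = False) -> EvalReport:
        """Score against a signed ground truth, aligning genes by name.

        An artificial stimulus gene present in the prediction but absent from
        the truth is dropped before scoring; any other mismatch is an error.
        """
        names = list(self.gene_names)
        w = self.weights
        if STIMULUS_GENE in names and STIMULUS_GENE not in truth.gene_names:
            i = names.index(STIMULUS_GENE)
            keep = [j for j in range(len(names)) if j != i]
            names = [names[j] for j in keep]
            w = w[np.ix_(keep, keep)]
        return evaluate(w, truth, gene_names=names, undirected=undirected)

    # -- reporting ----------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        ds = self.model.dataset
        lines = []
        title = "Velocity-GRN results (%s)" % (
            "time-lagged correlation" if self.method == "corr" else "Granger elastic net")
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"genes: {len(self.gene_names)}   time points: {ds.n_times}   "
                     f"cells: {sum(ds.n_cells)}")
        lines.append("params: " + ", ".join(
            f"{k}={v}" for k, v in self.params.items() if v is not None))
        if self.raw is not None and None in self.raw:
            coup = self.model.couplings
            lines.append(f"coupling diagnostics: max marginal violation "
                         f"{coup.max_marginal_violation():.3e}; outer iterations "
                         f"{[r.n_outer for r in coup.reports]}")
        m = len(self.gene_names)
        off = self.weights[~np.eye(m, dtype=bool)]
        nz = int(np.count_nonzero(np.abs(off) > 1e-12))
        lines.append(f"nonzero off-diagonal weights: {nz} / {off.size}")
        edges = self.edge_frame(top_fraction=1.0).head(top)
        lines.append("")
        lines.append(f"top {min(top, len(edges))} edges by |weight|:")
        lines.append(edges.to_string(index=False))
        return "\n".join(lines) + "\n"

    def __repr__(self):
        return (f"<GRNResults method={self.method!r} genes={len(self.gene_names)} "
                f"intervals={0 if self.per_interval is None else len(self.per_interval)}>")
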