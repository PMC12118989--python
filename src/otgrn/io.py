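"""Reading and writing expression matrices, metadata, edge lists and run configuration.

Expression input is a genes x cells matrix, either delimited text (CSV/TSV,
genes as rows, header row of cell identifiers) or a MatrixMarket file with
sidecar gene/cell name files.  Cell metadata is a delimited table with one row
per cell carrying a ``time`` label (or a continuous ``pseudotime`` that is
binned by quantiles), plus optional ``branch`` and ``weight`` columns.
Cohorts at different time points contain *different* cells (destructive
sampling); the dataset container therefore stores one matrix per time point.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml


@dataclasses.dataclass
class ExpressionDataset:
    """Time-stamped single-cell expression cohorts.

    Attributes
    ----------
    gene_names : list of str
        Ordered gene identifiers, identical across time points (m genes).
    times : ndarray, shape (N,)
        Strictly increasing real time stamps.
    matrices : list of ndarray
        One ``m x n(t)`` matrix per time point.
    cell_ids : list of list of str
        Cell identifiers per time point.
    branch_labels : list of ndarray, optional
        Per-cell categorical branch/lineage labels.
    cell_weights : list of ndarray, optional
        Per-cell nonnegative weights, summing to 1 within each time point.
    pseudotime : list of ndarray, optional
        Per-cell continuous pseudotime, if the time labels were derived by
        binning.
    transformed : bool
        Whether the log1p transform has been applied.
    """

    gene_names: list
    times: np.ndarray
    matrices: list
    cell_ids: list
    branch_labels: Optional[list] = None
    cell_weights: Optional[list] = None
    pseudotime: Optional[list] = None
    transformed: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.matrices = [np.asarray(x, dtype=float) for x in self.matrices]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self):
        if len(self.times) < 2:
            raise ValueError("dataset needs at least 2 time points, got %d" % len(self.times))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        m = len(self.gene_names)
        for t, x in zip(self.times, self.matrices):
            if x.shape[0] != m:
                raise ValueError(f"matrix at t={t} has {x.shape[0]} genes, expected {m}")
            if x.shape[1] < 2:
                raise ValueError(f"fewer than 2 cells at time {t}")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite expression value at time {t}")
            if not self.transformed and np.any(x < 0):
                raise ValueError(f"negative expression value at time {t}")
        if self.cell_weights is not None:
            for t, w in zip(self.times, self.cell_weights):
                w = np.asarray(w, dtype=float)
                if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
                    raise ValueError(f"cell weights at time {t} must be nonnegative and sum to 1")

    # -- conveniences -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_cells(self) -> list:
        return [x.shape[1] for x in self.matrices]

    def branch_names(self):
        if self.branch_labels is None:
            return []
        out = []
        for lab in self.branch_labels:
            for b in lab:
                if b not in out:
                    out.append(b)
        return out

    def subset_branch(self, branch) -> "ExpressionDataset":
        """Restrict to the cells of one branch, dropping time points with < 2 cells."""
        if self.branch_labels is None:
            raise ValueError("dataset has no branch labels")
        times, mats, cids, pts = [], [], [], []
        for k in range(self.n_times):
            mask = np.asarray(self.branch_labels[k]) == branch
            if mask.sum() < 2:
                continue
            times.append(self.times[k])
            mats.append(self.matrices[k][:, mask])
            cids.append([c for c, keep in zip(self.cell_ids[k], mask) if keep])
            if self.pseudotime is not None:
                pts.append(np.asarray(self.pseudotime[k])[mask])
        if len(times) < 2:
            raise ValueError(f"branch {branch!r} present at fewer than 2 time points")
        return ExpressionDataset(
            gene_names=list(self.gene_names),
            times=np.asarray(times),
            matrices=mats,
            cell_ids=cids,
            pseudotime=pts if self.pseudotime is not None else None,
            transformed=self.transformed,
        )


@dataclasses.dataclass
class GroundTruthNetwork:
    """Signed ground-truth regulatory network.

    ``adjacency[i, j]`` in {-1, 0, +1} means gene ``i`` regulates gene ``j``
    with that sign.  The diagonal (self-loops) is ignored in all scoring.
    """

    gene_names: list
    adjacency: np.ndarray
    stimulus: Optional[int] = None  # index of the stimulus node, if any

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        m = len(self.gene_names)
        if self.adjacency.shape != (m, m):
            raise ValueError("adjacency shape does not match gene_names")
        if not np.all(np.isin(self.adjacency, (-1, 0, 1))):
            raise ValueError("adjacency entries must be in {-1, 0, +1}")

    @property
    def n_edges(self) -> int:
        a = self.adjacency.copy()
        np.fill_diagonal(a, 0)
        return int(np.count_nonzero(a))

    def to_edge_list(self, path):
        rows = []
        a = self.adjacency
        for i, g1 in enumerate(self.gene_names):
            for j, g2 in enumerate(self.gene_names):
                if i != j and a[i, j] != 0:
                    rows.append((g1, g2, int(a[i, j])))
        df = pd.DataFrame(rows, columns=["regulator", "target", "sign"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_edge_list(cls, path, gene_names=None, stimulus=None):
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower(): c for c in df.columns}
        reg, tgt = df[cols["regulator"]], df[cols["target"]]
        sign = df[cols["sign"]] if "sign" in cols else pd.Series(np.ones(len(df)))
        if gene_names is None:
            gene_names = []
            for g in list(reg) + list(tgt):
                if g not in gene_names:
                    gene_names.append(g)
        idx = {g: i for i, g in enumerate(gene_names)}
        m = len(gene_names)
        adj = np.zeros((m, m), dtype=int)
        for g1, g2, s in zip(reg, tgt, sign):
            adj[idx[g1], idx[g2]] = int(np.sign(s))
        stim_idx = idx[stimulus] if isinstance(stimulus, str) else stimulus
        return cls(gene_names=list(gene_names), adjacency=adj, stimulus=stim_idx)


@dataclasses.dataclass
class RunConfig:
    """Hyperparameters of the inference pipeline.

    ``alpha`` trades the Wasserstein (feature) term against the
    Gromov-Wasserstein (structure) term; ``epsilon`` is the entropic
    regularization strength; ``lam`` and ``ratio_r`` are the elastic-net
    magnitude and l1/l2 mix of the Granger regression.
    """

    alpha: float = 0.5
    epsilon: float = 0.01
    lam: float = 1.0
    ratio_r: float = 0.5
    lag: int = 1
    n_bins: Optional[int] = None
    marginal_mode: str = "uniform"
    branch_mode: str = "combined"
    combine_rule: str = "sum"
    metric: str = "euclidean"
    gw_loss: str = "square"
    stimulus_time: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0 <= self.ratio_r <= 1:
            raise ValueError("ratio_r must lie in [0, 1]")
        if self.lag < 1:
            raise ValueError("lag must be a positive integer")
        if self.marginal_mode not in ("uniform", "branch_reweighed"):
            raise ValueError(f"unknown marginal_mode {self.marginal_mode!r}")
        if self.branch_mode not in ("split", "combined"):
            raise ValueError(f"unknown branch_mode {self.branch_mode!r}")
        if self.combine_rule not in ("sum", "maxabs"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _read_matrix(matrix_path, gene_names_path=None, cell_ids_path=None):
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if gene_names_path is None:
            gene_names_path = matrix_path.with_name(matrix_path.stem + "_genes.txt")
        if cell_ids_path is None:
            cell_ids_path = matrix_path.with_name(matrix_path.stem + "_cells.txt")
        genes = Path(gene_names_path).read_text().split()
        cells = Path(cell_ids_path).read_text().split()
        return pd.DataFrame(mat, index=genes, columns=cells)
    sep = _sniff_sep(matrix_path)
    return pd.read_csv(matrix_path, sep=sep, index_col=0)


def read_expression(matrix_path, metadata_path, n_bins=None,
                    gene_names_path=None, cell_ids_path=None) -> ExpressionDataset:
    """Read a genes x cells matrix and per-cell metadata into a dataset.

    The metadata table needs a ``cell_id`` column (or uses its first column),
    and either a ``time`` column or a ``pseudotime`` column (the latter is
    binned into ``n_bins`` quantile bins).  Optional columns: ``branch``,
    ``weight``.
    """
    df = _read_matrix(matrix_path, gene_names_path, cell_ids_path)
    meta = pd.read_csv(metadata_path, sep=_sniff_sep(metadata_path))
    meta.columns = [c.lower() for c in meta.columns]
    id_col = "cell_id" if "cell_id" in meta.columns else meta.columns[0]
    meta = meta.set_index(meta[id_col].astype(str))

    cells = [str(c) for c in df.columns]
    missing = [c for c in cells if c not in meta.index]
    if missing and len(missing) == len(cells) and df.shape[0] == len(meta):
        # no column matches but the row count does: classic transposed input
        raise ValueError(
            "matrix appears to be transposed (rows match the metadata cell count); "
            "expected genes as rows and cells as columns")
    if missing:
        raise ValueError(f"cell {missing[0]!r} missing from metadata "
                         f"({len(missing)} cells unmatched in total)")
    extra = [c for c in meta.index if c not in set(cells)]
    if extra:
        warnings.warn(f"{len(extra)} metadata rows have no matrix column "
                      f"(first: {extra[0]!r}); they are ignored")
    meta = meta.loc[cells]

    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative expression values in matrix")

    pseudotime = None
    if "time" in meta.columns:
        time_labels = meta["time"].to_numpy(dtype=float)
    elif "pseudotime" in meta.columns:
        if n_bins is None:
            raise ValueError("metadata has only pseudotime; pass n_bins to bin it")
        pseudotime = meta["pseudotime"].to_numpy(dtype=float)
        bins = bin_pseudotime(pseudotime, n_bins)
        # bin midpoints of the pseudotime ranges serve as time stamps
        time_labels = np.empty(len(bins))
        for b in range(n_bins):
            sel = bins == b
            time_labels[sel] = 0.5 * (pseudotime[sel].min() + pseudotime[sel].max())
    else:
        raise ValueError("metadata must contain a 'time' or 'pseudotime' column")

    uniq = np.unique(time_labels)
    if len(uniq) < 2:
        raise ValueError("fewer than 2 time points in metadata")

    matrices, cell_ids, branches, weights, pts = [], [], [], [], []
    has_branch = "branch" in meta.columns
    has_weight = "weight" in meta.columns
    for t in uniq:
        sel = np.flatnonzero(time_labels == t)
        matrices.append(values[:, sel])
        cell_ids.append([cells[i] for i in sel])
        if has_branch:
            branches.append(meta["branch"].to_numpy()[sel])
        if has_weight:
            w = meta["weight"].to_numpy(dtype=float)[sel]
            weights.append(w / w.sum())
        if pseudotime is not None:
            pts.append(pseudotime[sel])
    return ExpressionDataset(
        gene_names=[str(g) for g in df.index],
        times=uniq,
        matrices=matrices,
        cell_ids=cell_ids,
        branch_labels=branches if has_branch else None,
        cell_weights=weights if has_weight else None,
        pseudotime=pts if pseudotime is not None else None,
    )


def write_expression(dataset: ExpressionDataset, matrix_path, metadata_path):
    """Write a dataset back to the delimited-text layout read_expression expects."""
    mat = np.concatenate(dataset.matrices, axis=1)
    cols = [c for ids in dataset.cell_ids for c in ids]
    pd.DataFrame(mat, index=dataset.gene_names, columns=cols).to_csv(matrix_path, sep="\t")
    rows = {"cell_id": cols,
            "time": np.concatenate([np.full(n, t) for t, n in zip(dataset.times, dataset.n_cells)])}
    if dataset.branch_labels is not None:
        rows["branch"] = np.concatenate([np.asarray(b) for b in dataset.branch_labels])
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def bin_pseudotime(pseudotime, n_bins: int) -> np.ndarray:
    """Assign quantile-bin labels 0..n_bins-1 to per-cell pseudotimes.

    Cells are sorted and sliced into ``n_bins`` contiguous blocks whose sizes
    differ by at most one; tied pseudotimes spanning a block boundary all go
    to the lower block.
    """
    pt = np.asarray(pseudotime, dtype=float)
    n = pt.size
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > n:
        raise ValueError("n_bins may not exceed the number of cells")
    if np.all(pt == pt[0]):
        raise ValueError("all pseudotimes identical: no temporal signal to bin")
    order = np.argsort(pt, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = (np.arange(n) * n_bins) // n
    # ties share a bin; the lower bin wins at boundaries
    for value in np.unique(pt):
        sel = pt == value
        labels[sel] = labels[sel].min()
    if len(np.unique(labels)) < n_bins:
        raise ValueError("ties leave at least one quantile bin empty; reduce n_bins")
    return labels


def write_edge_list(weights, gene_names, top_fraction, out_path,
                    interval="global", exclude_targets=()) -> pd.DataFrame:
    """Write the top fraction of off-diagonal entries as a ranked edge table.

    Rows are sorted by \\|weight\\| descending (ties broken by regulator then
    target index); entries with zero weight are never emitted.  ``exclude_targets``
    names genes (e.g. an artificial stimulus) that may not appear as targets.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    w = np.asarray(weights, dtype=float)
    m = w.shape[0]
    excl = set(exclude_targets)
    entries = []
    for i in range(m):
        for j in range(m):
            if i == j or gene_names[j] in excl:
                continue
            if w[i, j] != 0:
                entries.append((i, j, w[i, j]))
    entries.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    n_possible = m * m - m
    k = min(len(entries), math.ceil(top_fraction * n_possible))
    rows = [(gene_names[i], gene_names[j], f"{v:.12g}", "+" if v > 0 else "-", interval)
            for i, j, v in entries[:k]]
    df = pd.DataFrame(rows, columns=["regulator", "target", "weight", "sign", "interval"])
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def read_edge_weights(path, gene_names):
    """Rebuild an m x m weight matrix from an edge-list table."""
    df = pd.read_csv(path, sep="\t")
    idx = {g: i for i, g in enumerate(gene_names)}
    w = np.zeros((len(gene_names), len(gene_names)))
    for _, row in df.iterrows():
        if row["regulator"] in idx and row["target"] in idx:
            w[idx[row["regulator"]], idx[row["target"]]] = float(row["weight"])
    return w
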