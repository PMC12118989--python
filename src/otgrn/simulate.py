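"""Synthetic time-stamped single-cell cohorts from a known signed network.

Each cell is an independent Euler-Maruyama path of the logistic-interaction
stochastic differential equation

    dx_g = ( beta_g * sigma( sum_h W[h,g] x_h + b_g + u_g ) - gamma_g * x_g ) dt
           + eta dB_t,        sigma(z) = 1 / (1 + exp(-z)),

clipped at zero (expression cannot go negative).  Observation is destructive:
for every observation time a *fresh* cohort of independent paths is recorded
at that time only, so no cell appears twice -- the sampling structure that
makes trajectory inference via optimal transport necessary.  Cells start at
the basal (stimulus-off) stationary point plus small noise; the optional
stimulus input ``u`` switches on at t = 0 and drives the system out of
equilibrium.  Branching applies branch-specific interaction matrices after
the branch time, with cells assigned to branches by configured proportions.

All randomness derives from a single seed through per-cohort substreams
(``numpy.random.SeedSequence.spawn``), so cohorts are order-independent.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence

import numpy as np

from .io import ExpressionDataset, GroundTruthNetwork


def _sigma(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclasses.dataclass
class BranchSpec:
    """Branch-specific dynamics: variants of W applied after ``time``."""

    time: float
    weight_variants: List[np.ndarray]     # one m x m matrix per branch
    proportions: np.ndarray               # (n_times, n_branches) or (n_branches,)
    names: Optional[list] = None

    def proportions_at(self, time_index: int, n_times: int) -> np.ndarray:
        prop = np.asarray(self.proportions, float)
        if prop.ndim == 1:
            return prop / prop.sum()
        if prop.shape[0] != n_times:
            raise ValueError("proportions must have one row per observation time")
        row = prop[time_index]
        return row / row.sum()


@dataclasses.dataclass
class SimulationConfig:
    weights: np.ndarray                  # W[h, g]: signed effect of gene h on gene g
    basal: np.ndarray                    # b_g
    production: np.ndarray               # beta_g
    degradation: np.ndarray              # gamma_g, > 0
    times: np.ndarray
    cells_per_time: int = 200
    noise_sd: float = 0.3
    init_sd: float = 0.05
    dt: float = 0.05
    stimulus_input: Optional[np.ndarray] = None   # u_g, active from t = 0
    branch: Optional[BranchSpec] = None
    dropout_rate: float = 0.0
    count_model: Optional[tuple] = None  # ("poisson", scale) or None
    gene_names: Optional[list] = None
    seed: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        self.basal = np.asarray(self.basal, float)
        self.production = np.asarray(self.production, float)
        self.degradation = np.asarray(self.degradation, float)
        self.times = np.asarray(self.times, float)
        m = self.weights.shape[0]
        if self.weights.shape != (m, m):
            raise ValueError("weights must be square")
        if np.any(self.degradation <= 0):
            raise ValueError("degradation rates must be > 0")
        spacing = np.diff(self.times)
        if np.any(spacing <= 0):
            raise ValueError("times must be strictly increasing")
        if self.dt > spacing.min() / 10 + 1e-12:
            raise ValueError("dt must be at most one tenth of the smallest time spacing")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.gene_names is None:
            self.gene_names = [f"g{i + 1}" for i in range(m)]

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]


def basal_fixed_point(config: SimulationConfig, n_steps: int = 5000) -> np.ndarray:
    """Deterministic stationary state of the stimulus-off system (Euler relaxation)."""
    m = config.n_genes
    x = np.zeros(m)
    for _ in range(n_steps):
        drift = config.production * _sigma(config.weights.T @ x + config.basal) \
            - config.degradation * x
        x = np.clip(x + config.dt * drift, 0.0, None)
    return x


def _drift(x, W, config):
    z = W.T @ x + config.basal[:, None]
    if config.stimulus_input is not None:
        z = z + config.stimulus_input[:, None]
    return config.production[:, None] * _sigma(z) - config.degradation[:, None] * x


def _integrate_cohort(config: SimulationConfig, t_obs, x0, branch_ids, rng):
    """Euler-Maruyama from 0 to t_obs for one cohort (m x n state matrix)."""
    x = x0.copy()
    n_steps = int(round(t_obs / config.dt))
    branch_sets = []
    if config.branch is not None:
        branch_sets = [branch_ids == b for b in range(len(config.branch.weight_variants))]
    for step in range(n_steps):
        t = step * config.dt
        if config.branch is None or t < config.branch.time:
            dx = _drift(x, config.weights, config) * config.dt
        else:
            dx = np.empty_like(x)
            for b, mask in enumerate(branch_sets):
                if mask.any():
                    dx[:, mask] = _drift(x[:, mask],
                                         config.branch.weight_variants[b],
                                         config) * config.dt
        if config.noise_sd > 0:
            dx = dx + config.noise_sd * np.sqrt(config.dt) \
                * rng.standard_normal(x.shape)
        x = np.clip(x + dx, 0.0, None)
        if np.any(np.abs(x) > 1e6):
            raise RuntimeError("unstable integration (|x| > 1e6); use a smaller dt")
    return x


def ground_truth_from_weights(config: SimulationConfig) -> GroundTruthNetwork:
    """Signed adjacency from the simulation weights (union over branch variants)."""
    adj = np.sign(config.weights).astype(int)
    if config.branch is not None:
        for Wb in config.branch.weight_variants:
            sb = np.sign(np.asarray(Wb)).astype(int)
            adj = np.where(adj == 0, sb, adj)
    np.fill_diagonal(adj, 0)
    return GroundTruthNetwork(gene_names=list(config.gene_names), adjacency=adj)


def simulate_dataset(config: SimulationConfig):
    """Simulate destructive-sampling cohorts; returns (dataset, truth network)."""
    m = config.n_genes
    N = len(config.times)
    fp = basal_fixed_point(config)
    root = np.random.SeedSequence(config.seed)
    cohort_seeds = root.spawn(N + 2)  # last two: count model, dropout
    matrices, cell_ids, branch_labels = [], [], []
    for i, t_obs in enumerate(config.times):
        rng = np.random.default_rng(cohort_seeds[i])
        n = config.cells_per_time
        if config.branch is not None:
            prop = config.branch.proportions_at(i, N)
            bids = rng.choice(len(prop), size=n, p=prop)
        else:
            bids = np.zeros(n, dtype=int)
        x0 = np.clip(fp[:, None] + config.init_sd * rng.standard_normal((m, n)), 0.0, None)
        x = _integrate_cohort(config, float(t_obs), x0, bids, rng)
        matrices.append(x)
        cell_ids.append([f"t{i}_c{j}" for j in range(n)])
        if config.branch is not None:
            names = config.branch.names or [f"branch{b}" for b in
                                            range(len(config.branch.weight_variants))]
            branch_labels.append(np.array([names[b] for b in bids]))
    if config.count_model is not None:
        kind, scale = config.count_model
        if kind != "poisson":
            raise ValueError(f"unknown count model {kind!r}")
        rng = np.random.default_rng(cohort_seeds[N])
        matrices = [rng.poisson(scale * x).astype(float) for x in matrices]
    dataset = ExpressionDataset(
        gene_names=list(config.gene_names),
        times=config.times.copy(),
        matrices=matrices,
        cell_ids=cell_ids,
        branch_labels=branch_labels if config.branch is not None else None,
    )
    if config.dropout_rate > 0:
        ds_seed = int(cohort_seeds[N + 1].generate_state(1)[0] % (2 ** 31))
        dataset = inject_dropout(dataset, config.dropout_rate, seed=ds_seed)
    return dataset, ground_truth_from_weights(config)


def inject_dropout(dataset: ExpressionDataset, rate: float, seed: int = 0) -> ExpressionDataset:
    """Set each entry to 0 independently with probability ``rate`` (reproducible)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mats = [np.where(rng.random(x.shape) < rate, 0.0, x) for x in dataset.matrices]
    return ExpressionDataset(
        gene_names=list(dataset.gene_names), times=dataset.times.copy(),
        matrices=mats, cell_ids=[list(c) for c in dataset.cell_ids],
        branch_labels=dataset.branch_labels, cell_weights=dataset.cell_weights,
        pseudotime=dataset.pseudotime, transformed=dataset.transformed,
    )


def downsample_branches(dataset: ExpressionDataset, schedule: dict,
                        seed: int = 0) -> ExpressionDataset:
    """Remove cells at random within branch x time to hit per-time keep fractions.

    ``schedule`` maps branch name -> keep fraction, either a scalar or one
    fraction per time point; unlisted branches are kept whole.  At least one
    cell per present branch is always retained.
    """
    if dataset.branch_labels is None:
        raise ValueError("downsampling requires branch labels")
    known = set(dataset.branch_names())
    unknown = set(schedule) - known
    if unknown:
        raise ValueError(f"schedule names unknown branch(es): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    N = dataset.n_times
    mats, cids, labs = [], [], []
    for k in range(N):
        lab = np.asarray(dataset.branch_labels[k])
        keep = np.zeros(lab.size, dtype=bool)
        for b in np.unique(lab):
            idx = np.flatnonzero(lab == b)
            frac = schedule.get(b, 1.0)
            if np.ndim(frac) > 0:
                frac = frac[k]
            if not 0 < frac <= 1:
                raise ValueError("keep fractions must lie in (0, 1]")
            n_keep = max(1, int(np.floor(frac * idx.size)))
            chosen = rng.choice(idx, size=n_keep, replace=False)
            keep[chosen] = True
        sel = np.flatnonzero(keep)
        mats.append(dataset.matrices[k][:, sel])
        cids.append([dataset.cell_ids[k][i] for i in sel])
        labs.append(lab[sel])
    return ExpressionDataset(
        gene_names=list(dataset.gene_names), times=dataset.times.copy(),
        matrices=mats, cell_ids=cids, branch_labels=labs,
        transformed=dataset.transformed,
    )


# ---------------------------------------------------------------------------
# canned fixtures
# ---------------------------------------------------------------------------

def _tiny2_config(sign: int, **overrides) -> SimulationConfig:
    W = np.zeros((2, 2))
    W[0, 1] = 4.0 * sign
    base = dict(
        weights=W,
        basal=np.array([-2.0, -3.0 if sign > 0 else 1.0]),
        production=np.full(2, 4.0),
        degradation=np.ones(2),
        times=np.array([0.0, 1.0, 2.0]),
        cells_per_time=30,
        stimulus_input=np.array([4.0, 0.0]),
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _fn4like_config(**overrides) -> SimulationConfig:
    # stimulus -> g1; g1 -> g2 and g1 -> g3 (the branch point); g2 -> g4;
    # g4 -| g1 closes an inhibition feedback loop.
    W = np.zeros((4, 4))
    W[0, 1] = 4.0
    W[0, 2] = 4.0
    W[1, 3] = 4.0
    W[3, 0] = -4.0
    WA, WB = W.copy(), W.copy()
    WA[0, 2] = 0.0  # branch A commits to the g2 arm
    WB[0, 1] = 0.0  # branch B commits to the g3 arm
    base = dict(
        weights=W,
        basal=np.full(4, -2.0),
        production=np.full(4, 4.0),
        degradation=np.ones(4),
        times=np.arange(6, dtype=float),
        cells_per_time=60,
        stimulus_input=np.array([4.0, 0.0, 0.0, 0.0]),
        branch=BranchSpec(time=2.0, weight_variants=[WA, WB],
                          proportions=np.array([0.5, 0.5]),
                          names=["A", "B"]),
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _tree8_config(**overrides) -> SimulationConfig:
    # 9-node tree rooted at the stimulus: stimulus -> g1 -> {g2, g3},
    # g2 -> {g4, g5}, g3 -> {g6, g7 (inhibited)}, g4 -> g8.
    W = np.zeros((8, 8))
    for h, g, w in [(0, 1, 4.0), (0, 2, 4.0), (1, 3, 4.0), (1, 4, 4.0),
                    (2, 5, 4.0), (2, 6, -4.0), (3, 7, 4.0)]:
        W[h, g] = w
    b = np.full(8, -2.0)
    b[6] = 1.0  # the inhibited gene is basally expressed so repression is visible
    base = dict(
        weights=W,
        basal=b,
        production=np.full(8, 4.0),
        degradation=np.ones(8),
        times=np.arange(10, dtype=float),
        cells_per_time=200,
        stimulus_input=np.array([4.0] + [0.0] * 7),
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def fixture_config(name: str, **overrides) -> SimulationConfig:
    """Simulation configuration behind :func:`make_fixture`."""
    if name == "tiny2":
        return _tiny2_config(+1, **overrides)
    if name == "tiny2_inh":
        return _tiny2_config(-1, **overrides)
    if name == "fn4like":
        return _fn4like_config(**overrides)
    if name == "tree8":
        return _tree8_config(**overrides)
    raise ValueError(f"unknown fixture {name!r}; choose from "
                     "tiny2, tiny2_inh, fn4like, tree8")


def make_fixture(name: str, **overrides):
    """Deterministic small benchmark datasets; returns (dataset, truth).

    ``tiny2`` / ``tiny2_inh``: two genes with a planted activating (resp.
    inhibiting) edge g1 -> g2, driven out of equilibrium by a stimulus input
    on g1.  ``fn4like``: four genes with a branching structure and an
    inhibition feedback loop plus stimulus.  ``tree8``: eight genes wired as
    a tree rooted at the stimulus; its ground truth includes the stimulus as
    a ninth node with the 8 tree edges.
    """
    config = fixture_config(name, **overrides)
    dataset, truth = simulate_dataset(config)
    if name == "tree8":
        m = 8
        adj = np.zeros((m + 1, m + 1), dtype=int)
        adj[:m, :m] = truth.adjacency
        adj[m, 0] = 1  # stimulus -> g1
        truth = GroundTruthNetwork(
            gene_names=list(truth.gene_names) + ["stimulus"],
            adjacency=adj, stimulus=m)
    return dataset, truth
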