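"""Entropic fused Gromov-Wasserstein couplings between consecutive cohorts.

The transport plan ``T`` between the cohorts at times t and t~ minimizes

    (1 - alpha) <T, D>_F  +  alpha * sum_{c,d,c~,d~} L(S[c,d], S~[c~,d~]) T[c,c~] T[d,d~]
                          +  epsilon * sum T log T

over the transportation polytope with prescribed marginals (p, q).  ``D``
compares cells across time points in feature space, while the quadratic
Gromov-Wasserstein term compares intra-cohort pairwise (geodesic) distances,
preserving global geometry such as branching.  Entropic regularization makes
the problem strictly convex in each linearization; larger ``epsilon`` yields
more diffuse plans.

The solver iterates linearization of the quadratic term: at each outer step
the GW term is replaced by its first-order expansion around the current plan
(for the squared-difference loss this uses the standard factorization
``const - 2 S T S~^T``), and the resulting entropic OT subproblem is solved by
Sinkhorn scaling, warm-started from the previous potentials.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional

import numpy as np
from scipy.special import logsumexp

from .preprocess import CostInputs


@dataclasses.dataclass
class SolverReport:
    n_outer: int
    converged: bool
    objective: float            # fused objective without the entropic term
    objective_entropic: float   # including epsilon * sum T log T
    marginal_violation: float
    objective_trace: list


@dataclasses.dataclass
class CouplingSequence:
    """Consecutive-pair transport plans T^{t_k, t_{k+1}} with their marginals."""

    couplings: List[np.ndarray]
    marginals: List[tuple]
    reports: List[SolverReport]

    def __len__(self):
        return len(self.couplings)

    def max_marginal_violation(self) -> float:
        out = 0.0
        for T, (p, q) in zip(self.couplings, self.marginals):
            out = max(out,
                      np.abs(T.sum(axis=1) - p).max(),
                      np.abs(T.sum(axis=0) - q).max())
        return out


# ---------------------------------------------------------------------------
# Sinkhorn
# ---------------------------------------------------------------------------

def sinkhorn(C, p, q, epsilon, max_iter=1000, tol=1e-9, log_domain=None, warm=None):
    """Entropic OT: minimize <T, C> + epsilon * sum T log T over Pi(p, q).

    Returns ``(T, (f, g))`` where (f, g) are the dual potentials (log domain),
    reusable for warm starts.  Falls back to log-domain iterations on
    numerical underflow at small epsilon.
    """
    C = np.asarray(C, float)
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if log_domain is None:
        log_domain = epsilon < 5e-3
    if not log_domain:
        out = _sinkhorn_standard(C, p, q, epsilon, max_iter, tol, warm)
        if out is not None:
            return out
        # underflow: automatic log-domain fallback
    return _sinkhorn_log(C, p, q, epsilon, max_iter, tol, warm)


def _sinkhorn_standard(C, p, q, epsilon, max_iter, tol, warm):
    K = np.exp(-C / epsilon)
    if warm is not None:
        u = np.exp(warm[0] / epsilon)
        v = np.exp(warm[1] / epsilon)
    else:
        u = np.ones_like(p)
        v = np.ones_like(q)
    for it in range(max_iter):
        Kv = K @ v
        if np.any(Kv == 0) or not np.all(np.isfinite(Kv)):
            return None
        u = p / Kv
        Ktu = K.T @ u
        if np.any(Ktu == 0) or not np.all(np.isfinite(Ktu)):
            return None
        v = q / Ktu
        if it % 10 == 0 or it == max_iter - 1:
            T = (u[:, None] * K) * v[None, :]
            if max(np.abs(T.sum(1) - p).max(), np.abs(T.sum(0) - q).max()) < tol:
                break
    T = (u[:, None] * K) * v[None, :]
    if not np.all(np.isfinite(T)):
        return None
    with np.errstate(divide="ignore"):
        f = epsilon * np.log(u)
        g = epsilon * np.log(v)
    return T, (f, g)


def _sinkhorn_log(C, p, q, epsilon, max_iter, tol, warm):
    logp, logq = np.log(p), np.log(q)
    if warm is not None:
        f, g = warm[0].copy(), warm[1].copy()
    else:
        f = np.zeros_like(p)
        g = np.zeros_like(q)
    Ce = C / epsilon
    for it in range(max_iter):
        f = epsilon * (logp - logsumexp(-Ce + g[None, :] / epsilon, axis=1))
        g = epsilon * (logq - logsumexp(-Ce + f[:, None] / epsilon, axis=0))
        if it % 10 == 0 or it == max_iter - 1:
            T = np.exp(-Ce + (f[:, None] + g[None, :]) / epsilon)
            if max(np.abs(T.sum(1) - p).max(), np.abs(T.sum(0) - q).max()) < tol:
                break
    T = np.exp(-Ce + (f[:, None] + g[None, :]) / epsilon)
    return T, (f, g)


# ---------------------------------------------------------------------------
# fused GW
# ---------------------------------------------------------------------------

def _gw_linearization(S1, S2, T, loss):
    """Matrix M with M[c,c~] = sum_{d,d~} L(S1[c,d], S2[c~,d~]) T[d,d~]."""
    if loss == "square":
        r = T.sum(axis=1)
        s = T.sum(axis=0)
        A = (S1 ** 2) @ r
        B = (S2 ** 2) @ s
        return A[:, None] + B[None, :] - 2.0 * (S1 @ T @ S2.T)
    if loss == "abs":
        n1, n2 = T.shape
        if max(n1, n2) > 200:
            raise ValueError("absolute-value GW loss uses a direct tensor "
                             "contraction and is limited to cohorts of <= 200 cells")
        M = np.empty((n1, n2))
        for c in range(n1):
            # diff[d, c~, d~] = |S1[c, d] - S2[c~, d~]|
            diff = np.abs(S1[c][:, None, None] - S2[None, :, :])
            M[c] = np.einsum("dce,de->c", diff, T)
        return M
    raise ValueError(f"unknown GW loss {loss!r}")


def fgw_objective(T, cost: CostInputs, alpha, loss="square"):
    """Fused objective (1-alpha)<T,D> + alpha * GW(T), without the entropic term."""
    lin = _gw_linearization(cost.S_source, cost.S_target, T, loss)
    return (1 - alpha) * float(np.sum(T * cost.D)) + alpha * float(np.sum(T * lin))


def _entropy_term(T, epsilon):
    Tpos = T[T > 0]
    return epsilon * float(np.sum(Tpos * np.log(Tpos)))


def _solve_linearized(cost, alpha, epsilon, T0, max_outer, outer_tol,
                      sinkhorn_max_iter, sinkhorn_tol, gw_loss,
                      anneal_from=0.1, n_anneal=10):
    """One run of the iterated-linearization loop from a given initial plan.

    The entropic coefficient is annealed geometrically from ``anneal_from``
    down to the target ``epsilon`` over the first iterations (a deterministic
    continuation that avoids the poorest stationary points of the quadratic
    term); convergence is judged at the target coefficient only.
    """
    p, q = cost.p, cost.q
    T = T0
    warm = None
    trace = []
    best = None
    prev_obj = None
    converged = False
    schedule = (list(np.geomspace(anneal_from, epsilon, n_anneal))
                if epsilon < anneal_from else [])
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        eps_k = schedule[n_outer - 1] if n_outer <= len(schedule) else epsilon
        M = (1 - alpha) * cost.D + alpha * _gw_linearization(
            cost.S_source, cost.S_target, T, gw_loss)
        T, warm = sinkhorn(M, p, q, eps_k, sinkhorn_max_iter, sinkhorn_tol, warm=warm)
        obj_plain = fgw_objective(T, cost, alpha, gw_loss)
        obj = obj_plain + _entropy_term(T, epsilon)
        trace.append(obj_plain)
        at_target = n_outer > len(schedule)
        if at_target and (best is None or obj < best[0]):
            best = (obj, obj_plain, T)
        if at_target and prev_obj is not None:
            denom = max(abs(prev_obj), 1e-16)
            if abs(prev_obj - obj) / denom < outer_tol:
                converged = True
                break
        if at_target:
            prev_obj = obj
    if best is None:
        best = (obj, obj_plain, T)
    return best, converged, n_outer, trace


def solve_entropic_fgw(cost: CostInputs, alpha=0.5, epsilon=0.01,
                       max_outer=50, outer_tol=1e-7,
                       sinkhorn_max_iter=1000, sinkhorn_tol=1e-9,
                       gw_loss="square", n_restarts=None):
    """Solve the entropic fused-GW problem; returns ``(T, SolverReport)``.

    Deterministic given its inputs.  At ``alpha = 0`` the problem is plain
    entropic OT (strictly convex) and is solved by a single Sinkhorn run.
    Otherwise the iterated-linearization loop starts from the independent
    coupling p q^T and -- on small problems, where the quadratic term's
    landscape has the most spurious stationary points and extra solves are
    cheap -- from ``n_restarts`` additional fixed-seed feasible plans; the
    best final objective wins.  The returned plan's marginal violation is
    polished below 1e-6 if necessary.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    p, q = cost.p, cost.q
    if alpha == 0:
        T, warm = sinkhorn(cost.D, p, q, epsilon, sinkhorn_max_iter, sinkhorn_tol)
        obj_plain = fgw_objective(T, cost, alpha, gw_loss)
        obj = obj_plain + _entropy_term(T, epsilon)
        converged, n_outer, trace = True, 1, [obj_plain]
    else:
        if n_restarts is None:
            n_restarts = 3 if max(len(p), len(q)) <= 64 else 0
        inits = [np.outer(p, q)]
        for s in range(n_restarts):
            M0 = np.random.default_rng(s).random((len(p), len(q)))
            T0, _ = sinkhorn(M0, p, q, 0.3, 500, sinkhorn_tol)
            inits.append(T0)
        best = None
        converged = False
        n_outer = 0
        trace = None
        for T0 in inits:
            cand, conv, nout, tr = _solve_linearized(
                cost, alpha, epsilon, T0, max_outer, outer_tol,
                sinkhorn_max_iter, sinkhorn_tol, gw_loss)
            n_outer += nout
            if best is None or cand[0] < best[0]:
                best = cand
                converged = conv
                trace = tr
        obj, obj_plain, T = best
    viol = max(np.abs(T.sum(1) - p).max(), np.abs(T.sum(0) - q).max())
    if viol > 1e-6:
        # polish feasibility on the final linearized cost
        M = (1 - alpha) * cost.D + alpha * _gw_linearization(
            cost.S_source, cost.S_target, T, gw_loss)
        T, _ = sinkhorn(M, p, q, epsilon, 10 * sinkhorn_max_iter, 1e-9,
                        log_domain=True)
        viol = max(np.abs(T.sum(1) - p).max(), np.abs(T.sum(0) - q).max())
        obj_plain = fgw_objective(T, cost, alpha, gw_loss)
        obj = obj_plain + _entropy_term(T, epsilon)
    if not converged:
        warnings.warn("fused-GW outer loop did not converge; returning best iterate")
    report = SolverReport(n_outer=n_outer, converged=converged,
                          objective=obj_plain, objective_entropic=obj,
                          marginal_violation=float(viol), objective_trace=trace)
    return T, report


def solve_coupling_sequence(cost_inputs: List[CostInputs], alpha=0.5, epsilon=0.01,
                            gw_loss="square", **kwargs) -> CouplingSequence:
    couplings, marginals, reports = [], [], []
    for ci in cost_inputs:
        T, rep = solve_entropic_fgw(ci, alpha=alpha, epsilon=epsilon,
                                    gw_loss=gw_loss, **kwargs)
        couplings.append(T)
        marginals.append((ci.p, ci.q))
        reports.append(rep)
    return CouplingSequence(couplings=couplings, marginals=marginals, reports=reports)


# ---------------------------------------------------------------------------
# composition and projection
# ---------------------------------------------------------------------------

def compose_couplings(couplings: List[np.ndarray]) -> np.ndarray:
    """Compose consecutive plans into a joint plan across a longer lag.

    With one plan the input is returned unchanged.  Otherwise each plan after
    the first is turned into a Markov kernel (rows normalized to sum 1; a zero
    row is replaced by the plan's target marginal, with a warning) and the
    chain ``diag(p) K_1 K_2 ...`` is accumulated.
    """
    if len(couplings) == 0:
        raise ValueError("no couplings to compose")
    out = couplings[0]
    for T in couplings[1:]:
        rows = T.sum(axis=1)
        qmass = T.sum(axis=0)
        K = np.empty_like(T)
        zero = rows == 0
        if np.any(zero):
            warnings.warn(f"{int(zero.sum())} cells have no descendants; their "
                          "transition rows teleport to the target marginal")
            K[zero] = qmass / qmass.sum()
        K[~zero] = T[~zero] / rows[~zero, None]
        out = out @ K
    return out


def save_couplings(seq: CouplingSequence, out_dir, times=None):
    """Dump each plan as a dense TSV plus a JSON manifest of time pairs/marginals."""
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, (T, (p, q)) in enumerate(zip(seq.couplings, seq.marginals)):
        name = f"coupling_{k}.tsv"
        np.savetxt(out / name, T, delimiter="\t", fmt="%.12g")
        entry = {"file": name, "shape": list(T.shape),
                 "p": [float(v) for v in p], "q": [float(v) for v in q]}
        if times is not None:
            entry["times"] = [float(times[k]), float(times[k + 1])]
        manifest.append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_couplings(in_dir) -> CouplingSequence:
    """Inverse of :func:`save_couplings`."""
    import json
    from pathlib import Path
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    couplings, marginals, reports = [], [], []
    for entry in manifest:
        T = np.loadtxt(src / entry["file"], delimiter="\t", ndmin=2)
        couplings.append(T)
        marginals.append((np.asarray(entry["p"]), np.asarray(entry["q"])))
        reports.append(SolverReport(0, True, float("nan"), float("nan"),
                                    float(max(np.abs(T.sum(1) - entry["p"]).max(),
                                              np.abs(T.sum(0) - entry["q"]).max())),
                                    []))
    return CouplingSequence(couplings=couplings, marginals=marginals, reports=reports)


def barycentric_project(T: np.ndarray, X_target: np.ndarray) -> np.ndarray:
    """Predict each source cell's state as the row-normalized T-average of target cells.

    ``T`` is n_source x n_target, ``X_target`` is m x n_target; returns an
    m x n_source matrix.  Applying the same function to ``T.T`` and the source
    expression gives ancestor predictions.
    """
    rows = T.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("coupling has a zero row; repair it with compose_couplings first")
    W = T / rows[:, None]
    return X_target @ W.T
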