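import itertools

import numpy as np
import pytest

from otgrn import (CostInputs, barycentric_project, compose_couplings,
                   sinkhorn, solve_entropic_fgw)
from otgrn.coupling import fgw_objective

from conftest import feasible_coupling


def _cost(D=None, S1=None, S2=None, n1=3, n2=3):
    if D is None:
        D = np.zeros((n1, n2))
    n1, n2 = D.shape
    if S1 is None:
        S1 = np.zeros((n1, n1))
    if S2 is None:
        S2 = np.zeros((n2, n2))
    return CostInputs(D=D, S_source=S1, S_target=S2,
                      p=np.full(n1, 1 / n1), q=np.full(n2, 1 / n2),
                      k_neighbors=1)


def _random_structure(rng, n):
    pts = rng.random((n, 2))
    S = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return S / S.max()


def _lp_optimum(D, n):
    """Exact OT optimum with uniform marginals by permutation enumeration."""
    best = np.inf
    for perm in itertools.permutations(range(n)):
        best = min(best, sum(D[i, perm[i]] for i in range(n)) / n)
    return best


class TestSinkhornSolver:
    def test_constant_cost_gives_independent_coupling(self):
        cost = _cost(D=np.full((4, 3), 0.7), n1=4, n2=3)
        T, rep = solve_entropic_fgw(cost, alpha=0.0, epsilon=0.05)
        np.testing.assert_allclose(T, np.outer(cost.p, cost.q), atol=1e-8)

    @pytest.mark.parametrize("n", [3, 4])
    def test_near_exact_lp_optimum_at_small_epsilon(self, rng, n):
        for _ in range(5):
            D = rng.random((n, n))
            cost = _cost(D=D)
            T, _ = solve_entropic_fgw(cost, alpha=0.0, epsilon=1e-3)
            ent_cost = float(np.sum(T * D))
            opt = _lp_optimum(D, n)
            assert ent_cost <= 1.01 * opt + 1e-12
            # tiny marginal slack can put the cost a hair below the LP optimum
            assert ent_cost >= opt - 1e-4

    def test_alpha0_matches_pure_entropic_ot(self, rng):
        D = rng.random((5, 4))
        cost = _cost(D=D, n1=5, n2=4)
        cost = CostInputs(D=D, S_source=_random_structure(rng, 5),
                          S_target=_random_structure(rng, 4),
                          p=cost.p, q=cost.q, k_neighbors=1)
        T, _ = solve_entropic_fgw(cost, alpha=0.0, epsilon=0.02)
        T_ref, _ = sinkhorn(D, cost.p, cost.q, 0.02, max_iter=5000, tol=1e-12)
        np.testing.assert_allclose(T, T_ref, atol=1e-8)

    def test_pure_gw_close_to_permutation_oracle(self, rng):
        n = 4
        for _ in range(5):
            cost = _cost(D=np.zeros((n, n)),
                         S1=_random_structure(rng, n), S2=_random_structure(rng, n))
            T, _ = solve_entropic_fgw(cost, alpha=1.0, epsilon=1e-3)
            # brute-force best permutation plan under the GW objective
            best = np.inf
            for pm in itertools.permutations(range(n)):
                P = np.zeros((n, n))
                P[range(n), pm] = 1 / n
                best = min(best, fgw_objective(P, cost, alpha=1.0))
            assert fgw_objective(T, cost, alpha=1.0) <= 1.05 * best + 1e-9

    def test_pure_gw_recovers_structure_preserving_matching(self, rng):
        # target structure is an exact relabeling of the source: the plan
        # should concentrate on that permutation as epsilon gets small
        n = 4
        S = _random_structure(rng, n)
        perm = np.array([2, 0, 3, 1])
        S2 = S[np.ix_(perm, perm)]
        cost = _cost(D=np.zeros((n, n)), S1=S, S2=S2)
        T, _ = solve_entropic_fgw(cost, alpha=1.0, epsilon=1e-3)
        # S2[c~, d~] = S[perm[c~], perm[d~]]: source cell perm[j] matches target j
        inv = np.argsort(perm)
        np.testing.assert_array_equal(np.argmax(T, axis=1), inv)
        assert T[range(n), inv].min() > 0.9 / n

    def test_marginal_feasibility(self, rng):
        for n1, n2 in [(4, 6), (7, 3)]:
            cost = CostInputs(D=rng.random((n1, n2)),
                              S_source=_random_structure(rng, n1),
                              S_target=_random_structure(rng, n2),
                              p=np.full(n1, 1 / n1), q=np.full(n2, 1 / n2),
                              k_neighbors=1)
            T, rep = solve_entropic_fgw(cost, alpha=0.5, epsilon=0.01)
            assert np.abs(T.sum(1) - cost.p).max() <= 1e-6
            assert np.abs(T.sum(0) - cost.q).max() <= 1e-6
            assert rep.marginal_violation <= 1e-6
            assert np.all(T >= 0)
            assert np.isclose(T.sum(), 1.0)

    def test_entropy_nondecreasing_in_epsilon(self, rng):
        cost = CostInputs(D=rng.random((5, 5)),
                          S_source=_random_structure(rng, 5),
                          S_target=_random_structure(rng, 5),
                          p=np.full(5, 0.2), q=np.full(5, 0.2), k_neighbors=1)

        def entropy(T):
            Tp = T[T > 0]
            return -np.sum(Tp * np.log(Tp))

        ents = []
        for eps in (1e-3, 1e-2, 1e-1):
            T, _ = solve_entropic_fgw(cost, alpha=0.5, epsilon=eps)
            ents.append(entropy(T))
        assert ents[0] <= ents[1] + 1e-9 <= ents[2] + 2e-9

    def test_objective_nonincreasing_over_outer_iterations(self, rng):
        cost = CostInputs(D=rng.random((6, 6)),
                          S_source=_random_structure(rng, 6),
                          S_target=_random_structure(rng, 6),
                          p=np.full(6, 1 / 6), q=np.full(6, 1 / 6), k_neighbors=1)
        _, rep = solve_entropic_fgw(cost, alpha=0.5, epsilon=0.01)
        trace = np.array(rep.objective_trace)
        assert np.all(np.diff(trace) <= 1e-6 * (1 + np.abs(trace[:-1])))

    def test_alpha_continuity_on_small_instance(self, rng):
        cost = CostInputs(D=rng.random((4, 4)),
                          S_source=_random_structure(rng, 4),
                          S_target=_random_structure(rng, 4),
                          p=np.full(4, 0.25), q=np.full(4, 0.25), k_neighbors=1)
        T_mid, _ = solve_entropic_fgw(cost, alpha=0.5, epsilon=0.05)
        for da in (-0.01, 0.01):
            T_near, _ = solve_entropic_fgw(cost, alpha=0.5 + da, epsilon=0.05)
            assert np.abs(T_near - T_mid).max() < 0.05

    def test_log_domain_fallback_at_tiny_epsilon(self, rng):
        D = rng.random((3, 3))
        T, _ = sinkhorn(D, np.full(3, 1 / 3), np.full(3, 1 / 3), 1e-4,
                        max_iter=20000)
        assert np.all(np.isfinite(T))
        assert np.abs(T.sum(1) - 1 / 3).max() < 1e-6

    def test_invalid_parameters_rejected(self):
        cost = _cost(D=np.zeros((2, 2)), n1=2, n2=2)
        with pytest.raises(ValueError):
            solve_entropic_fgw(cost, alpha=1.5)
        with pytest.raises(ValueError):
            solve_entropic_fgw(cost, epsilon=0.0)


class TestComposeCouplings:
    def test_single_coupling_returned_unchanged(self, rng):
        T = feasible_coupling(rng, 3, 4)
        assert compose_couplings([T]) is T

    def test_identity_kernel_preserves_coupling(self, rng):
        T = feasible_coupling(rng, 4, 4)
        ident = np.diag(T.sum(axis=1))  # diag(p): the identity Markov kernel
        np.testing.assert_allclose(compose_couplings([T, ident]), T, atol=1e-12)

    def test_uniform_independent_couplings_compose_to_uniform(self):
        U = np.full((2, 2), 0.25)
        np.testing.assert_allclose(compose_couplings([U, U]), U, atol=1e-15)

    def test_matches_chain_rule_oracle(self, rng):
        Ts = [feasible_coupling(rng, 4, 4) for _ in range(3)]
        got = compose_couplings(Ts)
        # explicit sum over intermediate cells: P(c0, c3)
        n = 4
        expected = np.zeros((n, n))
        p0 = Ts[0].sum(axis=1)
        K = [T / T.sum(axis=1, keepdims=True) for T in Ts]
        for c0 in range(n):
            for c1 in range(n):
                for c2 in range(n):
                    for c3 in range(n):
                        expected[c0, c3] += p0[c0] * K[0][c0, c1] * K[1][c1, c2] * K[2][c2, c3]
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert np.isclose(got.sum(), 1.0)
        np.testing.assert_allclose(got.sum(axis=1), p0, atol=1e-12)

    def test_zero_row_teleports_with_warning(self):
        T1 = np.full((2, 2), 0.25)
        T2 = np.array([[0.0, 0.0], [0.3, 0.7]]) / 1.0
        with pytest.warns(UserWarning, match="descendants"):
            out = compose_couplings([T1, T2])
        assert np.isclose(out.sum(), 1.0)


class TestBarycentricProjection:
    def test_hard_assignment_copies_matched_cell(self):
        T = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.0]])
        X = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
        out = barycentric_project(T, X)
        np.testing.assert_allclose(out, [[2.0, 1.0], [20.0, 10.0]])

    def test_uniform_coupling_predicts_target_mean(self, rng):
        X = rng.random((3, 5))
        T = np.full((4, 5), 1 / 20)
        out = barycentric_project(T, X)
        for c in range(4):
            np.testing.assert_allclose(out[:, c], X.mean(axis=1), atol=1e-12)

    def test_matches_weighted_average_loop(self, rng):
        T = feasible_coupling(rng, 3, 4)
        X = rng.random((2, 4))
        out = barycentric_project(T, X)
        for c in range(3):
            w = T[c] / T[c].sum()
            expected = sum(w[j] * X[:, j] for j in range(4))
            np.testing.assert_allclose(out[:, c], expected, atol=1e-12)

    def test_stays_in_convex_hull(self, rng):
        T = feasible_coupling(rng, 6, 5)
        X = rng.standard_normal((4, 5))
        out = barycentric_project(T, X)
        lo = X.min(axis=1, keepdims=True) - 1e-12
        hi = X.max(axis=1, keepdims=True) + 1e-12
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_zero_row_rejected(self):
        T = np.array([[0.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="zero row"):
            barycentric_project(T, np.ones((2, 2)))
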