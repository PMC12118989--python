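import numpy as np
import pytest

from otgrn import (CostInputs, ExpressionDataset, add_stimulus_gene,
                   compute_velocities, normalize_velocities, project_velocity,
                   solve_entropic_fgw)
from otgrn.coupling import CouplingSequence, SolverReport
from otgrn.velocity import STIMULUS_GENE

from conftest import feasible_coupling


def _seq(couplings):
    margs = [(T.sum(axis=1), T.sum(axis=0)) for T in couplings]
    reps = [SolverReport(1, True, 0.0, 0.0, 0.0, []) for _ in couplings]
    return CouplingSequence(couplings=list(couplings), marginals=margs, reports=reps)


def _dataset(times, mats):
    return ExpressionDataset(
        gene_names=[f"g{i}" for i in range(mats[0].shape[0])],
        times=np.asarray(times, float), matrices=mats,
        cell_ids=[[f"t{k}c{j}" for j in range(x.shape[1])]
                  for k, x in enumerate(mats)],
        transformed=True,
    )


class TestFiniteDifferences:
    def test_stationary_data_gives_zero_velocity(self, rng):
        X = rng.random((3, 4))
        eye = np.eye(4) / 4
        ds = _dataset([0.0, 1.0, 2.0], [X, X, X])
        field = compute_velocities(ds, _seq([eye, eye]))
        for v in field.velocities:
            np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_equal_spacing_centered_is_mean_of_forward_backward(self, rng):
        mats = [rng.random((2, 3)) for _ in range(3)]
        Ts = [feasible_coupling(rng, 3, 3) for _ in range(2)]
        ds = _dataset([0.0, 1.0, 2.0], mats)
        field = compute_velocities(ds, _seq(Ts))
        # manual forward and backward at the middle time point
        from otgrn import barycentric_project
        v_f = barycentric_project(Ts[1], mats[2]) - mats[1]
        v_b = mats[1] - barycentric_project(Ts[0].T, mats[0])
        np.testing.assert_allclose(field.velocities[1], (v_f + v_b) / 2, atol=1e-12)

    def test_nonuniform_spacing_weights(self, rng):
        # times (0, 1, 3): centered = 1/3 forward + 2/3 backward
        mats = [rng.random((2, 3)) for _ in range(3)]
        Ts = [feasible_coupling(rng, 3, 3) for _ in range(2)]
        ds = _dataset([0.0, 1.0, 3.0], mats)
        field = compute_velocities(ds, _seq(Ts))
        from otgrn import barycentric_project
        v_f = (barycentric_project(Ts[1], mats[2]) - mats[1]) / 2.0
        v_b = (mats[1] - barycentric_project(Ts[0].T, mats[0])) / 1.0
        np.testing.assert_allclose(field.velocities[1],
                                   v_f / 3 + 2 * v_b / 3, atol=1e-12)

    def test_two_time_points_forward_then_backward(self, rng):
        mats = [rng.random((2, 3)), rng.random((2, 4))]
        T = feasible_coupling(rng, 3, 4)
        ds = _dataset([0.0, 2.0], mats)
        field = compute_velocities(ds, _seq([T]))
        from otgrn import barycentric_project
        np.testing.assert_allclose(
            field.velocities[0], (barycentric_project(T, mats[1]) - mats[0]) / 2)
        np.testing.assert_allclose(
            field.velocities[1], (mats[1] - barycentric_project(T.T, mats[0])) / 2)

    def test_linearity_in_expression(self, rng):
        mats = [rng.random((2, 3)) for _ in range(3)]
        Ts = [feasible_coupling(rng, 3, 3) for _ in range(2)]
        f1 = compute_velocities(_dataset([0, 1, 2], mats), _seq(Ts))
        f2 = compute_velocities(_dataset([0, 1, 2], [2 * x for x in mats]), _seq(Ts))
        for a, b in zip(f1.velocities, f2.velocities):
            np.testing.assert_allclose(2 * a, b, atol=1e-12)

    def test_translation_recovers_shift(self, rng):
        # a cloud and its copy shifted by delta, coupled at small epsilon
        delta = np.array([1.0, -2.0, 0.5])
        X0 = rng.standard_normal((3, 40)) * 0.3 + 5.0
        X1 = X0 + delta[:, None]
        from otgrn import inter_cost_matrix, intra_structure_matrix
        cost = CostInputs(
            D=inter_cost_matrix(X0, X1),
            S_source=intra_structure_matrix(X0, 5),
            S_target=intra_structure_matrix(X1, 5),
            p=np.full(40, 1 / 40), q=np.full(40, 1 / 40), k_neighbors=5)
        T, _ = solve_entropic_fgw(cost, alpha=0.0, epsilon=1e-3)
        ds = _dataset([0.0, 1.0], [X0 - X0.min() + 1, X1 - X0.min() + 1])
        field = compute_velocities(ds, _seq([T]))
        mean_v = field.velocities[0].mean(axis=1)
        np.testing.assert_allclose(mean_v, delta, atol=0.05 * np.linalg.norm(delta))


class TestProjectVelocity:
    def test_hard_assignment_copies_source_velocity(self):
        T = np.array([[0.5, 0.0], [0.0, 0.5]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(project_velocity(T, V), V)

    def test_uniform_coupling_gives_mean_velocity(self, rng):
        V = rng.random((2, 3))
        T = np.full((3, 5), 1 / 15)
        out = project_velocity(T, V)
        for c in range(5):
            np.testing.assert_allclose(out[:, c], V.mean(axis=1), atol=1e-12)

    def test_matches_column_weighted_loop(self, rng):
        T = feasible_coupling(rng, 3, 5)
        V = rng.random((2, 3))
        out = project_velocity(T, V)
        for c in range(5):
            w = T[:, c] / T[:, c].sum()
            np.testing.assert_allclose(out[:, c], V @ w, atol=1e-12)

    def test_zero_column_rejected(self):
        T = np.array([[0.5, 0.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="zero column"):
            project_velocity(T, np.ones((2, 2)))


class TestNormalization:
    def _field(self, rng, n_times=3, m=3, n=4):
        mats = [rng.random((m, n)) for _ in range(n_times)]
        Ts = [feasible_coupling(rng, n, n) for _ in range(n_times - 1)]
        return compute_velocities(_dataset(range(n_times), mats), _seq(Ts))

    def test_two_point_population_sd(self):
        # pooled velocities (-2, 2): population SD 2, normalized to (-1, 1)
        from otgrn import VelocityField
        field = VelocityField(gene_names=["g0"], times=np.array([0.0, 1.0]),
                              velocities=[np.array([[-2.0]]), np.array([[2.0]])],
                              projected=[np.array([[0.0]])])
        out = normalize_velocities(field)
        np.testing.assert_allclose(out.velocities[0], [[-1.0]])
        np.testing.assert_allclose(out.velocities[1], [[1.0]])
        assert np.isclose(out.gene_sds[0], 2.0)

    def test_zero_sd_gene_untouched_and_flagged(self, rng):
        field = self._field(rng)
        for v in field.velocities:
            v[1, :] = 0.0
        for v in field.projected:
            v[1, :] = 0.0
        out = normalize_velocities(field)
        assert out.zero_sd_genes == ["g1"]
        for v in out.velocities:
            np.testing.assert_array_equal(v[1], 0.0)

    def test_pooled_sd_is_one(self, rng):
        out = normalize_velocities(self._field(rng))
        pooled = np.concatenate(out.velocities, axis=1)
        np.testing.assert_allclose(pooled.std(axis=1), 1.0, atol=1e-12)
        assert out.normalized

    def test_projected_share_gene_scales(self, rng):
        field = self._field(rng)
        out = normalize_velocities(field)
        scale = field.projected[0] / out.projected[0]
        np.testing.assert_allclose(scale, out.gene_sds[:, None] * np.ones_like(scale),
                                   atol=1e-10)

    def test_double_normalization_rejected(self, rng):
        with pytest.raises(ValueError):
            normalize_velocities(normalize_velocities(self._field(rng)))


class TestStimulusGene:
    def test_unit_velocity_at_stimulus_time_only(self, rng):
        mats = [rng.random((2, 3)) for _ in range(3)]
        Ts = [feasible_coupling(rng, 3, 3) for _ in range(2)]
        field = compute_velocities(_dataset([0, 1, 2], mats), _seq(Ts))
        field = normalize_velocities(field)
        out = add_stimulus_gene(field, 0)
        assert out.gene_names[-1] == STIMULUS_GENE
        np.testing.assert_array_equal(out.velocities[0][-1], 1.0)
        np.testing.assert_array_equal(out.velocities[1][-1], 0.0)
        np.testing.assert_array_equal(out.velocities[2][-1], 0.0)
        # projection of a constant is exact
        np.testing.assert_array_equal(out.projected[0][-1], 1.0)
        np.testing.assert_array_equal(out.projected[1][-1], 0.0)

    def test_stimulus_survives_normalization_with_unit_magnitude(self, rng):
        mats = [rng.random((2, 3)) for _ in range(3)]
        Ts = [feasible_coupling(rng, 3, 3) for _ in range(2)]
        field = add_stimulus_gene(
            compute_velocities(_dataset([0, 1, 2], mats), _seq(Ts)), 1)
        out = normalize_velocities(field)
        np.testing.assert_array_equal(out.velocities[1][-1], 1.0)

    def test_double_stimulus_rejected(self, rng):
        mats = [rng.random((2, 3)) for _ in range(2)]
        field = compute_velocities(_dataset([0, 1], mats),
                                   _seq([feasible_coupling(rng, 3, 3)]))
        out = add_stimulus_gene(field, 0)
        with pytest.raises(ValueError):
            add_stimulus_gene(out, 1)
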