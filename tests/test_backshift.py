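"""Shift-intervention estimation: oracle recovery, ambiguity resolution,
diagnostics, stability selection."""

import numpy as np
import pytest

import cytocausal as cc
from cytocausal.backshift import (
    EnvironmentSet,
    JointDiagonalizationError,
    ModelViolationError,
    StabilityConfig,
    diagnose_model,
    environment_covariances,
    estimate_backshift,
    joint_diagonalize,
    keep_count,
    resolve_scale_permutation,
    stability_select,
    _covariance_differences,
)


def _env_tables(model, variance_sets, n, seed):
    rng = np.random.default_rng(seed)
    return [
        cc.simulate_condition(model, intervention_variances=np.asarray(v, float),
                              n=n, seed=rng)
        for v in variance_sets
    ]


THREE_ENVS = [np.zeros(3), np.array([2.0, 0.5, 1.0]), np.array([0.5, 3.0, 0.7])]


class TestEnvironmentCovariances:
    def test_identity_covariance_recovered(self):
        m = cc.CausalModel(np.zeros((3, 3)), np.eye(3), np.zeros(3), ("a", "b", "c"))
        env = environment_covariances(_env_tables(m, [np.zeros(3)] * 3, 10_000, 0))
        assert np.abs(env.covariances[0] - np.eye(3)).max() < 0.1

    def test_too_small_table_rejected(self, acyclic3_model):
        tables = _env_tables(acyclic3_model, THREE_ENVS, 3, 0)  # n == p
        with pytest.raises(ValueError, match="rank-deficient"):
            environment_covariances(tables)

    def test_constant_marker_named(self, acyclic3_model):
        tables = _env_tables(acyclic3_model, THREE_ENVS, 50, 0)
        tables[1].values[:, 2] = 7.0
        with pytest.raises(ValueError, match="z"):
            environment_covariances(tables)

    def test_two_environments_rejected(self):
        with pytest.raises(ValueError, match="three environments"):
            EnvironmentSet((np.eye(2),) * 2, (10, 10), ("a", "b"))


class TestJointDiagonalize:
    def test_already_diagonal_returns_identity(self):
        diffs = [np.diag([1.0, -2.0, 0.5]), np.diag([-0.3, 1.0, 2.0])]
        W, res = joint_diagonalize(diffs)
        assert res == pytest.approx(0.0, abs=1e-12)
        # identity up to row scaling
        assert np.abs(W - np.diag(np.diag(W))).max() < 1e-10

    def test_population_recovery_acyclic(self, acyclic3_model):
        covs = tuple(acyclic3_model.population_covariance(np.asarray(v)) for v in THREE_ENVS)
        W, res = joint_diagonalize(_covariance_differences(covs))
        B_hat = resolve_scale_permutation(W)
        assert res < 1e-10
        assert np.abs(B_hat - acyclic3_model.B).max() < 1e-6

    def test_population_recovery_cyclic(self):
        B = np.array([[0.0, 0.4], [0.3, 0.0]])
        m = cc.CausalModel(B, np.eye(2), np.zeros(2), ("x", "y"))
        vsets = [np.zeros(2), [1.5, 0.2], [0.3, 2.0], [2.5, 1.0]]
        covs = tuple(m.population_covariance(np.asarray(v, float)) for v in vsets)
        B_hat = resolve_scale_permutation(joint_diagonalize(_covariance_differences(covs))[0])
        assert np.abs(B_hat - B).max() < 1e-6

    def test_hidden_intervention_leaves_residual(self, acyclic3_model):
        # an intervention on a hidden variable driving two observed markers
        # adds off-diagonal intervention covariance that conflicts with
        # diagonalizing the genuine covariance differences
        m = acyclic3_model
        hidden = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 0.0]])
        M = m.mixing()
        covs = tuple(
            [m.population_covariance(np.asarray(v)) for v in THREE_ENVS]
            + [m.population_covariance(np.array([1.0, 0.5, 0.0])) + M @ (2 * hidden) @ M.T]
        )
        try:
            _, res = joint_diagonalize(_covariance_differences(covs))
        except JointDiagonalizationError as exc:
            res = exc.residual
        assert res > 1e-3


class TestResolveScalePermutation:
    def test_inverts_permutation_and_scaling(self, acyclic3_model):
        W_true = np.eye(3) - acyclic3_model.B
        rng = np.random.default_rng(0)
        perm = rng.permutation(3)
        scales = rng.uniform(0.5, 2.0, 3) * rng.choice([-1, 1], 3)
        W_scrambled = (W_true * scales[:, None])[perm]
        B_hat = resolve_scale_permutation(W_scrambled)
        assert np.abs(B_hat - acyclic3_model.B).max() < 1e-12

    def test_pure_scaling_gives_zero_connectivity(self):
        assert np.abs(resolve_scale_permutation(2 * np.eye(3))).max() == 0.0

    def test_zero_column_unresolvable(self):
        W = np.eye(3)
        W[:, 1] = 0.0
        with pytest.raises(JointDiagonalizationError, match="unresolvable"):
            resolve_scale_permutation(W)


class TestEstimate:
    def test_three_environment_recovery(self, acyclic3_model):
        tables = _env_tables(acyclic3_model, THREE_ENVS, 10_000, 1)
        est = estimate_backshift(environment_covariances(tables))
        assert np.abs(est.B_hat - acyclic3_model.B).max() < 0.1
        # intervention variance estimates track the truth up to baseline shift
        assert np.abs(est.intervention_variances[1] - THREE_ENVS[1]).max() < 0.3

    def test_cyclic_recovery(self):
        B = np.array([[0.0, 0.4], [0.3, 0.0]])
        m = cc.CausalModel(B, np.eye(2), np.zeros(2), ("x", "y"))
        vsets = [np.zeros(2), [1.5, 0.2], [0.3, 2.0], [2.5, 1.0]]
        tables = _env_tables(m, vsets, 10_000, 2)
        est = estimate_backshift(environment_covariances(tables))
        assert np.abs(est.B_hat - B).max() < 0.05

    def test_permutation_equivariance(self, acyclic3_model):
        tables = _env_tables(acyclic3_model, THREE_ENVS, 5_000, 3)
        est = estimate_backshift(environment_covariances(tables))
        perm = [2, 0, 1]
        permuted = [
            cc.CellTable(t.values[:, perm], tuple(t.labels[i] for i in perm), t.meta)
            for t in tables
        ]
        est_p = estimate_backshift(environment_covariances(permuted))
        assert np.abs(est_p.B_hat - est.B_hat[np.ix_(perm, perm)]).max() < 1e-8

    def test_marker_rescaling_equivariance(self, acyclic3_model):
        tables = _env_tables(acyclic3_model, THREE_ENVS, 5_000, 4)
        est = estimate_backshift(environment_covariances(tables))
        s = 3.0  # rescale marker 0: B[i,0] scales by 1/s, B[0,j] by s
        scaled = [
            cc.CellTable(t.values * np.array([s, 1, 1]), t.labels, t.meta)
            for t in tables
        ]
        est_s = estimate_backshift(environment_covariances(scaled))
        expected = est.B_hat.copy()
        expected[:, 0] /= s
        expected[0, :] *= s
        assert np.abs(est_s.B_hat - expected).max() < 1e-8


class TestDiagnostics:
    def test_well_specified_model_passes(self, acyclic3_model):
        ok = 0
        for seed in range(5):
            tables = _env_tables(acyclic3_model, THREE_ENVS, 2_000, 10 + seed)
            report = diagnose_model(environment_covariances(tables), n_boot=30, seed=seed)
            ok += report.success
        assert ok >= 4

    def test_correlated_interventions_detected(self, acyclic3_model):
        # shared shift noise on two markers within one environment makes
        # Sigma_c non-diagonal there; with a fourth environment the
        # system is overdetermined and the violation leaves a residual
        # that the parametric bootstrap flags
        m = acyclic3_model
        M = m.mixing()
        fails = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            tables = _env_tables(m, THREE_ENVS, 4_000, rng)
            base = cc.simulate_condition(m, n=4_000, seed=rng)
            z = rng.standard_normal(4_000)
            w = rng.standard_normal((4_000, 3))
            c = np.column_stack([
                np.sqrt(1.2) * z + np.sqrt(0.3) * w[:, 0],
                np.sqrt(1.2) * z + np.sqrt(0.3) * w[:, 1],
                np.sqrt(0.5) * w[:, 2],
            ])
            bad = base.values + c @ M.T
            tables.append(cc.CellTable(bad, base.labels, base.meta))
            report = diagnose_model(environment_covariances(tables), n_boot=30, seed=seed)
            fails += not report.success
        assert fails >= 3

    def test_zero_bootstrap_rejected(self, acyclic3_model):
        tables = _env_tables(acyclic3_model, THREE_ENVS, 1_000, 0)
        with pytest.raises(ValueError, match="n_boot"):
            diagnose_model(environment_covariances(tables), n_boot=0)


class TestStabilitySelection:
    def test_keep_count_formula(self):
        # q = floor(sqrt(EV (2 pi - 1) p (p-1))) = floor(sqrt(455)) for p=14
        assert keep_count(14) == 21
        assert keep_count(14, StabilityConfig(ev=5, pi_thr=0.75)) == int(np.sqrt(455))

    def test_strong_edges_stable(self, acyclic3_model):
        tables = _env_tables(acyclic3_model, THREE_ENVS, 5_000, 5)
        result = stability_select(
            environment_covariances(tables),
            StabilityConfig(ev=5.0, n_sim=50, pi_thr=0.75, min_success=38),
            seed=0,
        )
        found = {(u, v) for u, v, _ in result.stable_edges}
        true_edges = {("x", "y"), ("y", "z"), ("x", "z")}
        assert found <= true_edges  # no false edges
        assert {("x", "y"), ("y", "z")} <= found  # strong edges recovered

    def test_min_success_guard(self, acyclic3_model):
        tables = _env_tables(acyclic3_model, THREE_ENVS, 1_000, 6)
        with pytest.raises(ModelViolationError, match="model violated"):
            stability_select(
                environment_covariances(tables),
                StabilityConfig(n_sim=10, min_success=11),
                seed=0,
            )
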