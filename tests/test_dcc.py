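import numpy as np
import pytest

from conftest import make_ts
from dynstates.dcc import (
    dcc_correlation_path,
    dcc_loglik,
    dynamic_connectome,
    fit_dcc,
    fit_garch11,
    static_fc,
)


def simulate_garch11(omega, alpha, beta, T, rng):
    x = np.empty(T)
    s = omega / (1 - alpha - beta) if alpha + beta < 1 else omega
    for t in range(T):
        x[t] = np.sqrt(s) * rng.standard_normal()
        s = omega + alpha * x[t] ** 2 + beta * s
    return x


class TestGarch:
    def test_iid_series_recovers_unconditional_variance(self):
        rng = np.random.default_rng(0)
        fit = fit_garch11(2.0 * rng.standard_normal(4000))
        assert abs(fit.unconditional_variance - 4.0) / 4.0 < 0.15

    def test_constant_variance_data_gives_flat_sigma_path(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        fit = fit_garch11(x)
        assert np.allclose(fit.sigma2_path, np.var(x), rtol=0.25)
        assert 0.8 < fit.std_residuals.var() < 1.2

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_garch11(np.full(100, 2.0))
        with pytest.raises(ValueError):
            fit_garch11(np.zeros(10))  # too short

    def test_stationarity_constraint_held(self):
        rng = np.random.default_rng(2)
        x = simulate_garch11(0.05, 0.15, 0.84, 1500, rng)
        fit = fit_garch11(x)
        assert fit.alpha >= 0 and fit.beta >= 0
        assert fit.alpha + fit.beta <= 1 - 1e-6 + 1e-12
        assert fit.sigma2_path.min() > 0
        assert fit.sigma2_path.size == x.size


class TestDcc:
    def test_forced_zero_theta_collapses_to_static_correlation(self, rng):
        Z = rng.standard_normal((300, 3))
        fit = fit_dcc(Z, fixed_theta=(0.0, 0.0))
        R = dcc_correlation_path(Z, fit)
        for t in (0, 150, 299):
            assert np.allclose(R[t], fit.sbar, atol=1e-12)

    def test_constant_correlation_recovered(self):
        rng = np.random.default_rng(1)
        z1 = rng.standard_normal(2000)
        z2 = 0.6 * z1 + np.sqrt(1 - 0.36) * rng.standard_normal(2000)
        Z = np.column_stack([z1, z2])
        fit = fit_dcc(Z, mode="pairwise")
        R = dcc_correlation_path(Z, fit)
        assert abs(R[:, 0, 1].mean() - 0.6) < 0.05

    def test_step_change_tracked(self):
        rng = np.random.default_rng(2)
        rho = np.where(np.arange(2000) < 1000, 0.0, 0.8)
        z1 = rng.standard_normal(2000)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(2000)
        Z = np.column_stack([z1, z2])
        fit = fit_dcc(Z, mode="pairwise")
        R = dcc_correlation_path(Z, fit)
        assert R[1000:, 0, 1].mean() - R[:1000, 0, 1].mean() >= 0.4

    @pytest.mark.parametrize("mode", ["pairwise", "joint", "ewma"])
    def test_optimum_dominates_reference_points(self, mode):
        rng = np.random.default_rng(3)
        rho = np.where(np.arange(800) < 400, 0.1, 0.7)
        z1 = rng.standard_normal(800)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(800)
        Z = np.column_stack([z1, z2])
        fit = fit_dcc(Z, mode=mode)
        if mode == "ewma":
            return  # fixed-parameter mode: nothing to dominate
        ll_mode = "joint" if mode == "joint" else "pairwise"
        for ref in [(0.0, 0.0), (0.01, 0.97)]:
            assert fit.loglik >= dcc_loglik(Z, fit.sbar, *ref, mode=ll_mode) - 1e-6

    def test_unstandardized_input_rejected(self, rng):
        Z = 3.0 * rng.standard_normal((200, 3))
        with pytest.raises(ValueError, match="standardized"):
            fit_dcc(Z)

    def test_single_column_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_dcc(rng.standard_normal((200, 1)))


class TestDynamicConnectome:
    def test_perfectly_correlated_nodes(self, rng):
        x = rng.standard_normal(300)
        ts = make_ts([np.column_stack([x, x + 1e-9 * rng.standard_normal(300)])])
        conn, _, _ = dynamic_connectome(ts)
        assert np.all(conn.frames[:, 0, 1] >= 0.99)

    def test_single_state_subject_time_mean_close_to_template(self, small_spec):
        from dynstates.synthetic import make_state_templates, TemplatePlan
        from dynstates.types import CohortSpec
        from dynstates.synthetic import simulate_subject

        plans = [TemplatePlan(blocks=[(list(range(5)), 0.5)], background=0.0)]
        spec = CohortSpec(
            n_controls=1, n_patients=0, n_nodes=10,
            templates=make_state_templates(10, 1, plans),
            runs_per_subject=2, frames_per_run=300, dwell_mean=300, seed=4,
        )
        ts, _ = simulate_subject(spec, "control", 0)
        conn, garch_fits, dcc_fit = dynamic_connectome(ts)
        err = np.abs(conn.frames.mean(axis=0) - spec.templates[0].corr).max()
        assert err < 0.1
        assert len(garch_fits) == 10

    def test_node_permutation_equivariance(self, rng):
        n = 6
        base = rng.standard_normal((400, n)) @ np.linalg.cholesky(
            0.3 * np.ones((n, n)) + 0.7 * np.eye(n)
        ).T
        ts = make_ts([base])
        perm = np.array([3, 1, 5, 0, 4, 2])
        ts_p = make_ts([base[:, perm]])
        conn, _, _ = dynamic_connectome(ts)
        conn_p, _, _ = dynamic_connectome(ts_p)
        assert np.allclose(
            conn_p.frames, conn.frames[:, perm][:, :, perm], atol=1e-8
        )

    def test_emitted_frames_are_valid_correlations(self, small_subject):
        ts, _ = small_subject
        conn, _, _ = dynamic_connectome(ts)
        conn.validate()  # symmetry, unit diagonal, range
        assert conn.n_frames == ts.n_frames_total
        dropped = conn.drop_burnin(5)
        assert dropped.n_frames == ts.n_frames_total - 5 * len(ts.runs)
        assert dropped.frame_in_run.min() == 5

    def test_constant_node_rejected(self):
        ts = make_ts([np.column_stack([np.zeros(100), np.random.default_rng(0).standard_normal(100)])])
        with pytest.raises(ValueError, match="node 0"):
            dynamic_connectome(ts)

    def test_determinism(self, small_subject):
        ts, _ = small_subject
        a, _, fit_a = dynamic_connectome(ts)
        b, _, fit_b = dynamic_connectome(ts)
        assert np.array_equal(a.frames, b.frames)
        assert fit_a.loglik == fit_b.loglik


class TestStaticFc:
    def test_linear_dependence(self):
        x = np.arange(100, dtype=float)
        ts = make_ts([np.column_stack([x, 2 * x, -x])])
        C = static_fc(ts)
        assert np.isclose(C[0, 1], 1.0)
        assert np.isclose(C[0, 2], -1.0)

    def test_matches_direct_formula(self, rng):
        X = rng.standard_normal((50, 3))
        ts = make_ts([X])
        C = static_fc(ts)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (50 - 1)
        sd = np.sqrt(np.diag(cov))
        assert np.allclose(C, cov / np.outer(sd, sd), atol=1e-12)

    def test_constant_node_rejected(self):
        ts = make_ts([np.column_stack([np.ones(50), np.arange(50.0)])])
        with pytest.raises(ValueError):
            static_fc(ts)
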