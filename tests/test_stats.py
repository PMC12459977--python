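import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dynstates.stats import (
    build_covariate_design,
    edgewise_ttest,
    fdr_bh,
    nbs_correct,
    partial_corr,
    pca_composite,
    topology_group_tests,
)
from dynstates.synthetic import make_state_templates, simulate_state_matrix_cohort
from dynstates.types import StateMatrix, upper_indices


def state_mats(arrs, state_id=0, prefix="s"):
    return [
        StateMatrix(subject_id=f"{prefix}{i}", state_id=state_id, matrix=m, n_frames=1)
        for i, m in enumerate(arrs)
    ]


def noisy_mats(n_subj, n_nodes, rng, delta=None):
    out = []
    iu = upper_indices(n_nodes)
    for _ in range(n_subj):
        M = np.zeros((n_nodes, n_nodes))
        vals = rng.normal(0.3, 0.1, iu[0].size)
        M[iu] = vals
        M += M.T
        np.fill_diagonal(M, 1.0)
        if delta:
            for i, j, d in delta:
                M[i, j] += d
                M[j, i] += d
        out.append(M)
    return out


class TestEdgewiseTtest:
    def test_identical_groups_give_null_stats(self, rng):
        mats = noisy_mats(5, 6, rng)
        t, p = edgewise_ttest(state_mats(mats, prefix="a"), state_mats(mats, prefix="b"))
        assert np.allclose(t, 0.0)
        offdiag = ~np.eye(6, dtype=bool)
        assert np.allclose(p[offdiag], 1.0)

    def test_planted_edge_dominates_at_low_noise(self):
        a = noisy_mats(6, 8, np.random.default_rng(0))
        b = noisy_mats(6, 8, np.random.default_rng(1), delta=[(2, 5, -0.5)])
        t, _ = edgewise_ttest(state_mats(a, prefix="a"), state_mats(b, prefix="b"))
        iu = upper_indices(8)
        assert np.unravel_index(np.argmax(np.abs(t)), t.shape) in [(2, 5), (5, 2)]

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        a = state_mats(noisy_mats(20, 46, rng), prefix="a")  # 1035 edges
        b = state_mats(noisy_mats(20, 46, rng), prefix="b")
        _, p = edgewise_ttest(a, b)
        iu = upper_indices(46)
        ks = sps.kstest(p[iu], "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_subjects_rejected(self, rng):
        a = state_mats(noisy_mats(1, 4, rng), prefix="a")
        b = state_mats(noisy_mats(4, 4, rng), prefix="b")
        with pytest.raises(ValueError):
            edgewise_ttest(a, b)


class TestNbs:
    def test_identical_groups_no_suprathreshold_components(self, rng):
        mats = noisy_mats(6, 10, rng)
        res = nbs_correct(
            state_mats(mats, prefix="a"), state_mats(mats, prefix="b"), n_perm=100
        )
        assert res.components == []

    def test_planted_component_detected_with_correct_sign(self):
        tpl = make_state_templates(30, 2)[0]
        edges = [(i, i + 1, -0.3) for i in range(6)]
        a, b = simulate_state_matrix_cohort(tpl, 15, 15, effect_edges=edges,
                                            noise_sd=0.1, seed=4)
        res = nbs_correct(a, b, edge_alpha=0.005, n_perm=500, seed=1)
        sig = res.significant()
        assert sig, "planted effect not flagged"
        best = sig[0]
        assert best.sign == 1  # group A exceeds group B at hypo edges
        assert len(set(best.edges) & {(i, i + 1) for i in range(6)}) >= 5

    def test_component_p_floor_and_reproducibility(self):
        tpl = make_state_templates(20, 2)[0]
        edges = [(i, i + 1, -0.35) for i in range(5)]
        a, b = simulate_state_matrix_cohort(tpl, 12, 12, effect_edges=edges,
                                            noise_sd=0.08, seed=5)
        r1 = nbs_correct(a, b, edge_alpha=0.005, n_perm=200, seed=9)
        r2 = nbs_correct(a, b, edge_alpha=0.005, n_perm=200, seed=9)
        assert all(c.p_value >= 1 / 201 for c in r1.components)
        assert [c.p_value for c in r1.components] == [c.p_value for c in r2.components]

    def test_extent_statistic_available(self):
        tpl = make_state_templates(20, 2)[0]
        a, b = simulate_state_matrix_cohort(tpl, 8, 8, noise_sd=0.1, seed=6)
        res = nbs_correct(a, b, n_perm=100, statistic="extent", seed=0)
        assert res.statistic == "extent"

    def test_single_subject_group_rejected(self, rng):
        a = state_mats(noisy_mats(1, 5, rng), prefix="a")
        b = state_mats(noisy_mats(5, 5, rng), prefix="b")
        with pytest.raises(ValueError):
            nbs_correct(a, b, n_perm=100)


class TestFdr:
    def test_all_tiny_p_all_rejected(self):
        assert fdr_bh(np.full(10, 0.001)).all()

    def test_all_large_p_none_rejected(self):
        assert not fdr_bh(np.full(10, 0.9)).any()

    def test_hand_run_step_up(self):
        # sorted p: .001 (<= 1/4*.05=.0125), .02 (<= .025), .03 (<= .0375), .2 (> .05)
        rej = fdr_bh(np.array([0.2, 0.001, 0.03, 0.02]))
        assert rej.tolist() == [False, True, True, True]

    def test_rejections_superset_of_bonferroni(self, rng):
        for seed in range(5):
            p = np.random.default_rng(seed).uniform(0, 0.2, 40)
            bh = fdr_bh(p, 0.05)
            bonf = p < 0.05 / p.size
            assert np.all(bh[bonf])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.1, 1.2]))


class TestPcaComposite:
    def _factor_table(self, n, loadings, noise, rng, factors=1):
        F = rng.standard_normal((n, factors))
        L = np.asarray(loadings)
        X = F @ L + noise * rng.standard_normal((n, L.shape[1]))
        return pd.DataFrame(X, columns=[f"sub{j}" for j in range(L.shape[1])])

    def test_single_dominant_factor(self, rng):
        tbl = self._factor_table(60, np.ones((1, 6)), 0.2, rng)
        comp = pca_composite(tbl)
        assert len(comp.retained) == 1
        assert comp.final_variance_explained > 0.8
        # orientation: higher composite = better (positive) subtest scores
        assert np.corrcoef(comp.final_score, tbl.sum(axis=1))[0, 1] > 0.9

    def test_two_orthogonal_factors_retained(self, rng):
        L = np.zeros((2, 8))
        L[0, :4] = 1.0
        L[1, 4:] = 1.0
        tbl = self._factor_table(80, L, 0.2, rng, factors=2)
        comp = pca_composite(tbl)
        assert len(comp.retained) == 2
        assert comp.final_score.shape == (80,)

    def test_perfectly_correlated_subtests_rank_one(self, rng):
        f = rng.standard_normal(30)
        tbl = pd.DataFrame({"a": f, "b": 2 * f, "c": -f})
        comp = pca_composite(tbl)
        assert comp.eigenvalues[0] == pytest.approx(3.0, abs=1e-8)
        assert np.allclose(comp.eigenvalues[1:], 0.0, atol=1e-8)
        assert len(comp.retained) == 1

    def test_zero_variance_subtest_dropped(self, rng):
        tbl = pd.DataFrame({
            "a": rng.standard_normal(20),
            "b": rng.standard_normal(20),
            "flat": np.ones(20),
        })
        comp = pca_composite(tbl)
        assert comp.dropped_subtests == ["flat"]

    def test_subtest_reordering_invariance(self, rng):
        tbl = self._factor_table(50, np.ones((1, 5)), 0.3, rng)
        comp1 = pca_composite(tbl)
        comp2 = pca_composite(tbl[list(tbl.columns[::-1])])
        assert np.allclose(comp1.final_score, comp2.final_score, atol=1e-8)

    def test_baseline_normalization_rows(self, rng):
        tbl = self._factor_table(40, np.ones((1, 4)), 0.3, rng)
        comp = pca_composite(tbl, baseline_rows=np.arange(10))
        assert comp.final_score.shape == (40,)

    def test_missing_values_rejected(self):
        tbl = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            pca_composite(tbl)


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        r, p = partial_corr(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_exact_covariate_residual_is_degenerate(self, rng):
        x = rng.standard_normal(30)
        c = rng.standard_normal(30)
        with pytest.raises(ValueError, match="zero-variance"):
            partial_corr(x, c, c)

    def test_confound_removed(self, rng):
        c = rng.standard_normal(200)
        x = c + 0.1 * rng.standard_normal(200)
        y = -c + 0.1 * rng.standard_normal(200)
        r_raw, _ = partial_corr(x, y)
        r_adj, p_adj = partial_corr(x, y, c)
        assert r_raw < -0.9
        assert abs(r_adj) < 0.2

    def test_affine_invariance_of_covariates(self, rng):
        x, y = rng.standard_normal((2, 50))
        C = rng.standard_normal((50, 3))
        r1, p1 = partial_corr(x, y, C)
        r2, p2 = partial_corr(x, y, 5 * C + 2)
        assert r1 == pytest.approx(r2, abs=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_power_at_generator_effect_size(self):
        # synthetic coupling, n=30, independent covariates
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = rng.normal(0, 0.03, 30)
            score = 8.0 * s + rng.normal(0, 0.2, 30)
            cov = pd.DataFrame({
                "age": rng.normal(55, 10, 30),
                "sex": rng.choice(["F", "M"], 30),
            })
            r, p = partial_corr(score, s, cov)
            hits += (r > 0) and (p < 0.05)
        assert hits >= 8

    def test_categorical_covariates_encoded(self):
        df = pd.DataFrame({"sex": ["F", "M", "F"], "age": [1.0, 2.0, 3.0]})
        X = build_covariate_design(df)
        assert X.shape == (3, 2)


class TestTopologyTests:
    def _nodal_table(self, n_subj, n_nodes, rng, prefix, bump=None):
        rows = []
        for s in range(n_subj):
            for node in range(n_nodes):
                val = rng.normal(1.0, 0.1)
                if bump and node in bump:
                    val += 0.5
                rows.append(dict(subject_id=f"{prefix}{s}", state_id=0, node_id=node,
                                 strength=val, ge=rng.normal(0.5, 0.05),
                                 le=rng.normal(0.4, 0.05), bc=rng.normal(0.1, 0.02)))
        return pd.DataFrame(rows)

    def test_identical_groups_no_rejections(self, rng):
        a = self._nodal_table(10, 12, np.random.default_rng(0), "a")
        b = self._nodal_table(10, 12, np.random.default_rng(0), "b")
        rep = topology_group_tests(a, b)
        assert not rep["significant"].any()

    def test_planted_strength_increase_detected(self):
        a = self._nodal_table(20, 12, np.random.default_rng(1), "a", bump={2, 3, 4, 5})
        b = self._nodal_table(20, 12, np.random.default_rng(2), "b")
        rep = topology_group_tests(a, b)
        hits = rep[(rep.metric == "strength") & rep.significant]["node_id"].tolist()
        assert set(hits) == {2, 3, 4, 5}

    def test_correction_none_reports_raw_p(self):
        a = self._nodal_table(8, 6, np.random.default_rng(3), "a")
        b = self._nodal_table(8, 6, np.random.default_rng(4), "b")
        rep = topology_group_tests(a, b, correction="none")
        assert ((rep.p < 0.05) == rep.significant).all()
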