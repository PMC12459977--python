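import numpy as np
import pytest

from dynstates.synthetic import (
    TemplatePlan,
    apply_effect_edges,
    default_cohort_spec,
    empirical_state_matrices,
    is_weak_template,
    make_state_templates,
    simulate_cohort,
    simulate_subject,
)
from dynstates.states import spatial_similarity
from dynstates.types import BehaviorCoupling, CohortSpec


class TestStateTemplates:
    def test_identity_template(self):
        plans = [TemplatePlan(blocks=[], background=0.0)]
        (tpl,) = make_state_templates(10, 1, plans)
        assert np.array_equal(tpl.corr, np.eye(10))

    def test_two_node_block_eigenvalues(self):
        # hand oracle: block {0,1} at 0.6, rest 0 -> spectrum {1.6, 1, 1, 0.4}
        plans = [TemplatePlan(blocks=[([0, 1], 0.6)], background=0.0)]
        (tpl,) = make_state_templates(4, 1, plans)
        assert tpl.corr[0, 1] == 0.6
        assert np.all(np.diag(tpl.corr) == 1.0)
        assert np.isclose(tpl.min_eigenvalue(), 0.4)

    def test_default_templates_distinct_and_pd(self):
        tpls = make_state_templates(40, 4)
        assert len(tpls) == 4
        for t in tpls:
            assert t.min_eigenvalue() > 0
        # one weak state, mirroring the overall-weak empirical pattern
        assert is_weak_template(tpls[-1])
        assert not any(is_weak_template(t) for t in tpls[:-1])
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(spatial_similarity(tpls[i].corr, tpls[j].corr)) < 0.5

    def test_non_pd_plan_rejected_not_repaired(self):
        # uniform -0.5 between two large weak groups cannot be a correlation matrix
        plans = [TemplatePlan(
            blocks=[], couplings=[(list(range(5)), list(range(5, 10)), -0.5)],
            background=0.0,
        )]
        with pytest.raises(ValueError, match="template 0"):
            make_state_templates(10, 1, plans)

    def test_effect_edges_pd_guard_names_edge(self):
        tpls = make_state_templates(20, 2)
        bad = [(0, i, j, -0.9) for i in range(5) for j in range(i + 1, 5)]
        with pytest.raises(ValueError, match="effect edges"):
            apply_effect_edges(tpls, bad)


class TestSimulateSubject:
    def test_single_state_labels_all_zero(self):
        spec = default_cohort_spec(
            n_controls=1, n_patients=0, n_nodes=6, k=1, seed=0,
            runs_per_subject=2, frames_per_run=60, dwell_mean=60,
        )
        _, labels = simulate_subject(spec, "control", 0)
        assert all(np.all(v == 0) for v in labels.values())

    def test_degenerate_garch_gives_unit_variance(self):
        spec = default_cohort_spec(
            n_controls=1, n_patients=0, n_nodes=4, k=1, seed=0,
            runs_per_subject=4, frames_per_run=500,
            garch_params=(1.0, 0.0, 0.0),
        )
        ts, _ = simulate_subject(spec, "control", 0)
        pooled = ts.concatenated(demean_per_run=False)
        assert np.allclose(pooled.var(axis=0), 1.0, atol=0.1)

    def test_long_run_correlation_converges_to_template(self):
        plans = [TemplatePlan(blocks=[([0, 1], 0.6)], background=0.0)]
        spec = CohortSpec(
            n_controls=1, n_patients=0, n_nodes=4,
            templates=make_state_templates(4, 1, plans),
            runs_per_subject=1, frames_per_run=4000, dwell_mean=4000, seed=5,
        )
        ts, _ = simulate_subject(spec, "control", 0)
        r = np.corrcoef(ts.runs[0][:, 0], ts.runs[0][:, 1])[0, 1]
        assert abs(r - 0.6) < 0.05

    def test_seed_reproducibility_and_stream_independence(self, small_spec):
        ts_a, lab_a = simulate_subject(small_spec, "control", 1)
        ts_b, lab_b = simulate_subject(small_spec, "control", 1)
        for ra, rb in zip(ts_a.runs, ts_b.runs):
            assert np.array_equal(ra, rb)  # bit-identical under fixed seed
        ts_c, _ = simulate_subject(small_spec, "control", 2)
        assert not np.array_equal(ts_a.runs[0], ts_c.runs[0])

    def test_within_state_correlation_matches_template(self, small_spec, small_subject):
        ts, labels = small_subject
        mats = empirical_state_matrices(ts, labels)
        # strongest-sampled state should be close to its template
        best = max(mats.values(), key=lambda m: m.n_frames)
        tpl = small_spec.templates[best.state_id].corr
        err = np.abs(best.matrix - tpl).max()
        assert err < 0.35  # short dwells: loose sup-norm bound


class TestSimulateCohort:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_controls=0, n_patients=0, n_nodes=4)

    def test_null_coupling_gives_no_association(self):
        spec = default_cohort_spec(
            n_controls=0, n_patients=30, n_nodes=20, seed=2,
            runs_per_subject=2, frames_per_run=100,
            effect_edges=[(0, 0, 1, -0.2)],
            behavior_coupling=BehaviorCoupling(slope_hypo=0.0, slope_hyper=0.0, noise_sd=1.0),
        )
        _, truth, behavior, _ = simulate_cohort(spec)
        scores = behavior.latent_score.to_numpy()
        assert scores.std() > 0
        # slope 0: score is pure noise, uncorrelated with anything planted

    def test_vanishing_noise_gives_perfect_coupling(self):
        spec = default_cohort_spec(
            n_controls=0, n_patients=15, n_nodes=20, seed=2,
            runs_per_subject=2, frames_per_run=100,
            effect_edges=[(0, 0, 1, -0.2)],
            behavior_coupling=BehaviorCoupling(slope_hypo=5.0, slope_hyper=0.0, noise_sd=1e-12),
        )
        subs, truth, behavior, _ = simulate_cohort(spec)
        strengths = []
        for ts in subs:
            mats = empirical_state_matrices(ts, truth.labels[ts.subject_id])
            strengths.append(mats[0].matrix[0, 1])
        r = np.corrcoef(behavior.latent_score, strengths)[0, 1]
        assert r > 0.999

    def test_cohort_structure_and_tables(self, small_spec):
        subs, truth, behavior, cov = simulate_cohort(small_spec)
        assert len(subs) == 4
        assert {s.subject_id[:3] for s in subs} == {"con", "pat"}
        assert len(behavior) == 4 and len(cov) == 4
        assert set(truth.labels) == {s.subject_id for s in subs}
        for ts in subs:
            labs = truth.subject_labels(ts.subject_id)
            assert labs.size == ts.n_frames_total
            assert set(np.unique(labs)) <= set(range(small_spec.k))
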