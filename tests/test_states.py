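import numpy as np
import pandas as pd
import pytest

from dynstates.states import (
    devectorize,
    dwell_times,
    elbow_select_k,
    group_state_matrix,
    kmeans_l1,
    match_states,
    relabel,
    spatial_similarity,
    subject_state_medians,
    vectorize_frames,
)
from dynstates.types import DynamicConnectome, FrameMatrix


def make_connectome(frames, subject_id="s0"):
    T = frames.shape[0]
    return DynamicConnectome(
        frames=frames,
        run_ids=np.repeat("run00", T),
        frame_in_run=np.arange(T),
        node_ids=np.arange(frames.shape[1]),
        subject_id=subject_id,
    )


def frame_matrix_from(data, n_nodes, subjects=None):
    T = data.shape[0]
    prov = pd.DataFrame(
        dict(
            subject_id=subjects if subjects is not None else ["s0"] * T,
            run_id=["run00"] * T,
            frame=np.arange(T),
        )
    )
    return FrameMatrix(data=data, provenance=prov, n_nodes=n_nodes)


class TestVectorization:
    def test_edge_column_convention(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.5
        R[0, 2] = R[2, 0] = -0.2
        R[1, 2] = R[2, 1] = 0.8
        fm = vectorize_frames([make_connectome(R[None])])
        # documented order: (0,1), (0,2), (1,2)
        assert np.allclose(fm.data[0], [0.5, -0.2, 0.8])

    def test_identity_frame_gives_zero_row(self):
        fm = vectorize_frames([make_connectome(np.eye(4)[None])])
        assert np.allclose(fm.data[0], 0.0)

    def test_round_trip(self, rng):
        R = rng.uniform(-1, 1, (5, 5))
        R = 0.5 * (R + R.T)
        np.fill_diagonal(R, 1.0)
        fm = vectorize_frames([make_connectome(R[None])])
        assert np.allclose(devectorize(fm.data[0], 5), R)

    def test_node_order_mismatch_rejected(self):
        a = make_connectome(np.eye(3)[None])
        b = make_connectome(np.eye(3)[None])
        b.node_ids = np.array([0, 2, 1])
        with pytest.raises(ValueError, match="node order"):
            vectorize_frames([a, b])

    def test_provenance_covers_rows(self, rng):
        conns = [
            make_connectome(np.repeat(np.eye(3)[None], 4, axis=0), "a"),
            make_connectome(np.repeat(np.eye(3)[None], 6, axis=0), "b"),
        ]
        fm = vectorize_frames(conns)
        assert fm.n_frames == 10
        assert (fm.provenance.subject_id.value_counts().to_dict()) == {"a": 4, "b": 6}


class TestKmeansL1:
    def test_separated_clouds_recovered_exactly(self, rng):
        A = rng.normal(0, 0.5, (80, 10)) + 10
        B = rng.normal(0, 0.5, (80, 10)) - 10
        X = np.vstack([A, B])
        part = kmeans_l1(X, 2, n_init=4, seed=0)
        labels = part.labels
        assert len(set(labels[:80])) == 1 and len(set(labels[80:])) == 1
        assert labels[0] != labels[-1]

    def test_k1_centroid_is_columnwise_median(self, rng):
        X = rng.standard_normal((31, 6))
        part = kmeans_l1(X, 1, n_init=1, seed=0)
        assert np.allclose(part.centroids[0], np.median(X, axis=0), atol=1e-6)

    def test_duplication_invariance(self, rng):
        # well-separated clouds: the optimum is unique, so duplicating every
        # row must converge to the same centroids (up to state relabeling)
        X = np.vstack([rng.normal(0, 0.3, (30, 5)) + mu for mu in (-6, 0, 6)])
        p1 = kmeans_l1(X, 3, n_init=5, seed=9)
        p2 = kmeans_l1(np.vstack([X, X]), 3, n_init=5, seed=9)
        perm, _ = match_states(p1.centroids, p2.centroids)
        assert np.allclose(p1.centroids, p2.centroids[perm], atol=1e-5)
        assert p2.inertia == pytest.approx(2 * p1.inertia, rel=1e-5)

    def test_objective_reported_and_labels_complete(self, rng):
        X = rng.standard_normal((50, 4))
        part = kmeans_l1(X, 4, n_init=2, seed=1)
        assert part.inertia > 0
        assert np.bincount(part.labels, minlength=4).min() >= 1

    def test_fewer_rows_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_l1(rng.standard_normal((3, 4)), 5)


class TestElbow:
    def test_two_clouds_select_two(self, rng):
        X = np.vstack([
            rng.normal(0, 1, (150, 20)) + 8,
            rng.normal(0, 1, (150, 20)) - 8,
        ])
        k, curve, parts = elbow_select_k(X, range(2, 7), n_init=4, seed=2)
        assert k == 2
        assert set(curve) == {2, 3, 4, 5, 6}

    def test_four_clouds_select_four(self, rng):
        X = np.vstack([
            rng.normal(0, 1, (100, 20)) + mu for mu in (0, 12, 24, 36)
        ])
        k, curve, parts = elbow_select_k(X, range(2, 8), n_init=4, seed=2)
        assert k == 4
        assert parts[4].k == 4

    def test_noise_returns_interior_k_and_full_curve(self, rng):
        X = rng.standard_normal((200, 10))
        k, curve, _ = elbow_select_k(X, range(2, 6), n_init=2, seed=0)
        assert 2 <= k <= 5
        assert sorted(curve) == [2, 3, 4, 5]

    def test_too_narrow_range_rejected(self, rng):
        with pytest.raises(ValueError):
            elbow_select_k(rng.standard_normal((50, 4)), [2, 3])


class TestStateMedians:
    def test_single_frame_state_is_that_frame(self):
        E = 3
        data = np.array([[0.1, 0.2, 0.3], [0.5, 0.6, 0.7]])
        fm = frame_matrix_from(data, 3)
        part_labels = np.array([0, 1])
        from dynstates.types import StatePartition

        part = StatePartition(k=2, centroids=data.copy(), labels=part_labels, inertia=0.0)
        mats = subject_state_medians(fm, part)
        assert len(mats) == 2
        assert np.allclose(mats[0].matrix[0, 1], 0.1)

    def test_oddcount_median(self):
        data = np.array([[0.2, 0, 0], [0.4, 0, 0], [0.9, 0, 0]])
        fm = frame_matrix_from(data, 3)
        from dynstates.types import StatePartition

        part = StatePartition(
            k=1, centroids=np.median(data, 0)[None], labels=np.zeros(3, int), inertia=1.0
        )
        (mat,) = subject_state_medians(fm, part)
        assert mat.matrix[0, 1] == 0.4
        assert mat.n_frames == 3

    def test_absent_state_omitted_not_zero_filled(self):
        data = np.tile([[0.3, 0.3, 0.3]], (4, 1))
        fm = frame_matrix_from(data, 3, subjects=["a", "a", "b", "b"])
        from dynstates.types import StatePartition

        part = StatePartition(
            k=2,
            centroids=np.vstack([data[0], data[0] + 1]),
            labels=np.array([0, 0, 1, 1]),
            inertia=0.0,
        )
        mats = subject_state_medians(fm, part)
        assert {(m.subject_id, m.state_id) for m in mats} == {("a", 0), ("b", 1)}
        assert group_state_matrix(mats, 0)[0, 1] == 0.3
        with pytest.raises(ValueError):
            group_state_matrix([m for m in mats if m.state_id == 0], 1)


class TestMatchingAndSimilarity:
    def test_identical_sets_identity_permutation(self, rng):
        C = rng.standard_normal((4, 10))
        perm, corr = match_states(C, C)
        assert np.array_equal(perm, np.arange(4))
        assert np.allclose(np.diag(corr), 1.0)

    def test_shuffle_recovered(self, rng):
        C = rng.standard_normal((5, 12))
        shuffle = np.array([2, 0, 4, 1, 3])
        perm, _ = match_states(C, C[shuffle])
        # perm maps A-state i to B-row holding it
        assert np.array_equal(shuffle[perm], np.arange(5))
        relabeled = relabel(np.arange(5), perm)
        assert np.array_equal(C[np.arange(5)], C[shuffle][relabeled])

    def test_noisy_copy_recovers_planted_permutation(self):
        rng = np.random.default_rng(11)
        C = rng.standard_normal((4, 50))
        shuffle = np.array([3, 2, 0, 1])
        noisy = C[shuffle] + rng.normal(0, 0.05, (4, 50))
        perm, corr = match_states(C, noisy)
        assert np.array_equal(shuffle[perm], np.arange(4))
        assert np.all(corr[np.arange(4), perm] > 0.9)

    def test_k_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            match_states(rng.standard_normal((3, 5)), rng.standard_normal((4, 5)))

    def test_similarity_self_and_negation(self, rng):
        M = rng.standard_normal((6, 6))
        M = M + M.T
        assert spatial_similarity(M, M) == pytest.approx(1.0)
        assert spatial_similarity(M, -M) == pytest.approx(-1.0)

    def test_similarity_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spatial_similarity(np.ones((4, 4)), np.eye(4))

    def test_distinct_block_templates_dissimilar(self):
        from dynstates.synthetic import make_state_templates

        tpls = make_state_templates(30, 4)
        assert abs(spatial_similarity(tpls[0].corr, tpls[1].corr)) < 0.3
        # the weak template is constant off-diagonal: similarity undefined
        with pytest.raises(ValueError, match="zero variance"):
            spatial_similarity(tpls[0].corr, tpls[3].corr)


class TestDwellTimes:
    def test_mean_dwell_from_labels(self):
        labels = np.array([0, 0, 0, 1, 1, 0, 2, 2, 2, 2])
        d = dwell_times(labels, 3)
        assert d[0] == pytest.approx(2.0)  # visits of 3 and 1
        assert d[1] == pytest.approx(2.0)
        assert d[2] == pytest.approx(4.0)
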