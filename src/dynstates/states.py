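"""Reoccurring connectivity states: L1 k-means (k-medians) over framewise networks.

Pooled framewise correlation matrices are vectorized (upper triangle, i < j,
row-major), clustered with Lloyd-style alternation under the Manhattan
distance — the centroid update under L1 is the element-wise median — and the
cluster count is chosen by an elbow rule on the ratio of within-cluster to
between-centroid distance. Frames enter clustering as raw correlations (no
Fisher transform).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import pairwise_distances

from .types import (
    DynamicConnectome,
    FrameMatrix,
    StateMatrix,
    StatePartition,
    upper_indices,
)

logger = logging.getLogger(__name__)


def vectorize_frames(connectomes: list[DynamicConnectome]) -> FrameMatrix:
    """Stack all subjects' frames as rows; columns are edges (i<j, row-major)."""
    if not connectomes:
        raise ValueError("no connectomes given")
    node_ids = connectomes[0].node_ids
    for c in connectomes[1:]:
        if not np.array_equal(c.node_ids, node_ids):
            raise ValueError("all connectomes must share node order")
    n = node_ids.size
    iu, ju = upper_indices(n)
    rows, prov = [], []
    for c in connectomes:
        rows.append(c.frames[:, iu, ju])
        prov.append(
            pd.DataFrame(
                dict(subject_id=c.subject_id, run_id=c.run_ids, frame=c.frame_in_run)
            )
        )
    return FrameMatrix(
        data=np.vstack(rows),
        provenance=pd.concat(prov, ignore_index=True),
        n_nodes=n,
    )


def devectorize(row: np.ndarray, n_nodes: int, diag: float = 1.0) -> np.ndarray:
    """Inverse of the edge vectorization: symmetric matrix with fixed diagonal."""
    iu, ju = upper_indices(n_nodes)
    M = np.zeros((n_nodes, n_nodes))
    M[iu, ju] = row
    M[ju, iu] = row
    np.fill_diagonal(M, diag)
    return M


@njit(cache=False)
def _assign_l1(X, C):
    """Nearest-centroid L1 assignment; returns (labels, point distances)."""
    n, m = X.shape
    k = C.shape[0]
    labels = np.empty(n, dtype=np.int64)
    dists = np.empty(n)
    for i in range(n):
        best = 1e300
        arg = 0
        for c in range(k):
            s = 0.0
            for j in range(m):
                diff = X[i, j] - C[c, j]
                s += diff if diff >= 0 else -diff
            if s < best:
                best = s
                arg = c
        labels[i] = arg
        dists[i] = best
    return labels, dists


def _l1_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    return pairwise_distances(X, C, metric="manhattan")


def _kmedians_once(
    X: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    prev_obj = np.inf
    for _ in range(max_iter):
        new_labels, point_dist = _assign_l1(X, centroids)
        # re-seed empty clusters at the farthest point from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(point_dist.argmax())
                centroids[c] = X[far]
                new_labels[far] = c
                point_dist[far] = 0.0
        obj = float(point_dist.sum())
        # L1 objective is non-increasing (up to float32 rounding) by construction
        if obj > prev_obj * (1 + 1e-6) + 1e-6:
            raise AssertionError("k-medians objective increased")
        if np.array_equal(new_labels, labels):
            prev_obj = obj
            labels = new_labels
            break
        labels = new_labels
        prev_obj = obj
        for c in range(k):
            centroids[c] = np.median(X[labels == c], axis=0)
    # final objective at the final centroids
    labels, point_dist = _assign_l1(X, centroids)
    return labels, centroids, float(point_dist.sum())


def kmeans_l1(
    frames: FrameMatrix | np.ndarray,
    k: int,
    n_init: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> StatePartition:
    """Best-of-``n_init`` k-medians partition of the pooled frames.

    Distances are computed in float32 (memory-bandwidth bound at full edge
    dimension); centroids and the objective are reported in float64.
    """
    X = frames.data if isinstance(frames, FrameMatrix) else np.asarray(frames)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    if X32.shape[0] < k:
        raise ValueError("need at least k rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        labels, centroids, obj = _kmedians_once(X32, k, max_iter, rng)
        if best is None or obj < best[2]:
            best = (labels, centroids, obj)
    labels, centroids, obj = best
    return StatePartition(
        k=k, centroids=centroids.astype(np.float64), labels=labels, inertia=obj
    )


def _elbow_ratio(X: np.ndarray, part: StatePartition) -> float:
    """Mean within-cluster L1 distance over mean pairwise between-centroid L1 distance."""
    D = _l1_distances(X, part.centroids)
    within = float(D[np.arange(X.shape[0]), part.labels].mean())
    CC = _l1_distances(part.centroids, part.centroids)
    iu = np.triu_indices(part.k, k=1)
    between = float(CC[iu].mean())
    return within / between


def elbow_select_k(
    frames: FrameMatrix | np.ndarray,
    k_range: range | list[int] = range(2, 9),
    n_init: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[int, dict[int, float], dict[int, StatePartition]]:
    """Elbow selection of the cluster count.

    For each k the within/between dispersion ratio r(k) (mean point-to-own-
    centroid L1 distance over mean pairwise centroid L1 distance) is computed
    from the best k-medians solution and reported as the elbow curve. The
    selected k* is where the objective curve bends hardest: with W(k) the
    total within-cluster L1 distance (W(kmin - 1) is also fit, down to the
    trivial k = 1 solution) and d(k) = W(k-1) - W(k) the successive drop, k*
    maximizes the slope ratio d(k) / d(k+1) over kmin <= k < kmax — the k
    after which adding clusters stops paying. Ties resolve toward smaller k.
    High-dimensional framewise data keep r(k) close to its noise floor, which
    makes curvature rules on r(k) itself unstable; the slope-ratio rule on
    W(k) recovers the generating k on well-separated data. Returns
    (k*, elbow curve, partitions per k).
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range needs at least 3 values")
    if ks[0] < 2:
        raise ValueError("k_range must start at k >= 2")
    if np.any(np.diff(ks) != 1):
        raise ValueError("k_range must be contiguous")
    X = frames.data if isinstance(frames, FrameMatrix) else np.asarray(frames, float)
    curve: dict[int, float] = {}
    parts: dict[int, StatePartition] = {}
    inertia: dict[int, float] = {}
    # reference solution below the range (k = 1 is the global median)
    k0 = ks[0] - 1
    if k0 == 1:
        med = np.median(X, axis=0)
        inertia[1] = float(np.abs(X - med).sum())
    else:
        inertia[k0] = kmeans_l1(X, k0, n_init=n_init, max_iter=max_iter, seed=seed).inertia
    for k in ks:
        part = kmeans_l1(X, k, n_init=n_init, max_iter=max_iter, seed=seed)
        parts[k] = part
        inertia[k] = part.inertia
        curve[k] = _elbow_ratio(X, part)
        logger.info("elbow: k=%d ratio=%.4f inertia=%.1f", k, curve[k], part.inertia)
    floor = 1e-12 * inertia[k0]
    drop = {k: max(inertia[k - 1] - inertia[k], floor) for k in ks}
    slope_ratio = {k: drop[k] / drop[k + 1] for k in ks[:-1]}
    k_star = max(sorted(slope_ratio), key=lambda k: (slope_ratio[k], -k))
    for part in parts.values():
        part.elbow_curve = dict(curve)
    return k_star, curve, parts


def subject_state_medians(
    frames: FrameMatrix, partition: StatePartition
) -> list[StateMatrix]:
    """Element-wise median matrix per subject per state.

    States with no frames for a subject are absent from the result (not
    zero-filled).
    """
    if len(partition.labels) != frames.n_frames:
        raise ValueError("partition labels must cover all frames")
    out: list[StateMatrix] = []
    subjects = frames.provenance["subject_id"].to_numpy()
    for subject in pd.unique(subjects):
        rows = np.flatnonzero(subjects == subject)
        for s in range(partition.k):
            sel = rows[partition.labels[rows] == s]
            if sel.size == 0:
                logger.info("subject %s has no frames in state %d (absent)", subject, s)
                continue
            med = np.median(frames.data[sel], axis=0)
            out.append(
                StateMatrix(
                    subject_id=str(subject),
                    state_id=s,
                    matrix=devectorize(med, frames.n_nodes),
                    n_frames=int(sel.size),
                )
            )
    return out


def group_state_matrix(mats: list[StateMatrix], state_id: int) -> np.ndarray:
    """Group-level state matrix: element-wise median over subjects' medians."""
    stack = [m.matrix for m in mats if m.state_id == state_id]
    if not stack:
        raise ValueError(f"no subject has state {state_id}")
    return np.median(np.stack(stack), axis=0)


def match_states(
    centroids_a: np.ndarray, centroids_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one state correspondence between two centroid sets.

    Maximizes total pairwise Pearson correlation by optimal assignment
    (Hungarian algorithm, not greedy). Returns ``(perm, corr)`` where
    ``perm[i]`` is the state of B matched to state i of A.
    """
    A = np.atleast_2d(np.asarray(centroids_a, float))
    B = np.atleast_2d(np.asarray(centroids_b, float))
    if A.shape != B.shape:
        raise ValueError("centroid sets must share k and edge dimension")
    k = A.shape[0]
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = np.corrcoef(A[i], B[j])[0, 1]
    row, col = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[row] = col
    return perm, corr


def relabel(labels: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Apply a state permutation to a label vector (perm[old] = new)."""
    return np.asarray(perm)[np.asarray(labels)]


def spatial_similarity(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Pearson correlation of the vectorized upper triangles of two matrices."""
    A = np.asarray(mat_a, float)
    B = np.asarray(mat_b, float)
    if A.shape != B.shape:
        raise ValueError("matrices must share shape")
    iu = np.triu_indices(A.shape[0], k=1)
    a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: spatial similarity undefined")
    return float(np.corrcoef(a, b)[0, 1])


def dwell_times(labels: np.ndarray, k: int) -> dict[int, float]:
    """Mean dwell (consecutive frames per visit) per state; convenience only."""
    labels = np.asarray(labels)
    out: dict[int, list[int]] = {s: [] for s in range(k)}
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            out[int(labels[start])].append(t - start)
            start = t
    return {s: (float(np.mean(v)) if v else 0.0) for s, v in out.items()}
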