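"""Independent brute-force oracles used to cross-check the fast implementations.

These deliberately share no code with the package: shortest paths are
Floyd-Warshall with explicit loops, betweenness counts shortest paths by
dynamic programming over the distance matrix, and efficiencies are computed
directly from the definitions.
"""

from __future__ import annotations

import numpy as np

_TIE_TOL = 1e-12


def fw_distances(W: np.ndarray) -> np.ndarray:
    """Floyd-Warshall all-pairs shortest paths over lengths 1/W."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = D[i, k] + D[k, j]
                if via < D[i, j]:
                    D[i, j] = via
    return D


def path_counts(W: np.ndarray, D: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of distinct shortest s-t paths (tie tolerance 1e-12)."""
    n = W.shape[0]
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    order = []
    for s in range(n):
        # accumulate counts over nodes in increasing distance from s
        idx = np.argsort(D[s])
        for v in idx:
            if v == s or not np.isfinite(D[s, v]):
                continue
            total = 0.0
            for u in range(n):
                if u == v or W[u, v] <= 0:
                    continue
                if abs(D[s, u] + 1.0 / W[u, v] - D[s, v]) < _TIE_TOL:
                    total += sigma[s, u]
            sigma[s, v] = total
    return sigma


def brute_betweenness(W: np.ndarray) -> np.ndarray:
    """Normalized betweenness by direct summation of fractional contributions."""
    n = W.shape[0]
    D = fw_distances(W)
    sigma = path_counts(W, D)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t or not np.isfinite(D[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v == s or v == t:
                    continue
                if abs(D[s, v] + D[v, t] - D[s, t]) < _TIE_TOL:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def brute_global_efficiency(W: np.ndarray) -> float:
    D = fw_distances(W)
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def brute_nodal_global_efficiency(W: np.ndarray) -> np.ndarray:
    D = fw_distances(W)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                out[i] += 1.0 / D[i, j]
    return out / (n - 1)


def brute_nodal_local_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if W[i, j] > 0]
        if len(nb) < 2:
            continue
        out[i] = brute_global_efficiency(W[np.ix_(nb, nb)])
    return out


def random_weighted_graph(n: int, rng: np.random.Generator, p_edge: float = 0.5) -> np.ndarray:
    """Random symmetric weight matrix with weights in (0.1, 1)."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = 0.1 + 0.9 * rng.random()
    return W


def ols_residual(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Normal-equations OLS residual via pseudo-inverse (independent of lstsq)."""
    beta = np.linalg.pinv(X.T @ X) @ X.T @ y
    return y - X @ beta
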