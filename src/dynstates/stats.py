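"""Group statistics: edgewise contrasts with NBS correction, FDR, behavioral
PCA composite, and covariate-adjusted partial correlation.

Edgewise contrasts use Welch (unequal-variance) two-sample t tests on the
upper-triangle edges of subject state matrices. Family-wise error over edges
is controlled with the network-based statistic (NBS): edges with p below the
edge threshold form a suprathreshold graph, its connected components are
measured by extent (edge count), and component significance is the
permutation p value of the observed extent against the null distribution of
the maximal component extent under group-label permutation. Components are
formed separately among positive-t (hyper) and negative-t (hypo) edges; the
permutation null takes the maximum over both signs, so the two families are
controlled jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.multivariate.factor_rotation import rotate_factors
from statsmodels.stats.multitest import multipletests

from .types import StateMatrix, upper_indices

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Welch t machinery (vectorized over edges and permutations)
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t and two-sided p per column; a is (na, m), b is (nb, m)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = np.where(se2 > 0, t, 0.0)
    df = np.where(se2 > 0, df, na + nb - 2)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


def _stack_state(mats: list[StateMatrix], state_id: int) -> tuple[np.ndarray, int]:
    keep = [m for m in mats if m.state_id == state_id]
    n_total = len({m.subject_id for m in mats})
    if len(keep) < n_total:
        logger.info(
            "state %d: %d of %d subjects contribute (others absent, excluded)",
            state_id, len(keep), n_total,
        )
    if not keep:
        raise ValueError(f"no subject in this group has state {state_id}")
    n = keep[0].matrix.shape[0]
    iu = upper_indices(n)
    return np.stack([m.matrix[iu] for m in keep]), n


def edgewise_ttest(
    group_a: list[StateMatrix], group_b: list[StateMatrix], state_id: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t per upper-triangle edge; returns (t_matrix, p_matrix)."""
    A, n = _stack_state(group_a, state_id)
    B, n_b = _stack_state(group_b, state_id)
    if n != n_b:
        raise ValueError("groups must share node count")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = _welch_t(A, B)
    iu = upper_indices(n)
    t_mat = np.zeros((n, n))
    p_mat = np.ones((n, n))
    t_mat[iu] = t
    t_mat += t_mat.T
    p_mat[iu] = p
    p_mat = np.minimum(p_mat, p_mat.T)
    np.fill_diagonal(p_mat, 1.0)
    return t_mat, p_mat


# ---------------------------------------------------------------------------
# NBS
# ---------------------------------------------------------------------------

@dataclass
class NbsComponent:
    edges: list[tuple[int, int]]
    size: int          # extent (edge count)
    intensity: float   # sum of |t| over the component's edges
    sign: int          # +1: group A > group B on these edges; -1: reverse
    p_value: float


@dataclass
class NbsResult:
    t_matrix: np.ndarray
    p_matrix: np.ndarray
    components: list[NbsComponent]
    n_perm: int
    seed: int
    statistic: str = "intensity"
    null_max_stat: np.ndarray = field(repr=False, default=None)

    def significant(self, comp_alpha: float = 0.05) -> list[NbsComponent]:
        return [c for c in self.components if c.p_value < comp_alpha]


def _components_by_sign(
    t: np.ndarray, p: np.ndarray, edge_alpha: float, iu: tuple, n: int
) -> list[tuple[list[int], int]]:
    """Connected components of suprathreshold edges, per t-sign.

    Returns a list of (edge-index list, sign)."""
    out = []
    supra = p < edge_alpha
    for sign in (+1, -1):
        sel = np.flatnonzero(supra & ((t > 0) if sign > 0 else (t < 0)))
        if sel.size == 0:
            continue
        rows, cols = iu[0][sel], iu[1][sel]
        adj = csr_matrix((np.ones(sel.size), (rows, cols)), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        edge_comp = labels[rows]
        for c in np.unique(edge_comp):
            out.append((sel[edge_comp == c].tolist(), sign))
    return out


def _component_stat(t: np.ndarray, edge_idx: list[int], statistic: str) -> float:
    if statistic == "extent":
        return float(len(edge_idx))
    return float(np.abs(t[edge_idx]).sum())


def nbs_correct(
    group_a: list[StateMatrix] | np.ndarray,
    group_b: list[StateMatrix] | np.ndarray,
    edge_alpha: float = 0.05,
    comp_alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
    state_id: int = 0,
    statistic: str = "intensity",
) -> NbsResult:
    """Network-based-statistic correction of an edgewise group contrast.

    Groups may be lists of StateMatrix (filtered by ``state_id``) or
    pre-stacked (n_subjects, E) edge arrays. The observed statistic of a
    suprathreshold component is its intensity (sum of |t| over its edges) by
    default, or its extent (edge count) with ``statistic="extent"``; the null
    is the maximal component statistic over ``n_perm`` group-label
    permutations; component p = (1 + #{null >= observed}) / (n_perm + 1).

    Intensity is the default because at a lenient edge threshold (0.05) the
    chance suprathreshold edges alone exceed the percolation threshold of the
    node graph, so the null maximal *extent* is a giant component (~ tens of
    edges) and compact effects can never outgrow it no matter how strong;
    intensity still accumulates evidence from strong true edges.
    """
    if statistic not in ("intensity", "extent"):
        raise ValueError("statistic must be 'intensity' or 'extent'")
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; component p values will be coarse", n_perm)
    if isinstance(group_a, np.ndarray):
        A = np.asarray(group_a, float)
        B = np.asarray(group_b, float)
        E = A.shape[1]
        n = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    else:
        A, n = _stack_state(group_a, state_id)
        B, _ = _stack_state(group_b, state_id)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    iu = upper_indices(n)

    t_obs, p_obs = _welch_t(A, B)
    observed = _components_by_sign(t_obs, p_obs, edge_alpha, iu, n)

    X = np.vstack([A, B])
    na, nb = A.shape[0], B.shape[0]
    n_subj = na + nb
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    X2 = X * X
    tot_sum, tot_sumsq = X.sum(axis=0), X2.sum(axis=0)
    done = 0
    while done < n_perm:  # blocked label permutations: two matmuls per block
        b = min(256, n_perm - done)
        G = np.zeros((b, n_subj))
        for i in range(b):
            G[i, rng.permutation(n_subj)[:na]] = 1.0
        sum_a = G @ X
        sumsq_a = G @ X2
        m_a, m_b = sum_a / na, (tot_sum - sum_a) / nb
        v_a = np.maximum(sumsq_a - na * m_a**2, 0.0) / (na - 1)
        v_b = np.maximum(tot_sumsq - sumsq_a - nb * m_b**2, 0.0) / (nb - 1)
        se2 = v_a / na + v_b / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t_blk = np.where(se2 > 0, (m_a - m_b) / np.sqrt(se2), 0.0)
            df_blk = np.where(
                se2 > 0,
                se2**2 / ((v_a / na) ** 2 / (na - 1) + (v_b / nb) ** 2 / (nb - 1)),
                n_subj - 2,
            )
        p_blk = 2.0 * sps.t.sf(np.abs(t_blk), df_blk)
        for i in range(b):
            comps = _components_by_sign(t_blk[i], p_blk[i], edge_alpha, iu, n)
            if comps:
                null_max[done + i] = max(
                    _component_stat(t_blk[i], e, statistic) for e, _ in comps
                )
        done += b

    components = []
    for edge_idx, sign in observed:
        stat_val = _component_stat(t_obs, edge_idx, statistic)
        p_val = float((1 + np.sum(null_max >= stat_val)) / (n_perm + 1))
        edges = [(int(iu[0][e]), int(iu[1][e])) for e in edge_idx]
        components.append(
            NbsComponent(
                edges=edges, size=len(edge_idx),
                intensity=float(np.abs(t_obs[edge_idx]).sum()),
                sign=sign, p_value=p_val,
            )
        )
    components.sort(key=lambda c: c.p_value)

    t_mat = np.zeros((n, n))
    p_mat = np.ones((n, n))
    t_mat[iu] = t_obs
    t_mat += t_mat.T
    p_mat[iu] = p_obs
    p_mat = np.minimum(p_mat, p_mat.T)
    np.fill_diagonal(p_mat, 1.0)
    return NbsResult(
        t_matrix=t_mat, p_matrix=p_mat, components=components,
        n_perm=n_perm, seed=seed, statistic=statistic, null_max_stat=null_max,
    )


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# behavioral PCA composite
# ---------------------------------------------------------------------------

@dataclass
class BehaviorComposite:
    loadings: pd.DataFrame            # subtest x component (rotated)
    eigenvalues: np.ndarray
    variance_explained: np.ndarray    # fraction per component (all components)
    retained: list[int]
    final_score: pd.Series            # one score per subject
    final_variance_explained: float
    dropped_subtests: list[str] = field(default_factory=list)


def pca_composite(
    behavior: pd.DataFrame, baseline_rows: np.ndarray | None = None
) -> BehaviorComposite:
    """PCA composite of behavioral subtests.

    Subtests are z-scored to the mean/SD of ``baseline_rows`` (e.g. the acute
    sample; all rows if None); PCA is on the correlation matrix; components
    with eigenvalue > 1 and explained variance > 10% are retained and obliquely
    rotated (direct oblimin, gamma = 0); a final PCA on the component scores
    returns exactly one score per subject, sign-oriented so higher = better
    (positive mean loading on the subtests).
    """
    num = behavior.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need at least 2 numeric subtests")
    if num.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if num.isna().any().any():
        raise ValueError("missing values are not handled (imputation out of scope)")
    if baseline_rows is None:
        baseline_rows = np.arange(num.shape[0])
    base = num.iloc[np.asarray(baseline_rows)]
    mu, sd = base.mean(), base.std(ddof=1)
    dropped = sd.index[sd <= 0].tolist()
    if dropped:
        logger.warning("dropping zero-variance subtest(s): %s", dropped)
        num = num.drop(columns=dropped)
        mu, sd = mu.drop(dropped), sd.drop(dropped)
    Z = ((num - mu) / sd).to_numpy()
    m = Z.shape[1]

    corr = np.corrcoef(Z.T)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    var_frac = eigval / m
    retained = [i for i in range(m) if eigval[i] > 1.0 and var_frac[i] > 0.10]
    if not retained:
        retained = [0]  # degenerate flat spectrum: keep the leading component
        logger.warning("no component met eigenvalue>1 & variance>10%%; keeping the first")

    load = eigvec[:, retained] * np.sqrt(eigval[retained])
    if len(retained) > 1:
        load_rot, _ = rotate_factors(load, "quartimin")  # direct oblimin, gamma = 0
    else:
        load_rot = load
    # Thurstone regression scores: Z corr^+ Lambda (pinv: corr may be singular)
    scores = Z @ (np.linalg.pinv(corr, hermitian=True) @ load_rot)

    if scores.shape[1] > 1:
        score_corr = np.corrcoef(scores.T)
        w_val, w_vec = np.linalg.eigh(score_corr)
        w = w_vec[:, -1]
        final = ((scores - scores.mean(0)) / scores.std(0, ddof=1)) @ w
        final_var = float(w_val[-1] / scores.shape[1])
    else:
        final = scores[:, 0]
        final_var = float(var_frac[retained[0]])

    # orient: higher score = better performance on the (z-scored) subtests
    orient = np.sign(np.mean([np.corrcoef(final, Z[:, j])[0, 1] for j in range(m)]))
    if orient < 0:
        final = -final

    index = behavior.index
    return BehaviorComposite(
        loadings=pd.DataFrame(load_rot, index=num.columns,
                              columns=[f"comp{i + 1}" for i in range(load_rot.shape[1])]),
        eigenvalues=eigval,
        variance_explained=var_frac,
        retained=retained,
        final_score=pd.Series(final, index=index, name="composite_score"),
        final_variance_explained=final_var,
        dropped_subtests=dropped,
    )


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def build_covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric design from a covariate table: one-hot categoricals, first level dropped."""
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return X.to_numpy(dtype=float)


def _residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_corr(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Returns (r, p) with p from the t distribution on n - q - 2 degrees of
    freedom (q = number of independent covariate columns). With no covariates
    this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None or (hasattr(covariates, "shape") and np.size(covariates) == 0):
        C = np.empty((n, 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            C = build_covariate_design(covariates)
        else:
            C = np.asarray(covariates, float)
            if C.ndim == 1:
                C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match n")
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("rank-deficient covariates: %d dependent column(s) ignored",
                       X.shape[1] - rank)
    q = rank - 1
    if n <= q + 2:
        raise ValueError("need n > q + 2 observations")
    rx, ry = _residualize(x, X), _residualize(y, X)
    if rx.std() <= 1e-12 * max(1.0, x.std()) or ry.std() <= 1e-12 * max(1.0, y.std()):
        raise ValueError("zero-variance residual: partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - q - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# topological group tests
# ---------------------------------------------------------------------------

def topology_group_tests(
    nodal_a: pd.DataFrame,
    nodal_b: pd.DataFrame,
    metrics: tuple[str, ...] = ("strength", "ge", "le", "bc"),
    q: float = 0.05,
    correction: str = "fdr",
) -> pd.DataFrame:
    """Per-node Welch t tests per state and metric, BH-corrected across nodes
    within each (state, metric) family.

    Inputs are nodal metric tables as produced by
    :func:`dynstates.graph.state_metrics_table`.
    """
    if correction not in ("fdr", "none"):
        raise ValueError("correction must be 'fdr' or 'none'")
    rows = []
    states = sorted(set(nodal_a["state_id"]) & set(nodal_b["state_id"]))
    for state in states:
        sa = nodal_a[nodal_a["state_id"] == state]
        sb = nodal_b[nodal_b["state_id"] == state]
        nodes = sorted(set(sa["node_id"]))
        if nodes != sorted(set(sb["node_id"])):
            raise ValueError("groups must share node sets")
        for metric in metrics:
            A = sa.pivot(index="subject_id", columns="node_id", values=metric).to_numpy()
            B = sb.pivot(index="subject_id", columns="node_id", values=metric).to_numpy()
            t, p = _welch_t(A, B)
            rej = fdr_bh(p, q=q) if correction == "fdr" else p < q
            for node, (tv, pv, rv) in zip(nodes, zip(t, p, rej)):
                rows.append(
                    dict(state_id=state, metric=metric, node_id=node,
                         t=float(tv), p=float(pv), significant=bool(rv))
                )
    return pd.DataFrame(rows)
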