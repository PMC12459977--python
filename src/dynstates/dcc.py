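"""Framewise time-varying correlation via GARCH(1,1) + two-stage DCC.

Stage 1 fits a univariate GARCH(1,1) to each (demeaned) node series by
Gaussian quasi-maximum likelihood,

    sigma2_t = omega + alpha * x_{t-1}^2 + beta * sigma2_{t-1},

and standardizes the series, z_t = x_t / sigma_t. Stage 2 estimates the
dynamic conditional correlation recursion

    q_t = (1 - theta1 - theta2) * sbar + theta1 * z_{t-1} z'_{t-1} + theta2 * q_{t-1},
    r_t = q_t normalized to unit diagonal,

with q_1 = sbar (the sample correlation of the standardized residuals) and
sigma2_1 the sample variance. The exponentially-weighted-moving-average form
of the recursion is the boundary case theta1 + theta2 = 1; the estimated
model keeps theta1 + theta2 < 1 (stationarity).

Stage 2 comes in three modes. ``mode="ewma"`` (the default for framewise
state analysis) uses the boundary form theta1 = 1 - lambda, theta2 = lambda
with a fixed smoothing parameter: it is the exponentially weighted moving
average of the standardized-residual outer products and tracks regime
changes at full amplitude. ``mode="pairwise"`` estimates a bivariate
(theta1, theta2) per edge by quasi-maximum likelihood — the established
ROI-pair formulation for functional-connectivity DCC. ``mode="joint"``
estimates one shared (theta1, theta2) by the full N-dimensional
quasi-likelihood; it degenerates toward static correlation when most edges
do not vary (the shared-parameter penalty on static edges dominates), so it
is not the default. QML-estimated parameters optimize one-step prediction
and therefore shrink the tracked amplitude to theta1/(1 - theta2), which
smears regime switches — the reason the state pipeline uses the EWMA form.
A consequence of edge-wise assembly (ewma/pairwise modes) is that the
emitted R_t is exactly symmetric with unit diagonal and entries in [-1, 1]
but is not guaranteed positive semidefinite.

Optimization is deterministic: a fixed start grid is screened by likelihood
and refined locally (pairwise: shrinking pattern search inside the numba
kernel; joint: Nelder-Mead polish of the best grid points). The returned
optimum dominates the reference points (0, 0) and (0.01, 0.97) by
construction, since both are screened.

Numerical floors: sigma2_t and the diagonal of q_t are floored at 1e-10;
pairwise correlations are clipped at |r| <= 1 - 1e-6 inside the likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .types import DynamicConnectome, RoiTimeSeriesSet, upper_indices

logger = logging.getLogger(__name__)

_STATIONARITY_MARGIN = 1e-6
_VAR_FLOOR = 1e-10
_R_CLIP = 1.0 - 1e-6

# fixed start grids; sums >= 1 are skipped at screen time
_GARCH_START_GRID = [(a, b) for a in (0.05, 0.10, 0.20) for b in (0.50, 0.70, 0.90)]
_DCC_START_GRID = [
    (0.0, 0.0), (0.01, 0.97), (0.02, 0.93), (0.05, 0.90), (0.05, 0.80),
    (0.10, 0.85), (0.10, 0.70), (0.15, 0.80), (0.20, 0.75), (0.30, 0.65),
]


@dataclass
class GarchFit:
    omega: float
    alpha: float
    beta: float
    sigma2_path: np.ndarray
    std_residuals: np.ndarray
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        if self.alpha + self.beta > 1 - _STATIONARITY_MARGIN + 1e-12:
            raise ValueError("alpha + beta violates stationarity margin")
        if np.any(self.sigma2_path <= 0):
            raise ValueError("sigma2 path must be positive everywhere")

    @property
    def unconditional_variance(self) -> float:
        return self.omega / (1.0 - self.alpha - self.beta)


@dataclass
class DccFit:
    """Second-stage DCC parameters.

    ``theta1``/``theta2`` are scalars in joint mode and per-edge arrays
    (upper-triangle order) in pairwise mode.
    """

    theta1: float | np.ndarray
    theta2: float | np.ndarray
    sbar: np.ndarray
    loglik: float
    converged: bool
    mode: str = "pairwise"

    def __post_init__(self) -> None:
        s = np.asarray(self.theta1) + np.asarray(self.theta2)
        limit = 1.0 + 1e-12 if self.mode == "ewma" else 1 - _STATIONARITY_MARGIN + 1e-9
        if np.any(s > limit):
            raise ValueError("theta1 + theta2 violates stationarity margin")
        if not np.allclose(self.sbar, self.sbar.T, atol=1e-10):
            raise ValueError("sbar must be symmetric")


# ---------------------------------------------------------------------------
# numba kernels: GARCH
# ---------------------------------------------------------------------------

@njit(cache=False)
def _garch_negll(x, omega, alpha, beta, sigma2_0):
    T = x.shape[0]
    s = sigma2_0
    nll = 0.0
    log2pi = 1.8378770664093453
    nll += 0.5 * (log2pi + np.log(s) + x[0] * x[0] / s)
    for t in range(1, T):
        s = omega + alpha * x[t - 1] * x[t - 1] + beta * s
        if s < _VAR_FLOOR:
            s = _VAR_FLOOR
        nll += 0.5 * (log2pi + np.log(s) + x[t] * x[t] / s)
    return nll


@njit(cache=False)
def _garch_filter(x, omega, alpha, beta, sigma2_0):
    T = x.shape[0]
    path = np.empty(T)
    path[0] = sigma2_0
    for t in range(1, T):
        s = omega + alpha * x[t - 1] * x[t - 1] + beta * path[t - 1]
        path[t] = s if s > _VAR_FLOOR else _VAR_FLOOR
    return path


# ---------------------------------------------------------------------------
# numba kernels: pairwise DCC
# ---------------------------------------------------------------------------

@njit(cache=False, inline="always")
def _pair_negll(z1, z2, sbar, t1, t2):
    T = z1.shape[0]
    q11 = 1.0
    q22 = 1.0
    q12 = sbar
    nll = 0.0
    for t in range(T):
        d = q11 * q22
        if d < _VAR_FLOOR:
            d = _VAR_FLOOR
        r = q12 / np.sqrt(d)
        if r > _R_CLIP:
            r = _R_CLIP
        elif r < -_R_CLIP:
            r = -_R_CLIP
        om = 1.0 - r * r
        a = z1[t]
        b = z2[t]
        nll += 0.5 * (np.log(om) + (a * a + b * b - 2.0 * r * a * b) / om - a * a - b * b)
        one = 1.0 - t1 - t2
        q11 = one + t1 * a * a + t2 * q11
        q22 = one + t1 * b * b + t2 * q22
        q12 = one * sbar + t1 * a * b + t2 * q12
    return nll


@njit(cache=False)
def _pair_dcc_fit_all(Z, sbar_vec, iu, ju, grid):
    """Per-edge (theta1, theta2) by grid screen + shrinking pattern search."""
    E = iu.shape[0]
    theta = np.empty((E, 2))
    nll_out = np.empty(E)
    for e in range(E):
        z1 = Z[:, iu[e]]
        z2 = Z[:, ju[e]]
        sb = sbar_vec[e]
        best_nll = 1e300
        b1 = 0.0
        b2 = 0.0
        for g in range(grid.shape[0]):
            t1 = grid[g, 0]
            t2 = grid[g, 1]
            if t1 + t2 >= 1.0 - _STATIONARITY_MARGIN and t1 + t2 > 0.0:
                continue
            v = _pair_negll(z1, z2, sb, t1, t2)
            if v < best_nll:
                best_nll = v
                b1 = t1
                b2 = t2
        step1 = 0.04
        step2 = 0.08
        for _ in range(4):
            improved = True
            while improved:
                improved = False
                for d1 in (-step1, 0.0, step1):
                    for d2 in (-step2, 0.0, step2):
                        if d1 == 0.0 and d2 == 0.0:
                            continue
                        t1 = b1 + d1
                        t2 = b2 + d2
                        if t1 < 0.0 or t2 < 0.0 or t1 + t2 > 1.0 - _STATIONARITY_MARGIN:
                            continue
                        v = _pair_negll(z1, z2, sb, t1, t2)
                        if v < best_nll - 1e-9:
                            best_nll = v
                            b1 = t1
                            b2 = t2
                            improved = True
            step1 *= 0.35
            step2 *= 0.35
        theta[e, 0] = b1
        theta[e, 1] = b2
        nll_out[e] = best_nll
    return theta, nll_out


@njit(cache=False)
def _pair_dcc_path(Z, sbar_vec, theta, iu, ju):
    """Edge-wise correlation paths r_t under per-pair recursions; (T, E)."""
    T = Z.shape[0]
    E = iu.shape[0]
    out = np.empty((T, E))
    for e in range(E):
        z1 = Z[:, iu[e]]
        z2 = Z[:, ju[e]]
        sb = sbar_vec[e]
        t1 = theta[e, 0]
        t2 = theta[e, 1]
        q11 = 1.0
        q22 = 1.0
        q12 = sb
        one = 1.0 - t1 - t2
        for t in range(T):
            d = q11 * q22
            if d < _VAR_FLOOR:
                d = _VAR_FLOOR
            r = q12 / np.sqrt(d)
            if r > 1.0:
                r = 1.0
            elif r < -1.0:
                r = -1.0
            out[t, e] = r
            a = z1[t]
            b = z2[t]
            q11 = one + t1 * a * a + t2 * q11
            q22 = one + t1 * b * b + t2 * q22
            q12 = one * sb + t1 * a * b + t2 * q12
    return out


# ---------------------------------------------------------------------------
# numba kernels: joint DCC
# ---------------------------------------------------------------------------

@njit(cache=False)
def _dcc_negll_joint(Z, Sbar, t1, t2):
    T, N = Z.shape
    Q = Sbar.copy()
    d = np.empty(N)
    w = np.empty(N)
    nll = 0.0
    for t in range(T):
        for i in range(N):
            qi = Q[i, i]
            d[i] = np.sqrt(qi if qi > _VAR_FLOOR else _VAR_FLOOR)
        R = np.empty((N, N))
        for i in range(N):
            for j in range(N):
                R[i, j] = Q[i, j] / (d[i] * d[j])
        L = np.linalg.cholesky(R)
        z = Z[t]
        for i in range(N):
            s = z[i]
            for j in range(i):
                s -= L[i, j] * w[j]
            w[i] = s / L[i, i]
        logdet = 0.0
        quad = 0.0
        zz = 0.0
        for i in range(N):
            logdet += 2.0 * np.log(L[i, i])
            quad += w[i] * w[i]
            zz += z[i] * z[i]
        nll += 0.5 * (logdet + quad - zz)
        for i in range(N):
            for j in range(N):
                Q[i, j] = (1.0 - t1 - t2) * Sbar[i, j] + t1 * z[i] * z[j] + t2 * Q[i, j]
    return nll


@njit(cache=False)
def _dcc_path_joint(Z, Sbar, t1, t2):
    T, N = Z.shape
    Q = Sbar.copy()
    d = np.empty(N)
    out = np.empty((T, N, N))
    for t in range(T):
        for i in range(N):
            qi = Q[i, i]
            d[i] = np.sqrt(qi if qi > _VAR_FLOOR else _VAR_FLOOR)
        for i in range(N):
            for j in range(N):
                out[t, i, j] = Q[i, j] / (d[i] * d[j])
        z = Z[t]
        for i in range(N):
            for j in range(N):
                Q[i, j] = (1.0 - t1 - t2) * Sbar[i, j] + t1 * z[i] * z[j] + t2 * Q[i, j]
    return out


# ---------------------------------------------------------------------------
# stationarity-preserving reparameterization (joint mode / GARCH polish)
# ---------------------------------------------------------------------------

def _sigmoid(u: float) -> float:
    from scipy.special import expit

    return float(expit(u))

def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))

def _pair_from_u(u1: float, u2: float) -> tuple[float, float]:
    total = _sigmoid(u1) * (1.0 - _STATIONARITY_MARGIN)
    frac = _sigmoid(u2)
    return total * frac, total * (1.0 - frac)

def _u_from_pair(a: float, b: float) -> tuple[float, float]:
    total = min(a + b, 1.0 - _STATIONARITY_MARGIN)
    frac = a / total if total > 0 else 0.5
    return _logit(total / (1.0 - _STATIONARITY_MARGIN)), _logit(frac)


# ---------------------------------------------------------------------------
# stage 1: univariate GARCH(1,1)
# ---------------------------------------------------------------------------

def fit_garch11(x: np.ndarray) -> GarchFit:
    """Quasi-maximum-likelihood GARCH(1,1) fit to a single demeaned series."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 50:
        raise ValueError("need at least 50 frames to fit GARCH(1,1)")
    var = float(np.var(x))
    if var <= 0:
        raise ValueError("constant series: GARCH fit undefined")
    sigma2_0 = var

    def negll_params(omega: float, alpha: float, beta: float) -> float:
        return _garch_negll(x, omega, alpha, beta, sigma2_0)

    def negll_u(u: np.ndarray) -> float:
        omega = np.exp(u[0])
        alpha, beta = _pair_from_u(u[1], u[2])
        return negll_params(omega, alpha, beta)

    candidates: list[tuple[float, tuple[float, float, float]]] = []
    starts = []
    for a, b in _GARCH_START_GRID:
        if a + b >= 1 - _STATIONARITY_MARGIN:
            continue
        omega = var * (1 - a - b)
        nll = negll_params(omega, a, b)
        candidates.append((nll, (omega, a, b)))
        starts.append((nll, (omega, a, b)))
    # constant-variance reference point
    candidates.append((negll_params(var, 0.0, 0.0), (var, 0.0, 0.0)))

    starts.sort(key=lambda s: s[0])
    any_converged = False
    for _nll0, (omega, a, b) in starts[:2]:
        u0 = np.array([np.log(omega), *_u_from_pair(a, b)])
        res = minimize(negll_u, u0, method="Nelder-Mead",
                       options=dict(maxiter=600, xatol=1e-6, fatol=1e-8))
        omega_hat = float(np.exp(res.x[0]))
        alpha_hat, beta_hat = _pair_from_u(res.x[1], res.x[2])
        candidates.append((float(res.fun), (omega_hat, alpha_hat, beta_hat)))
        any_converged = any_converged or bool(res.success)

    best_nll, (omega, alpha, beta) = min(candidates, key=lambda c: c[0])
    if not any_converged:
        logger.warning("GARCH(1,1) optimizer did not converge; returning best point")
    path = _garch_filter(x, omega, alpha, beta, sigma2_0)
    return GarchFit(
        omega=omega, alpha=alpha, beta=beta,
        sigma2_path=path, std_residuals=x / np.sqrt(path),
        loglik=-best_nll, converged=any_converged,
    )


# ---------------------------------------------------------------------------
# stage 2: DCC
# ---------------------------------------------------------------------------

def _regularized_sbar(Z: np.ndarray) -> np.ndarray:
    Sbar = np.corrcoef(Z.T)
    lam = np.linalg.eigvalsh(Sbar)[0]
    if lam < 1e-8:
        eps = min(1e-4, max(1e-6, 2 * (1e-8 - lam)))
        logger.warning(
            "Sbar nearly singular (min eigenvalue %.3g); shrinking toward identity (eps=%.1e)",
            lam, eps,
        )
        Sbar = (1 - eps) * Sbar + eps * np.eye(Sbar.shape[0])
        np.fill_diagonal(Sbar, 1.0)
    logger.debug("Sbar condition number: %.3g", np.linalg.cond(Sbar))
    return Sbar


def _check_standardized(Z: np.ndarray) -> None:
    col_var = Z.var(axis=0)
    if np.any(col_var < 0.5) or np.any(col_var > 2.0):
        bad = np.flatnonzero((col_var < 0.5) | (col_var > 2.0))
        raise ValueError(
            f"columns {bad.tolist()} of Z are not standardized (sample variance "
            f"outside [0.5, 2]); fit GARCH first"
        )


DEFAULT_EWMA_LAMBDA = 0.7


def fit_dcc(
    Z: np.ndarray,
    fixed_theta: tuple[float, float] | None = None,
    mode: str = "pairwise",
    ewma_lambda: float = DEFAULT_EWMA_LAMBDA,
) -> DccFit:
    """Second-stage DCC fit on standardized residuals.

    ``mode="pairwise"`` (default) estimates a bivariate (theta1, theta2) per
    edge by quasi-maximum likelihood; ``mode="joint"`` estimates one shared
    pair by the N-dimensional quasi-likelihood; ``mode="ewma"`` uses the
    boundary form theta1 = 1 - lambda, theta2 = lambda with a fixed smoothing
    parameter (no estimation) — the formulation that tracks regime changes at
    full amplitude, which the framewise-state analysis uses by default.
    ``fixed_theta`` skips optimization and evaluates the joint recursion at
    the given parameters.
    """
    Z = np.ascontiguousarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("Z must be (frames, N) with N >= 2")
    T, N = Z.shape
    if T < 50:
        raise ValueError("need at least 50 frames to fit DCC")
    _check_standardized(Z)
    Sbar = _regularized_sbar(Z)

    if fixed_theta is not None:
        t1, t2 = fixed_theta
        nll = _dcc_negll_joint(Z, Sbar, t1, t2)
        return DccFit(theta1=t1, theta2=t2, sbar=Sbar, loglik=-nll,
                      converged=True, mode="joint")

    if mode == "ewma":
        if not 0 < ewma_lambda < 1:
            raise ValueError("ewma_lambda must lie in (0, 1)")
        t1, t2 = 1.0 - ewma_lambda, ewma_lambda
        ll = dcc_loglik(Z, Sbar, t1, t2, mode="pairwise")
        return DccFit(theta1=t1, theta2=t2, sbar=Sbar, loglik=ll,
                      converged=True, mode="ewma")

    if mode == "pairwise":
        iu, ju = upper_indices(N)
        grid = np.array(_DCC_START_GRID)
        theta, nll = _pair_dcc_fit_all(
            Z, Sbar[iu, ju].copy(), iu.astype(np.int64), ju.astype(np.int64), grid
        )
        return DccFit(theta1=theta[:, 0], theta2=theta[:, 1], sbar=Sbar,
                      loglik=float(-nll.sum()), converged=True, mode="pairwise")

    if mode != "joint":
        raise ValueError("mode must be 'pairwise' or 'joint'")

    candidates: list[tuple[float, tuple[float, float]]] = []
    starts = []
    for a, b in _DCC_START_GRID:
        if a + b >= 1 - _STATIONARITY_MARGIN and a + b > 0:
            continue
        nll = _dcc_negll_joint(Z, Sbar, a, b)
        candidates.append((nll, (a, b)))
        if a + b > 0:
            starts.append((nll, (a, b)))

    def negll_u(u: np.ndarray) -> float:
        t1, t2 = _pair_from_u(u[0], u[1])
        return _dcc_negll_joint(Z, Sbar, t1, t2)

    starts.sort(key=lambda s: s[0])
    any_converged = False
    for _nll0, (a, b) in starts[:2]:
        u0 = np.array(_u_from_pair(a, b))
        res = minimize(negll_u, u0, method="Nelder-Mead",
                       options=dict(maxiter=200, xatol=1e-5, fatol=1e-7))
        t1, t2 = _pair_from_u(res.x[0], res.x[1])
        candidates.append((float(res.fun), (t1, t2)))
        any_converged = any_converged or bool(res.success)
    if not any_converged:
        logger.warning("DCC optimizer did not converge; returning best point")

    best_nll, (t1, t2) = min(candidates, key=lambda c: c[0])
    return DccFit(theta1=t1, theta2=t2, sbar=Sbar, loglik=-best_nll,
                  converged=any_converged, mode="joint")


def dcc_loglik(Z: np.ndarray, sbar: np.ndarray, theta1, theta2, mode: str = "pairwise") -> float:
    """Stage-2 quasi-log-likelihood at given parameters (for diagnostics/tests)."""
    Z = np.ascontiguousarray(Z, dtype=float)
    if mode == "joint":
        return float(-_dcc_negll_joint(Z, sbar, float(theta1), float(theta2)))
    iu, ju = upper_indices(Z.shape[1])
    t1 = np.broadcast_to(np.asarray(theta1, float), iu.shape).astype(float)
    t2 = np.broadcast_to(np.asarray(theta2, float), iu.shape).astype(float)
    total = 0.0
    for e in range(iu.size):
        total -= _pair_negll(
            Z[:, iu[e]].copy(), Z[:, ju[e]].copy(), sbar[iu[e], ju[e]], t1[e], t2[e]
        )
    return float(total)


def dcc_correlation_path(
    Z: np.ndarray, fit: DccFit, bidirectional: bool = False
) -> np.ndarray:
    """Framewise correlation matrices R_t under a fitted DCC recursion.

    ``bidirectional=True`` averages the causal (forward) path with the path
    of the time-reversed series — a zero-phase variant that centers the
    effective estimation window on each frame instead of lagging behind it
    (the same rationale as forward-backward filtering) and halves the
    estimation variance. Offline state analysis uses this by default.
    """
    if bidirectional:
        Rf = dcc_correlation_path(Z, fit, bidirectional=False)
        Rb = dcc_correlation_path(np.ascontiguousarray(Z[::-1]), fit,
                                  bidirectional=False)[::-1]
        R = 0.5 * (Rf + Rb)
        ii = np.arange(R.shape[1])
        R[:, ii, ii] = 1.0
        return R
    Z = np.ascontiguousarray(Z, dtype=float)
    T, N = Z.shape
    if fit.mode == "joint":
        R = _dcc_path_joint(Z, fit.sbar, float(fit.theta1), float(fit.theta2))
        R = 0.5 * (R + np.swapaxes(R, 1, 2))
    else:
        iu, ju = upper_indices(N)
        theta = np.column_stack([
            np.broadcast_to(np.asarray(fit.theta1, float), iu.shape),
            np.broadcast_to(np.asarray(fit.theta2, float), iu.shape),
        ])
        edge_paths = _pair_dcc_path(
            Z, fit.sbar[iu, ju].copy(), theta, iu.astype(np.int64), ju.astype(np.int64)
        )
        R = np.empty((T, N, N))
        R[:, iu, ju] = edge_paths
        R[:, ju, iu] = edge_paths
    np.clip(R, -1.0, 1.0, out=R)
    ii = np.arange(N)
    R[:, ii, ii] = 1.0
    return R


# ---------------------------------------------------------------------------
# per-subject driver + static complement
# ---------------------------------------------------------------------------

def dynamic_connectome(
    ts: RoiTimeSeriesSet,
    mode: str = "ewma",
    ewma_lambda: float = DEFAULT_EWMA_LAMBDA,
    bidirectional: bool = True,
) -> tuple[DynamicConnectome, list[GarchFit], DccFit]:
    """Framewise time-varying correlation network for one subject.

    Runs are demeaned per run and concatenated; one GARCH(1,1) fit per node
    on the concatenated series, then the stage-2 DCC fit, with the recursions
    run straight through run boundaries. Frame provenance (run_id,
    frame-within-run) is retained so callers can drop per-run burn-in frames
    downstream.
    """
    X = ts.concatenated(demean_per_run=True)
    T, N = X.shape
    garch_fits: list[GarchFit] = []
    Z = np.empty_like(X)
    for i in range(N):
        if np.var(X[:, i]) <= 0:
            raise ValueError(f"node {ts.node_ids[i]} is constant; cannot standardize")
        fit = fit_garch11(X[:, i])
        garch_fits.append(fit)
        Z[:, i] = fit.std_residuals
    dcc_fit = fit_dcc(Z, mode=mode, ewma_lambda=ewma_lambda)
    R = dcc_correlation_path(Z, dcc_fit, bidirectional=bidirectional)

    run_ids = np.concatenate(
        [np.repeat(rid, run.shape[0]) for rid, run in zip(ts.run_ids, ts.runs)]
    )
    frame_in_run = np.concatenate([np.arange(run.shape[0]) for run in ts.runs])
    conn = DynamicConnectome(
        frames=R, run_ids=run_ids, frame_in_run=frame_in_run,
        node_ids=ts.node_ids, subject_id=ts.subject_id,
    )
    return conn, garch_fits, dcc_fit


def static_fc(ts: RoiTimeSeriesSet) -> np.ndarray:
    """Static functional connectivity: Pearson correlation over all frames."""
    X = ts.concatenated(demean_per_run=True)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 frames for static FC")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant node(s) {ts.node_ids[bad].tolist()}: correlation undefined")
    C = np.corrcoef(X.T)
    np.fill_diagonal(C, 1.0)
    return C
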