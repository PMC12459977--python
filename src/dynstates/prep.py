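"""Optional denoising of extracted ROI time series.

Replicates the signal-level preprocessing applied before network
construction: linear detrending, nuisance (confound) regression, and
temporal band-pass filtering. Runs are processed independently — no
cross-run concatenation before filtering — to avoid boundary artifacts.
The canonical order is detrend -> nuisance regression -> band-pass.

The band-pass is a zero-phase forward-backward 4th-order Butterworth
filter (no phase distortion); confound regressors themselves are not
filtered.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .types import RoiTimeSeriesSet

logger = logging.getLogger(__name__)


def detrend_linear(ts: RoiTimeSeriesSet) -> RoiTimeSeriesSet:
    """Remove the per-run, per-node least-squares line (intercept + slope*t)."""
    for run_id, run in zip(ts.run_ids, ts.runs):
        if run.shape[0] < 3:
            raise ValueError(f"run {run_id!r}: need >= 3 frames to detrend")

    def _detrend(run: np.ndarray, run_id: str) -> np.ndarray:
        t = np.arange(run.shape[0], dtype=float)
        X = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(X, run, rcond=None)
        return run - X @ coef

    return ts.map_runs(_detrend)


def regress_nuisance(
    ts: RoiTimeSeriesSet, confounds: dict[str, np.ndarray] | list[np.ndarray]
) -> RoiTimeSeriesSet:
    """OLS residuals of every node signal on [1, confounds], per run.

    ``confounds`` maps run_id -> (frames, q) matrix (or is a list parallel to
    the runs). Rank-deficient designs have their dependent columns dropped
    with a logged warning. Residuals are orthogonal to every kept column.
    """
    if isinstance(confounds, dict):
        conf_map = confounds
    else:
        conf_map = dict(zip(ts.run_ids, confounds))

    def _regress(run: np.ndarray, run_id: str) -> np.ndarray:
        C = np.asarray(conf_map[run_id], dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != run.shape[0]:
            raise ValueError(
                f"run {run_id!r}: confound rows {C.shape[0]} != frames {run.shape[0]}"
            )
        if C.shape[1] >= run.shape[0]:
            raise ValueError(f"run {run_id!r}: need q < frames")
        X = np.column_stack([np.ones(run.shape[0]), C])
        # drop linearly dependent columns via pivoted QR rank detection
        q, r, piv = _qr_rank(X)
        if len(piv) < X.shape[1]:
            dropped = sorted(set(range(X.shape[1])) - set(piv))
            logger.warning(
                "run %s: dropping %d linearly dependent confound column(s): %s",
                run_id, X.shape[1] - len(piv), dropped,
            )
            X = X[:, piv]
        beta, *_ = np.linalg.lstsq(X, run, rcond=None)
        return run - X @ beta

    return ts.map_runs(_regress)


def _qr_rank(X: np.ndarray, tol: float | None = None) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Column-pivoted QR; returns (Q, R, independent column indices in original order)."""
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if tol is None:
        tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    keep = sorted(piv[:rank].tolist())
    return q, r, keep


def bandpass(
    ts: RoiTimeSeriesSet, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 4
) -> RoiTimeSeriesSet:
    """Zero-phase Butterworth band-pass per run and node.

    Frequencies are in Hz; the Nyquist frequency is 1/(2*tr). A sinusoid
    inside the band retains >= 90% amplitude; one well outside retains <= 10%
    (steady state, edges excluded).
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be < Nyquist {nyquist}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr, output="sos")

    def _filter(run: np.ndarray, run_id: str) -> np.ndarray:
        return signal.sosfiltfilt(sos, run, axis=0)

    return ts.map_runs(_filter)


def preprocess(
    ts: RoiTimeSeriesSet,
    confounds: dict[str, np.ndarray] | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> RoiTimeSeriesSet:
    """Canonical order: detrend -> nuisance regression (if given) -> band-pass."""
    out = detrend_linear(ts)
    if confounds is not None:
        out = regress_nuisance(out, confounds)
    return bandpass(out, low_hz=low_hz, high_hz=high_hz)
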