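"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* node indices are 0-based and contiguous;
* edge vectorization is the upper triangle (i < j) in row-major order,
  i.e. (0,1), (0,2), ..., (0,N-1), (1,2), ...;
* every correlation matrix is symmetric with unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd


@dataclass
class RoiTimeSeriesSet:
    """One subject's resting-state runs of ROI signals.

    Parameters
    ----------
    subject_id
        Subject identifier.
    runs
        One ``(frames, n_nodes)`` float array per run.
    run_ids
        Run identifiers, parallel to ``runs``.
    tr
        Sampling interval (repetition time) in seconds.
    node_ids
        Node identifiers in column order, shared by all runs.
    """

    subject_id: str
    runs: list[np.ndarray]
    run_ids: list[str]
    tr: float
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        if len(self.runs) != len(self.run_ids):
            raise ValueError("runs and run_ids must be parallel")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        n = self.node_ids.size
        for run_id, run in zip(self.run_ids, self.runs):
            run = np.asarray(run, dtype=float)
            if run.ndim != 2 or run.shape[1] != n:
                raise ValueError(
                    f"run {run_id!r}: expected (frames, {n}) matrix, got {run.shape}"
                )
            if run.shape[0] < 2:
                raise ValueError(f"run {run_id!r}: need at least 2 frames")
            if not np.all(np.isfinite(run)):
                raise ValueError(f"run {run_id!r}: non-finite values present")

    @property
    def n_nodes(self) -> int:
        return self.node_ids.size

    @property
    def n_frames_total(self) -> int:
        return sum(run.shape[0] for run in self.runs)

    def concatenated(self, demean_per_run: bool = True) -> np.ndarray:
        """All runs stacked along time, optionally demeaned per run."""
        blocks = []
        for run in self.runs:
            run = np.asarray(run, dtype=float)
            if demean_per_run:
                run = run - run.mean(axis=0, keepdims=True)
            blocks.append(run)
        return np.vstack(blocks)

    def map_runs(self, fn) -> "RoiTimeSeriesSet":
        """New set with ``fn(run_matrix, run_id)`` applied to every run."""
        new_runs = [np.asarray(fn(run, rid), dtype=float) for run, rid in zip(self.runs, self.run_ids)]
        return RoiTimeSeriesSet(
            subject_id=self.subject_id,
            runs=new_runs,
            run_ids=list(self.run_ids),
            tr=self.tr,
            node_ids=self.node_ids.copy(),
        )


@dataclass
class StateTemplate:
    """A ground-truth correlation pattern for one latent connectivity state."""

    template_id: int
    corr: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        C = np.asarray(self.corr, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("template corr must be square")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("template corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("template corr must have unit diagonal")
        if np.any(np.abs(C) > 1 + 1e-12):
            raise ValueError("template corr entries must lie in [-1, 1]")
        lam = float(np.linalg.eigvalsh(C)[0])
        if lam <= 0:
            raise ValueError(
                f"template {self.template_id} is not positive definite "
                f"(min eigenvalue {lam:.3g})"
            )
        self.corr = C

    @property
    def n_nodes(self) -> int:
        return self.corr.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.corr)[0])


@dataclass
class BehaviorCoupling:
    """Linear coupling of the behavioral score to planted effect-edge strength.

    score = intercept + slope_hypo * mean(hypo-edge strength)
                      - slope_hyper * mean(hyper-edge strength) + N(0, noise_sd)

    so that hypo-connectivity correlates positively and hyper-connectivity
    negatively with the score (higher score = better performance).
    """

    intercept: float = 0.0
    slope_hypo: float = 8.0
    slope_hyper: float = 8.0
    noise_sd: float = 0.2


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``effect_edges`` lists planted group differences as
    ``(state_id, i, j, delta)``: patients' template for ``state_id`` has
    ``delta`` added at edge (i, j). Negative deltas are hypo-connectivity,
    positive deltas hyper-connectivity.
    """

    n_controls: int = 20
    n_patients: int = 20
    n_nodes: int = 104
    templates: list[StateTemplate] = field(default_factory=list)
    dwell_mean: float = 20.0
    runs_per_subject: int = 6
    frames_per_run: int = 118
    tr: float = 2.0
    garch_params: tuple[float, float, float] = (0.1, 0.1, 0.8)
    effect_edges: list[tuple[int, int, int, float]] = field(default_factory=list)
    behavior_coupling: BehaviorCoupling = field(default_factory=BehaviorCoupling)
    seed: int = 0

    def __post_init__(self) -> None:
        omega, alpha, beta = self.garch_params
        if omega <= 0 or alpha < 0 or beta < 0:
            raise ValueError("garch_params: need omega > 0, alpha >= 0, beta >= 0")
        if alpha + beta >= 1:
            raise ValueError("garch_params: alpha + beta must be < 1 (stationarity)")
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_controls + self.n_patients == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 frame")
        for t in self.templates:
            if t.n_nodes != self.n_nodes:
                raise ValueError("template size does not match n_nodes")

    @property
    def k(self) -> int:
        return len(self.templates)

    def hypo_edges(self) -> list[tuple[int, int, int, float]]:
        return [e for e in self.effect_edges if e[3] < 0]

    def hyper_edges(self) -> list[tuple[int, int, int, float]]:
        return [e for e in self.effect_edges if e[3] > 0]


@dataclass
class GroundTruth:
    """Latent quantities of a simulated cohort.

    ``labels[subject_id][run_id]`` is the per-frame latent state path.
    """

    labels: dict[str, dict[str, np.ndarray]]
    effect_edges: list[tuple[int, int, int, float]]
    coupling: BehaviorCoupling

    def subject_labels(self, subject_id: str) -> np.ndarray:
        runs = self.labels[subject_id]
        return np.concatenate([runs[rid] for rid in sorted(runs)])


@dataclass
class DynamicConnectome:
    """Frame-indexed sequence of full correlation matrices from DCC."""

    frames: np.ndarray          # (T, N, N)
    run_ids: np.ndarray         # (T,) run id per frame
    frame_in_run: np.ndarray    # (T,) frame index within its run
    node_ids: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        T = self.frames.shape[0]
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be (T, N, N)")
        if len(self.run_ids) != T or len(self.frame_in_run) != T:
            raise ValueError("frame provenance must cover every frame")
        self.run_ids = np.asarray(self.run_ids)
        self.frame_in_run = np.asarray(self.frame_in_run, dtype=int)
        self.node_ids = np.asarray(self.node_ids, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.frames.shape[1]

    def validate(self, psd_tol: float | None = None) -> None:
        """Check symmetry, unit diagonal and range of every frame.

        Pass ``psd_tol`` (e.g. 1e-8) to additionally check positive
        semidefiniteness; pairwise-assembled DCC frames are not guaranteed
        PSD, so this check is opt-in.
        """
        F = self.frames
        if not np.allclose(F, np.swapaxes(F, 1, 2), atol=1e-10):
            raise ValueError("non-symmetric correlation frame")
        diags = F[:, np.arange(F.shape[1]), np.arange(F.shape[1])]
        if not np.allclose(diags, 1.0, atol=1e-10):
            raise ValueError("frame diagonal differs from 1")
        if np.any(np.abs(F) > 1 + 1e-10):
            raise ValueError("correlation outside [-1, 1]")
        if psd_tol is not None:
            for t in range(F.shape[0]):
                lam = np.linalg.eigvalsh(F[t])[0]
                if lam < -psd_tol:
                    raise ValueError(f"frame {t} not PSD (min eigenvalue {lam:.3g})")

    def drop_burnin(self, n_burnin: int) -> "DynamicConnectome":
        """Drop the first ``n_burnin`` frames of every run (recursion burn-in)."""
        keep = self.frame_in_run >= n_burnin
        return DynamicConnectome(
            frames=self.frames[keep],
            run_ids=self.run_ids[keep],
            frame_in_run=self.frame_in_run[keep],
            node_ids=self.node_ids,
            subject_id=self.subject_id,
        )


@dataclass
class FrameMatrix:
    """Pooled framewise connectomes, one row per frame, columns = edges (i < j)."""

    data: np.ndarray           # (T_total, E)
    provenance: pd.DataFrame   # columns subject_id, run_id, frame
    n_nodes: int

    def __post_init__(self) -> None:
        E = self.n_nodes * (self.n_nodes - 1) // 2
        if self.data.shape[1] != E:
            raise ValueError(f"expected {E} edge columns for {self.n_nodes} nodes")
        if len(self.provenance) != self.data.shape[0]:
            raise ValueError("provenance must cover every row exactly once")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def rows_for_subject(self, subject_id: str) -> np.ndarray:
        return np.flatnonzero((self.provenance["subject_id"] == subject_id).to_numpy())


@dataclass
class StatePartition:
    """Result of decomposing pooled frames into k reoccurring states."""

    k: int
    centroids: np.ndarray             # (k, E)
    labels: np.ndarray                # (T_total,)
    inertia: float
    elbow_curve: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.k:
            raise ValueError("labels outside {0..k-1}")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        counts = np.bincount(self.labels, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("every state must be nonempty")


@dataclass
class StateMatrix:
    """One subject's median connectivity matrix for one state."""

    subject_id: str
    state_id: int
    matrix: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("state matrix must be symmetric")
        if self.n_frames < 1:
            raise ValueError(
                "states with no contributing frames are absent, not zero-filled"
            )
        self.matrix = M


def upper_indices(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the documented edge order (i < j, row-major)."""
    return np.triu_indices(n_nodes, k=1)


def edge_columns(n_nodes: int) -> list[tuple[int, int]]:
    iu, ju = upper_indices(n_nodes)
    return list(zip(iu.tolist(), ju.tolist()))
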