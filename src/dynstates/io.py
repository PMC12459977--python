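"""Plain-text file formats and the run configuration.

Everything is TSV/JSON: node tables, per-run time-series matrices (rows =
frames, columns = node ids in node-table order; gzip accepted), ground-truth
JSON, connectome long TSV (upper triangle, i < j) with a JSON sidecar,
partition JSON + centroid TSV, metric tables, and binary meta-mask TSVs.
Floats are written at full repr precision so read(write(x)) round-trips
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DynamicConnectome,
    FrameMatrix,
    GroundTruth,
    RoiTimeSeriesSet,
    StateMatrix,
    StatePartition,
    BehaviorCoupling,
    upper_indices,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def write_timeseries(ts: RoiTimeSeriesSet, out_dir: str | Path) -> Path:
    """One directory per subject: run TSVs plus a small JSON manifest."""
    out = Path(out_dir) / ts.subject_id
    out.mkdir(parents=True, exist_ok=True)
    cols = [str(i) for i in ts.node_ids]
    for run_id, run in zip(ts.run_ids, ts.runs):
        pd.DataFrame(run, columns=cols).to_csv(
            out / f"{run_id}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
    meta = dict(subject_id=ts.subject_id, tr=ts.tr, run_ids=list(ts.run_ids),
                node_ids=[int(i) for i in ts.node_ids])
    (out / "subject.json").write_text(json.dumps(meta, indent=1))
    return out


def read_timeseries_subject(subject_dir: str | Path,
                            node_table: pd.DataFrame | None = None) -> RoiTimeSeriesSet:
    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / "subject.json").read_text())
    node_ids = np.array(meta["node_ids"], dtype=int)
    if node_table is not None:
        expected = node_table.sort_values("node_id")["node_id"].to_numpy()
        if not np.array_equal(node_ids, expected):
            raise ValueError(
                f"subject {meta['subject_id']}: node order does not match node table"
            )
    runs = []
    for run_id in meta["run_ids"]:
        path = subject_dir / f"{run_id}.tsv"
        if not path.exists() and (subject_dir / f"{run_id}.tsv.gz").exists():
            path = subject_dir / f"{run_id}.tsv.gz"
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        missing = [str(i) for i in node_ids if str(i) not in df.columns]
        if missing:
            raise ValueError(f"run {run_id!r}: missing node column(s) {missing}")
        runs.append(df[[str(i) for i in node_ids]].to_numpy(dtype=float))
    return RoiTimeSeriesSet(
        subject_id=meta["subject_id"], runs=runs, run_ids=list(meta["run_ids"]),
        tr=float(meta["tr"]), node_ids=node_ids,
    )


def read_timeseries(data_dir: str | Path,
                    node_table: pd.DataFrame | None = None) -> list[RoiTimeSeriesSet]:
    data_dir = Path(data_dir)
    subjects = sorted(p for p in data_dir.iterdir() if (p / "subject.json").exists())
    if not subjects:
        raise ValueError(f"no subject directories under {data_dir}")
    return [read_timeseries_subject(p, node_table) for p in subjects]


def read_confounds(conf_dir: str | Path, ts: RoiTimeSeriesSet) -> dict[str, np.ndarray]:
    """Per-run confound TSVs (header row, one column per regressor)."""
    conf_dir = Path(conf_dir)
    out = {}
    for run_id in ts.run_ids:
        df = pd.read_csv(conf_dir / f"{run_id}.tsv", sep="\t")
        out[run_id] = df.to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# ground truth / behavior
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = dict(
        labels={
            s: {r: labels.tolist() for r, labels in runs.items()}
            for s, runs in truth.labels.items()
        },
        effect_edges=[[int(s), int(i), int(j), float(d)] for s, i, j, d in truth.effect_edges],
        coupling=dataclasses.asdict(truth.coupling),
    )
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        labels={
            s: {r: np.array(v, dtype=int) for r, v in runs.items()}
            for s, runs in payload["labels"].items()
        },
        effect_edges=[tuple(e) for e in payload["effect_edges"]],
        coupling=BehaviorCoupling(**payload["coupling"]),
    )


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def write_connectome(conn: DynamicConnectome, path: str | Path) -> None:
    """Gzipped long TSV (run_id, frame, i, j, r; upper triangle) + JSON sidecar."""
    path = Path(path)
    n = conn.n_nodes
    iu, ju = upper_indices(n)
    T = conn.n_frames
    df = pd.DataFrame(
        dict(
            run_id=np.repeat(conn.run_ids, iu.size),
            frame=np.repeat(conn.frame_in_run, iu.size),
            i=np.tile(iu, T),
            j=np.tile(ju, T),
            r=conn.frames[:, iu, ju].ravel(),
        )
    )
    with gzip.open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = dict(subject_id=conn.subject_id, node_ids=[int(i) for i in conn.node_ids])
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_connectome(path: str | Path) -> DynamicConnectome:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    node_ids = np.array(sidecar["node_ids"], dtype=int)
    n = node_ids.size
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    iu, ju = upper_indices(n)
    E = iu.size
    T = len(df) // E
    frames = np.empty((T, n, n))
    r = df["r"].to_numpy().reshape(T, E)
    frames[:, iu, ju] = r
    frames[:, ju, iu] = r
    frames[:, np.arange(n), np.arange(n)] = 1.0
    run_ids = df["run_id"].to_numpy()[::E]
    frame_in_run = df["frame"].to_numpy()[::E]
    return DynamicConnectome(
        frames=frames, run_ids=run_ids, frame_in_run=frame_in_run,
        node_ids=node_ids, subject_id=sidecar["subject_id"],
    )


# ---------------------------------------------------------------------------
# partitions / state matrices
# ---------------------------------------------------------------------------

def write_partition(partition: StatePartition, frames: FrameMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = frames.provenance.copy()
    prov["label"] = partition.labels
    prov.to_csv(out / "labels.tsv", sep="\t", index=False)
    pd.DataFrame(partition.centroids).to_csv(
        out / "centroids.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    meta = dict(k=int(partition.k), inertia=float(partition.inertia),
                elbow_curve={str(k): float(v) for k, v in partition.elbow_curve.items()})
    (out / "partition.json").write_text(json.dumps(meta, indent=1))


def write_state_matrices(mats: list[StateMatrix], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in mats:
        pd.DataFrame(m.matrix).to_csv(
            out / f"{m.subject_id}_state{m.state_id}.tsv",
            sep="\t", index=False, float_format=_FLOAT_FMT,
        )


def read_meta_masks(path: str | Path, n_nodes: int) -> dict[str, np.ndarray]:
    """Meta-mask TSV with columns node_id, term, in_mask -> term -> bool mask."""
    df = pd.read_csv(path, sep="\t")
    needed = {"node_id", "term", "in_mask"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"meta-mask TSV missing column(s): {sorted(missing)}")
    masks = {}
    for term, sub in df.groupby("term"):
        m = np.zeros(n_nodes, dtype=bool)
        m[sub.loc[sub["in_mask"] != 0, "node_id"].to_numpy(dtype=int)] = True
        masks[str(term)] = m
    return masks


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through JSON unchanged."""

    out_dir: str = "results/run"
    data_dir: str | None = None          # None -> simulate
    # simulation
    n_controls: int = 20
    n_patients: int = 20
    n_nodes: int = 104
    k_true: int = 4
    runs_per_subject: int = 6
    frames_per_run: int = 118
    tr: float = 2.0
    # prep
    apply_prep: bool = False
    low_hz: float = 0.01
    high_hz: float = 0.1
    # dcc
    burnin: int = 5
    # clustering
    k: int | None = None                 # None -> elbow selection
    k_min: int = 2
    k_max: int = 8
    n_init: int = 20
    max_iter: int = 300
    # thresholds / hubs
    r_min: float = 0.2
    n_hubs: int = 20
    # stats
    edge_alpha: float = 0.05
    comp_alpha: float = 0.05
    n_perm: int = 5000
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**payload)
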