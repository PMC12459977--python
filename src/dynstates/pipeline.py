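"""End-to-end pipeline driver: simulate/ingest -> prep -> DCC -> cluster ->
state medians -> topology -> hub fits -> group statistics.

Every stage writes its artifact under the configured output directory and is
recorded in ``manifest.json`` (stage name, seeds/thresholds used, output
files with SHA-256 hashes), so a rerun with the same config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as dio
from .atlas import make_atlas_fixture, write_node_table
from .dcc import dynamic_connectome, static_fc
from .graph import state_metrics_table, threshold_positive, nodal_strength
from .hubmeta import extract_hubs, fit_strength_distribution
from .prep import preprocess
from .states import (
    elbow_select_k,
    group_state_matrix,
    kmeans_l1,
    subject_state_medians,
    vectorize_frames,
)
from .stats import nbs_correct, topology_group_tests
from .synthetic import default_cohort_spec, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = [
    "ingest", "prep", "dcc", "cluster", "state_medians",
    "metrics", "hubs", "group_stats",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config) -> None:
        self.out_dir = out_dir
        self.entries: list[dict] = []
        self.config = dataclasses.asdict(config)

    def record(self, stage: str, outputs: list[Path], **params) -> None:
        self.entries.append(
            dict(
                stage=stage,
                params=params,
                outputs=[
                    dict(path=str(p.relative_to(self.out_dir)), sha256=_sha256(p))
                    for p in outputs
                ],
            )
        )

    def write(self) -> None:
        (self.out_dir / "manifest.json").write_text(
            json.dumps(dict(config=self.config, stages=self.entries), indent=1)
        )


def run_pipeline(config: dio.RunConfig) -> dict:
    """Run every stage; returns a small in-memory report of headline numbers."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    report: dict = {}

    # 1. ingest or simulate -------------------------------------------------
    atlas = make_atlas_fixture() if config.n_nodes == 104 else None
    if config.data_dir is None:
        spec = default_cohort_spec(
            n_controls=config.n_controls, n_patients=config.n_patients,
            n_nodes=config.n_nodes, k=config.k_true, seed=config.seed,
            runs_per_subject=config.runs_per_subject,
            frames_per_run=config.frames_per_run, tr=config.tr,
        )
        subjects, truth, behavior, covariates = simulate_cohort(spec)
        data_dir = out / "data"
        outputs = [dio.write_timeseries(ts, data_dir) / "subject.json" for ts in subjects]
        dio.write_ground_truth(truth, out / "ground_truth.json")
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
        covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
        outputs += [out / "ground_truth.json", out / "behavior.tsv", out / "covariates.tsv"]
        if atlas is not None:
            write_node_table(atlas, out / "nodes.tsv")
            outputs.append(out / "nodes.tsv")
        manifest.record("ingest", outputs, simulated=True, seed=config.seed)
    else:
        subjects = dio.read_timeseries(config.data_dir, atlas)
        truth = None
        behavior = covariates = None
        manifest.record("ingest", [], simulated=False, data_dir=config.data_dir)
    report["n_subjects"] = len(subjects)

    # 2. prep ---------------------------------------------------------------
    if config.apply_prep:
        subjects = [
            preprocess(ts, low_hz=config.low_hz, high_hz=config.high_hz)
            for ts in subjects
        ]
    manifest.record("prep", [], applied=config.apply_prep,
                    low_hz=config.low_hz, high_hz=config.high_hz)

    # 3. DCC ----------------------------------------------------------------
    connectomes, sfc = [], {}
    dcc_params = {}
    for ts in subjects:
        conn, garch_fits, dcc_fit = dynamic_connectome(ts)
        conn = conn.drop_burnin(config.burnin)
        connectomes.append(conn)
        sfc[ts.subject_id] = static_fc(ts)
        dcc_params[ts.subject_id] = dict(theta1=dcc_fit.theta1, theta2=dcc_fit.theta2)
    (out / "dcc_params.json").write_text(json.dumps(dcc_params, indent=1))
    manifest.record("dcc", [out / "dcc_params.json"], burnin=config.burnin)

    # 4. cluster ------------------------------------------------------------
    frames = vectorize_frames(connectomes)
    if config.k is not None:
        partition = kmeans_l1(frames, config.k, n_init=config.n_init,
                              max_iter=config.max_iter, seed=config.seed)
        logger.info("clustering with fixed k=%d (elbow stage skipped)", config.k)
    else:
        k_star, curve, parts = elbow_select_k(
            frames, range(config.k_min, config.k_max + 1),
            n_init=config.n_init, max_iter=config.max_iter, seed=config.seed,
        )
        partition = parts[k_star]
        report["elbow_curve"] = curve
    report["k"] = partition.k
    dio.write_partition(partition, frames, out / "partition")
    manifest.record(
        "cluster", sorted((out / "partition").glob("*")),
        k=partition.k, n_init=config.n_init, seed=config.seed,
        fixed_k=config.k is not None,
    )

    # 5. state medians ------------------------------------------------------
    mats = subject_state_medians(frames, partition)
    dio.write_state_matrices(mats, out / "state_matrices")
    manifest.record("state_medians", sorted((out / "state_matrices").glob("*.tsv"))[:5])

    # 6. topology -----------------------------------------------------------
    nodal, global_ = state_metrics_table(mats, r_min=config.r_min)
    nodal.to_csv(out / "nodal_metrics.tsv", sep="\t", index=False)
    global_.to_csv(out / "global_metrics.tsv", sep="\t", index=False)
    manifest.record("metrics", [out / "nodal_metrics.tsv", out / "global_metrics.tsv"],
                    r_min=config.r_min)

    # 7. hubs + distribution fits ------------------------------------------
    controls = [m for m in mats if m.subject_id.startswith("con")] or mats
    hub_report = {}
    for state in range(partition.k):
        try:
            gmat = group_state_matrix(controls, state)
        except ValueError:
            continue
        strengths = nodal_strength(threshold_positive(gmat, r_min=config.r_min))
        entry = {}
        if np.count_nonzero(strengths > 0) >= 5:
            fit = fit_strength_distribution(strengths)
            entry["best_family"] = fit.best_family
            entry["r2"] = {f: fit.r2(f) for f in fit.fits}
        if strengths.size >= config.n_hubs:
            hubs = extract_hubs(strengths, n_hubs=config.n_hubs, state_id=state)
            entry["hub_nodes"] = hubs.node_ids.tolist()
        hub_report[str(state)] = entry
    (out / "hubs.json").write_text(json.dumps(hub_report, indent=1))
    manifest.record("hubs", [out / "hubs.json"], n_hubs=config.n_hubs)

    # 8. group statistics ---------------------------------------------------
    stats_report = {}
    con = [m for m in mats if m.subject_id.startswith("con")]
    pat = [m for m in mats if m.subject_id.startswith("pat")]
    if con and pat and config.n_controls >= 2 and config.n_patients >= 2:
        for state in sorted({m.state_id for m in mats}):
            if not any(m.state_id == state for m in con):
                continue
            if not any(m.state_id == state for m in pat):
                continue
            nbs = nbs_correct(
                con, pat, edge_alpha=config.edge_alpha, comp_alpha=config.comp_alpha,
                n_perm=config.n_perm, seed=config.seed, state_id=state,
            )
            stats_report[f"state{state}"] = dict(
                n_components=len(nbs.components),
                significant=[
                    dict(size=c.size, sign=c.sign, p=c.p_value)
                    for c in nbs.significant(config.comp_alpha)
                ],
            )
        nodal_con = nodal[nodal["subject_id"].str.startswith("con")]
        nodal_pat = nodal[nodal["subject_id"].str.startswith("pat")]
        topo = topology_group_tests(nodal_con, nodal_pat)
        topo.to_csv(out / "topology_tests.tsv", sep="\t", index=False)
        (out / "nbs.json").write_text(json.dumps(stats_report, indent=1))
        manifest.record("group_stats", [out / "nbs.json", out / "topology_tests.tsv"],
                        n_perm=config.n_perm, edge_alpha=config.edge_alpha,
                        comp_alpha=config.comp_alpha, seed=config.seed)
    else:
        manifest.record("group_stats", [], skipped="need both groups with >= 2 subjects")
    report["stats"] = stats_report

    manifest.write()
    report["manifest_stages"] = [e["stage"] for e in manifest.entries]
    return report
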