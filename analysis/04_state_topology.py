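"""Weighted topology of the recovered connectivity states.

Builds each subject's within-state connectivity matrices for a small cohort,
thresholds them (r > 0.2, positive weights only), and computes nodal and
global graph metrics (strength, global/local efficiency, betweenness).
Writes the metric tables and a per-state global summary.
"""

from pathlib import Path

from dynstates.graph import state_metrics_table
from dynstates.synthetic import default_cohort_spec, empirical_state_matrices, simulate_cohort

OUT = Path("results/analysis/04_topology")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = default_cohort_spec(n_controls=4, n_patients=4, seed=SEED)
    subjects, truth, _, _ = simulate_cohort(spec)
    mats = []
    for ts in subjects:
        mats.extend(empirical_state_matrices(ts, truth.labels[ts.subject_id]).values())

    nodal, global_ = state_metrics_table(mats, r_min=0.2)
    nodal.to_csv(OUT / "nodal_metrics.tsv", sep="\t", index=False)
    global_.to_csv(OUT / "global_metrics.tsv", sep="\t", index=False)

    summary = global_.groupby("state_id")[["total_strength", "global_ge", "global_le"]].mean()
    print("mean global metrics per state (subject-level, r > 0.2):")
    print(summary.round(3).to_string())
    print("the weak state (3) should show markedly lower strength and efficiency")
    print(f"artifacts in {OUT}")


if __name__ == "__main__":
    main()
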