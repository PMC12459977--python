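"""Simulate a demonstration cohort and write its artifacts.

Generates the 104-node atlas fixture and a small synthetic cohort (2
controls + 2 patients; the study-scale default is 20 + 20) with 4 latent
connectivity states, GARCH(1,1) marginals, planted hypo-/hyper-connectivity
and coupled behavioral scores, then writes the node table, one example
subject, ground truth, and the behavior/covariate tables.
"""

from pathlib import Path

import numpy as np

from dynstates import io as dio
from dynstates.atlas import make_atlas_fixture, write_node_table
from dynstates.synthetic import default_cohort_spec, simulate_cohort

OUT = Path("results/analysis/01_cohort")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = default_cohort_spec(n_controls=2, n_patients=2, seed=SEED)
    subjects, truth, behavior, covariates = simulate_cohort(spec)

    write_node_table(make_atlas_fixture(), OUT / "nodes.tsv")
    dio.write_timeseries(subjects[0], OUT / "data")          # one example subject
    dio.write_ground_truth(truth, OUT / "ground_truth.json")
    behavior.to_csv(OUT / "behavior.tsv", sep="\t", index=False)
    covariates.to_csv(OUT / "covariates.tsv", sep="\t", index=False)

    labels = truth.subject_labels(subjects[0].subject_id)
    occupancy = np.bincount(labels, minlength=spec.k) / labels.size
    print(f"cohort: {len(subjects)} subjects x {spec.runs_per_subject} runs "
          f"x {spec.frames_per_run} frames, {spec.n_nodes} nodes")
    print(f"planted effects: {len(spec.hypo_edges())} hypo edges (state 0), "
          f"{len(spec.hyper_edges())} hyper edges (state 1)")
    print(f"example subject state occupancy: {np.round(occupancy, 3)}")
    print(f"artifacts in {OUT}")


if __name__ == "__main__":
    main()
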