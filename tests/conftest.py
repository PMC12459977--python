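import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracles module

from dynstates import (
    CohortSpec,
    RoiTimeSeriesSet,
    default_cohort_spec,
    simulate_subject,
)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Small but fully structured cohort spec (4 states incl. weak, 20 nodes)."""
    return default_cohort_spec(
        n_controls=2, n_patients=2, n_nodes=20, k=4, seed=3,
        runs_per_subject=2, frames_per_run=100,
        effect_edges=[(0, 0, 1, -0.2), (1, 10, 11, 0.2)],
    )


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return simulate_subject(small_spec, "control", 0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def make_ts(runs, tr=2.0, subject_id="s0"):
    """Helper: wrap raw run matrices into a RoiTimeSeriesSet."""
    runs = [np.asarray(r, dtype=float) for r in runs]
    return RoiTimeSeriesSet(
        subject_id=subject_id,
        runs=runs,
        run_ids=[f"run{i:02d}" for i in range(len(runs))],
        tr=tr,
        node_ids=np.arange(runs[0].shape[1]),
    )
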