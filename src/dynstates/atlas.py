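"""Parcellation fixtures: a symmetric cortical language network plus subcortex.

The node table emulates a 68-node bilateral cortical language parcellation
(34 regions per hemisphere, named symmetrically) extended with 36 subcortical
parcels (amygdala, hippocampus, basal ganglia, thalamus subregions), 104
nodes in total. Coordinates are schematic MNI-like positions generated by a
deterministic layout, not anatomical claims.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

NODE_COLUMNS = ["node_id", "name", "hemisphere", "x", "y", "z", "structure", "substructure"]

# Gyral labels cycled to name cortical parcels; loosely language-flavored.
_CORTICAL_LABELS = [
    "SFG", "MFG", "IFG", "PrG", "PoG", "STG", "MTG", "ITG", "FuG", "PhG", "pSTS",
]

DEFAULT_SUBCORTICAL_PLAN = {
    "amygdala": 4,
    "hippocampus": 4,
    "basal_ganglia": 12,
    "thalamus": 16,
}


def make_atlas_fixture(
    n_cortical_per_hemi: int = 34,
    subcortical_plan: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build a node table with symmetric cortical rows plus subcortical parcels.

    Returns a DataFrame with columns ``node_id, name, hemisphere, x, y, z,
    structure, substructure``; node_id is contiguous from 0, cortical rows come
    first (all L then all R), then subcortical rows grouped by substructure.
    """
    if subcortical_plan is None:
        subcortical_plan = dict(DEFAULT_SUBCORTICAL_PLAN)
    if n_cortical_per_hemi < 0:
        raise ValueError("n_cortical_per_hemi must be >= 0")
    for sub, count in subcortical_plan.items():
        if count < 0:
            raise ValueError(f"subcortical count for {sub!r} must be >= 0")

    rows = []
    for hemi in ("L", "R"):
        sign = -1.0 if hemi == "L" else 1.0
        for i in range(n_cortical_per_hemi):
            label = _CORTICAL_LABELS[i % len(_CORTICAL_LABELS)]
            ordinal = i // len(_CORTICAL_LABELS) + 1
            # deterministic schematic layout, mirrored across the midline
            x = sign * (35.0 + 8.0 * (i % 4))
            y = -60.0 + 6.0 * (i % 17)
            z = -10.0 + 5.0 * (i % 13)
            rows.append(
                dict(
                    name=f"{label}_{ordinal}_{hemi}",
                    hemisphere=hemi,
                    x=x, y=y, z=z,
                    structure="cortical",
                    substructure=label,
                )
            )
    for sub in sorted(subcortical_plan):
        count = subcortical_plan[sub]
        for i in range(count):
            hemi = "L" if i % 2 == 0 else "R"
            sign = -1.0 if hemi == "L" else 1.0
            x = sign * (8.0 + 3.0 * (i // 2 % 4))
            y = -18.0 + 4.0 * (i % 5)
            z = -4.0 + 3.0 * (i % 7)
            rows.append(
                dict(
                    name=f"{sub}_{i // 2 + 1}_{hemi}",
                    hemisphere=hemi,
                    x=x, y=y, z=z,
                    structure="subcortical",
                    substructure=sub,
                )
            )

    table = pd.DataFrame(rows, columns=[c for c in NODE_COLUMNS if c != "node_id"])
    table.insert(0, "node_id", np.arange(len(table)))
    return table


def validate_node_table(table: pd.DataFrame) -> None:
    """Check the node-table invariants; raise ValueError on violation."""
    missing = [c for c in NODE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"node table missing columns: {missing}")
    ids = table["node_id"].to_numpy()
    if len(ids) and (ids.min() != 0 or not np.array_equal(np.sort(ids), np.arange(len(ids)))):
        raise ValueError("node_id must be unique and contiguous from 0")
    cortical = table[table["structure"] == "cortical"]
    bad = cortical[~cortical["hemisphere"].isin(["L", "R"])]
    if len(bad):
        raise ValueError("every cortical node needs hemisphere L or R")


def write_node_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_node_table(table)
    table.to_csv(path, sep="\t", index=False)


def read_node_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_node_table(table)
    return table


def hemisphere_mask(table: pd.DataFrame, hemisphere: str) -> np.ndarray:
    """Boolean node mask for one hemisphere, in node_id order."""
    t = table.sort_values("node_id")
    return (t["hemisphere"] == hemisphere).to_numpy()
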