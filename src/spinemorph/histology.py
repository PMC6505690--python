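"""Fused-joint proportions from annotated histology joint-status tables.

Vertebral segmentation is scored manually on stained sections; what enters
this module is the resulting count table per specimen: for each spinal
region (cervical / thoracic / lumbar) and joint type (vertebral body or
spinous process), the number of fused-or-partially-segmented joints and the
total number of joints visible across all sections. The fused-joint
proportion is simply fused / total, pooled over sections. Sample sizes are
one to three specimens per group, so no statistics are attached — exports
are dot-plot style, one proportion per specimen.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import pandas as pd

__all__ = [
    "REGIONS",
    "JOINT_TYPES",
    "JointStatusTable",
    "fused_proportion",
    "pool_tables",
    "proportions_frame",
]

REGIONS = ("cervical", "thoracic", "lumbar")
JOINT_TYPES = ("vertebral_body", "spinous_process")


@dataclasses.dataclass
class JointStatusTable:
    """Per-specimen fused/total joint counts by region and joint type."""

    specimen_id: str
    rows: pd.DataFrame  # columns: region, joint_type, n_fused, n_total

    def __post_init__(self) -> None:
        frame = pd.DataFrame(self.rows)
        required = {"region", "joint_type", "n_fused", "n_total"}
        if not required.issubset(frame.columns):
            raise ValueError(f"joint table needs columns {sorted(required)}")
        if not frame["region"].isin(REGIONS).all():
            raise ValueError(f"region must be one of {REGIONS}")
        if not frame["joint_type"].isin(JOINT_TYPES).all():
            raise ValueError(f"joint_type must be one of {JOINT_TYPES}")
        if (frame["n_total"] < 1).any():
            raise ValueError("n_total must be >= 1")
        if (frame["n_fused"] < 0).any() or (frame["n_fused"] > frame["n_total"]).any():
            raise ValueError("need 0 <= n_fused <= n_total")
        self.rows = frame.reset_index(drop=True)


def fused_proportion(table: JointStatusTable, region: str, joint_type: str) -> float:
    """Fused-joint proportion n_fused / n_total for one (region, joint type)."""
    match = table.rows[
        (table.rows["region"] == region) & (table.rows["joint_type"] == joint_type)
    ]
    if match.empty:
        raise KeyError(f"region/type not scored: ({region}, {joint_type})")
    fused = int(match["n_fused"].sum())
    total = int(match["n_total"].sum())
    return fused / total


def pool_tables(tables: Iterable[JointStatusTable], specimen_id: str = "pooled") -> JointStatusTable:
    """Pool counts across specimens (or sections); proportions on the pooled
    counts equal the count-weighted combination of the per-table ones."""
    frames = [t.rows for t in tables]
    if not frames:
        raise ValueError("nothing to pool")
    pooled = (
        pd.concat(frames)
        .groupby(["region", "joint_type"], as_index=False)[["n_fused", "n_total"]]
        .sum()
    )
    return JointStatusTable(specimen_id=specimen_id, rows=pooled)


def proportions_frame(tables: Iterable[JointStatusTable]) -> pd.DataFrame:
    """Long-format per-specimen proportions for dot-plot style export."""
    rows = []
    for table in tables:
        for _, r in table.rows.iterrows():
            rows.append(
                {
                    "specimen_id": table.specimen_id,
                    "region": r["region"],
                    "joint_type": r["joint_type"],
                    "n_fused": int(r["n_fused"]),
                    "n_total": int(r["n_total"]),
                    "proportion": r["n_fused"] / r["n_total"],
                }
            )
    return pd.DataFrame(rows)
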