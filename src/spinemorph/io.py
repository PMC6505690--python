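"""Specimen document I/O and tabular exports.

Specimens travel as JSON documents with a fixed schema (validated with
pydantic): vertebrae with centre and endplate landmark coordinates, ribs
with centerline point lists, stage/group metadata. The single canonical
unit is millimetres — the ``units`` field must literally be "mm", and no
unit autodetection is attempted. Reading a written document reproduces the
specimen exactly (floats round-trip through JSON repr).

CSV exports are UTF-8, comma-separated, dot-decimal, header row mandatory.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .geometry import Polyline3
from .ribs import Rib, rib_metrics
from .specimen import Specimen
from .spine import CurvatureProfile, Spine, Vertebra
from .wedging import WedgeReport

__all__ = [
    "SCHEMA_VERSION",
    "SpecimenDocument",
    "read_specimen",
    "write_specimen",
    "read_cohort",
    "profiles_frame",
    "wedge_frame",
    "rib_frame",
    "traces_frame",
]

SCHEMA_VERSION = 1

Point3 = tuple[float, float, float]


class VertebraDocument(BaseModel):
    label: str
    centre: Point3
    superior_endplate: tuple[Point3, Point3]
    inferior_endplate: tuple[Point3, Point3]
    fused_with_next: bool = False


class RibDocument(BaseModel):
    side: Literal["left", "right"]
    index: int = Field(ge=1)
    present: bool = True
    centerline: Optional[list[Point3]] = None


class SpecimenDocument(BaseModel):
    """The on-disk specimen schema (coordinates in mm)."""

    schema_version: int
    specimen_id: str
    stage: int = Field(ge=0)
    group: str
    units: Literal["mm"] = "mm"
    vertebrae: list[VertebraDocument]
    ribs: Optional[list[RibDocument]] = None
    region_counts: dict[str, int] = Field(
        default_factory=lambda: {"C": 14, "T": 7, "L": 7}
    )


def specimen_to_document(specimen: Specimen) -> SpecimenDocument:
    spine = specimen.spine
    return SpecimenDocument(
        schema_version=SCHEMA_VERSION,
        specimen_id=spine.specimen_id,
        stage=spine.stage,
        group=spine.group,
        vertebrae=[
            VertebraDocument(
                label=v.label,
                centre=tuple(v.centre),
                superior_endplate=(tuple(v.superior_endplate[0]),
                                   tuple(v.superior_endplate[1])),
                inferior_endplate=(tuple(v.inferior_endplate[0]),
                                   tuple(v.inferior_endplate[1])),
                fused_with_next=v.fused_with_next,
            )
            for v in spine.vertebrae
        ],
        ribs=[
            RibDocument(
                side=r.side,
                index=r.index,
                present=r.present,
                centerline=[tuple(p) for p in r.centerline.points] if r.present else None,
            )
            for r in specimen.ribs
        ],
        region_counts=dict(spine.region_counts),
    )


def document_to_specimen(doc: SpecimenDocument) -> Specimen:
    vertebrae = [
        Vertebra(
            label=v.label,
            centre=np.array(v.centre),
            superior_endplate=np.array(v.superior_endplate),
            inferior_endplate=np.array(v.inferior_endplate),
            fused_with_next=v.fused_with_next,
        )
        for v in doc.vertebrae
    ]
    spine = Spine(
        specimen_id=doc.specimen_id,
        stage=doc.stage,
        group=doc.group,
        vertebrae=vertebrae,
        region_counts=dict(doc.region_counts),
    )
    ribs = []
    if doc.ribs is None:
        warnings.warn(f"{doc.specimen_id}: document has no ribs block; "
                      "specimen loaded with zero ribs", stacklevel=3)
    else:
        for r in doc.ribs:
            centerline = None
            if r.present and r.centerline is not None:
                centerline = Polyline3(np.array(r.centerline))
            ribs.append(Rib(side=r.side, index=r.index, centerline=centerline))
    return Specimen(spine=spine, ribs=ribs)


def write_specimen(specimen: Specimen, path: str | Path) -> Path:
    path = Path(path)
    doc = specimen_to_document(specimen)
    path.write_text(json.dumps(doc.model_dump(), indent=1), encoding="utf-8")
    return path


def read_specimen(path: str | Path) -> Specimen:
    """Read and validate one specimen document.

    Schema violations surface as pydantic validation errors naming the
    offending path; an unknown ``schema_version`` is rejected before
    validation.
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {version!r} "
                         f"(expected {SCHEMA_VERSION})")
    doc = SpecimenDocument.model_validate(raw)
    return document_to_specimen(doc)


def read_cohort(directory: str | Path) -> list[Specimen]:
    """Read every ``*.json`` specimen document in a directory (sorted order),
    skipping a ``manifest.json`` if present."""
    directory = Path(directory)
    specimens = []
    for path in sorted(directory.glob("*.json")):
        if path.name == "manifest.json":
            continue
        specimens.append(read_specimen(path))
    if not specimens:
        raise FileNotFoundError(f"no specimen documents found in {directory}")
    return specimens


# ---------------------------------------------------------------------------
# tabular exports


def profiles_frame(profiles: Iterable[CurvatureProfile]) -> pd.DataFrame:
    """Long-format GC profile table: one row per (specimen, vertebra)."""
    rows = []
    for p in profiles:
        for label, gc in p.values.items():
            rows.append(
                {
                    "specimen_id": p.specimen_id,
                    "group": p.group,
                    "stage": p.stage,
                    "label": label,
                    "gc_mm_inv": gc,
                    "gc_signed_mm_inv": p.signed_values[label],
                }
            )
    return pd.DataFrame(rows)


def wedge_frame(reports: Iterable[WedgeReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for rec in rep.records:
            rows.append(
                {
                    "specimen_id": rep.specimen_id,
                    "group": rep.group,
                    "stage": rep.stage,
                    "label": rec.label,
                    "angle_deg": rec.wedge_angle,
                    "wedged": rec.wedged,
                    "fused": rec.fused,
                }
            )
    return pd.DataFrame(rows)


def rib_frame(specimens: Iterable[Specimen]) -> pd.DataFrame:
    """Per-rib metrics table; absent ribs get NaN metrics."""
    rows = []
    for spec in specimens:
        for rib in spec.ribs:
            row = {
                "specimen_id": spec.specimen_id,
                "group": spec.group,
                "stage": spec.stage,
                "side": rib.side,
                "index": rib.index,
                "present": rib.present,
                "L_C_mm": np.nan,
                "L_S_mm": np.nan,
                "N": np.nan,
                "ICM": np.nan,
            }
            if rib.present:
                m = rib_metrics(rib)
                row.update(L_C_mm=m.L_C, L_S_mm=m.L_S, N=m.N, ICM=m.ICM)
            rows.append(row)
    return pd.DataFrame(rows)


def traces_frame(traces: dict[str, np.ndarray]) -> pd.DataFrame:
    """Aligned centre traces (from align_outlines) as a plottable table."""
    rows = []
    for sid, pts in traces.items():
        for i, (x, y, z) in enumerate(pts):
            rows.append({"specimen_id": sid, "ordinal": i + 1,
                         "x_mm": x, "y_mm": y, "z_mm": z})
    return pd.DataFrame(rows)
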