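"""Vertebral wedge angles, wedged/fused classification and abnormal counts.

A vertebra is *wedged* when the lines drawn along its superior and inferior
endplate surfaces, viewed in the sagittal plane, meet at an angle strictly
greater than a threshold (10 degrees by default, reflecting normal
variability in vertebral shape). Adjacent vertebrae are *fused* when no
separation between them can be identified — here either an explicit
annotation or an overlapping-endplate geometric criterion. A vertebra is
*abnormal* when it is wedged or fused.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryError, project_to_plane
from .spine import ANALYSIS_WINDOW, Spine, Vertebra

__all__ = [
    "WedgeRecord",
    "WedgeReport",
    "wedge_angle",
    "intervertebral_gap",
    "classify_vertebrae",
    "cohort_abnormal_summary",
]

WEDGE_THRESHOLD_DEG = 10.0
# strict ">" comparison with a guard far below measurement precision, so that
# an angle constructed at exactly the threshold never trips on float rounding
_ANGLE_GUARD_DEG = 1e-9


def _endplate_direction(endplate: np.ndarray) -> np.ndarray:
    """Unit direction of an endplate line in the sagittal projection."""
    pts = project_to_plane(np.asarray(endplate, dtype=float), "sagittal")
    d = pts[1] - pts[0]
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise GeometryError("degenerate endplate: endpoints coincide in sagittal view")
    return d / n


def wedge_angle(vertebra: Vertebra) -> float:
    """Angle (degrees, in [0, 90]) between the two endplate lines, sagittal view.

    Computed from the absolute cosine of the endplate direction vectors,
    which equals the intersection angle of the two (undirected) lines and is
    well defined even when they are parallel.
    """
    u = _endplate_direction(vertebra.superior_endplate)
    v = _endplate_direction(vertebra.inferior_endplate)
    c = min(1.0, abs(float(np.dot(u, v))))
    return math.degrees(math.acos(c))


def intervertebral_gap(upper: Vertebra, lower: Vertebra) -> float:
    """Signed separation (mm) between two adjacent vertebrae along the local axis.

    Distance from the upper vertebra's inferior endplate midpoint to the lower
    vertebra's superior endplate midpoint, projected on the cranial axis
    joining the two centres. Non-positive means the endplates overlap.
    """
    axis = upper.centre - lower.centre
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise GeometryError("degenerate pair: coincident vertebral centres")
    axis = axis / n
    inf_mid = upper.inferior_endplate.mean(axis=0)
    sup_mid = lower.superior_endplate.mean(axis=0)
    return float(np.dot(inf_mid - sup_mid, axis))


@dataclasses.dataclass
class WedgeRecord:
    label: str
    wedge_angle: float  # degrees; NaN when unmeasured
    wedged: bool
    fused: bool
    measured: bool = True

    @property
    def abnormal(self) -> bool:
        return self.wedged or self.fused


@dataclasses.dataclass
class WedgeReport:
    """Per-specimen wedge/fusion classification over the analysis window."""

    specimen_id: str
    group: str
    stage: int
    records: list[WedgeRecord]

    @property
    def n_wedged(self) -> int:
        return sum(r.wedged for r in self.records)

    @property
    def n_fused(self) -> int:
        return sum(r.fused for r in self.records)

    @property
    def n_abnormal(self) -> int:
        return sum(r.abnormal for r in self.records)


def classify_vertebrae(
    spine: Spine,
    threshold: float = WEDGE_THRESHOLD_DEG,
    window: tuple[str, str] = ANALYSIS_WINDOW,
) -> WedgeReport:
    """Classify each vertebra in the window as wedged and/or fused.

    Wedged: endplate angle strictly greater than ``threshold`` degrees.
    Fused: the ``fused_with_next`` annotation, or a non-positive
    intervertebral gap (overlapping endplates); both members of a fused pair
    are flagged. Vertebrae with degenerate endplates are reported unmeasured
    rather than raising.
    """
    verts = spine.window(*window)
    records = {v.label: WedgeRecord(v.label, float("nan"), False, False, measured=False)
               for v in verts}
    for v in verts:
        try:
            angle = wedge_angle(v)
        except GeometryError:
            warnings.warn(f"{spine.specimen_id}: degenerate endplate at {v.label}, "
                          "left unmeasured", stacklevel=2)
            continue
        rec = records[v.label]
        rec.wedge_angle = angle
        rec.wedged = angle > threshold + _ANGLE_GUARD_DEG
        rec.measured = True
    for upper, lower in zip(verts[:-1], verts[1:]):
        fused = upper.fused_with_next
        if not fused:
            try:
                fused = intervertebral_gap(upper, lower) <= 0.0
            except GeometryError:
                fused = False
        if fused:
            records[upper.label].fused = True
            records[lower.label].fused = True
    return WedgeReport(
        specimen_id=spine.specimen_id,
        group=spine.group,
        stage=spine.stage,
        records=[records[v.label] for v in verts],
    )


def cohort_abnormal_summary(reports: Iterable[WedgeReport]) -> pd.DataFrame:
    """Mean and sample SD (n-1) of wedged / fused / abnormal counts per (group, stage).

    SD is NaN for single-specimen groups.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("empty cohort")
    rows = [
        {
            "specimen_id": r.specimen_id,
            "group": r.group,
            "stage": r.stage,
            "n_wedged": r.n_wedged,
            "n_fused": r.n_fused,
            "n_abnormal": r.n_abnormal,
        }
        for r in reports
    ]
    frame = pd.DataFrame(rows)
    agg = frame.groupby(["group", "stage"])[["n_wedged", "n_fused", "n_abnormal"]].agg(
        ["mean", "std", "count"]
    )
    agg.columns = [f"{metric}_{stat}" for metric, stat in agg.columns]
    return agg.reset_index()
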