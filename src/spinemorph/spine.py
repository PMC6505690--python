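"""Vertebral-line curvature profiles, spine height and outline alignment.

The spine is an ordered sequence of vertebrae, cervical (C) to thoracic (T)
to lumbar (L); the default regional layout is the avian embryonic one used
throughout this package: 14 cervical, 7 thoracic, 7 lumbar. Quantitative
operations run over the analysis window C8..L7 — the most cranial vertebra
reliably identifiable in the source imaging is C8, so curvature profiles
and the height measure both start there.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import (
    GeometryError,
    SplineCurve,
    curvature_at,
    fit_smoothing_spline,
    project_to_plane,
    signed_curvature_at,
)

__all__ = [
    "DEFAULT_REGION_COUNTS",
    "ANALYSIS_WINDOW",
    "Vertebra",
    "Spine",
    "CurvatureProfile",
    "make_labels",
    "compute_gc_profile",
    "spine_height",
    "align_outlines",
]

DEFAULT_REGION_COUNTS: Mapping[str, int] = {"C": 14, "T": 7, "L": 7}
ANALYSIS_WINDOW = ("C8", "L7")


def make_labels(region_counts: Mapping[str, int] = DEFAULT_REGION_COUNTS) -> list[str]:
    """Full ordered label sequence, e.g. C1..C14, T1..T7, L1..L7."""
    labels = []
    for region in ("C", "T", "L"):
        labels.extend(f"{region}{i}" for i in range(1, region_counts[region] + 1))
    return labels


@dataclasses.dataclass
class Vertebra:
    """One vertebra: centre plus the two endplate landmark pairs (mm).

    ``superior_endplate`` / ``inferior_endplate`` are (2, 3) endpoint arrays of
    the line drawn along the cranial / caudal endplate surface in the sagittal
    view. ``fused_with_next`` is an annotation-level fusion flag with the
    next (caudal) vertebra.
    """

    label: str
    centre: np.ndarray
    superior_endplate: np.ndarray
    inferior_endplate: np.ndarray
    fused_with_next: bool = False

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        for name in ("superior_endplate", "inferior_endplate"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (2, 3):
                raise ValueError(f"{name} must be two 3D endpoints, got {arr.shape}")
            setattr(self, name, arr)


@dataclasses.dataclass
class Spine:
    """An ordered (cranial to caudal) vertebral column of one specimen."""

    specimen_id: str
    stage: int
    group: str
    vertebrae: list[Vertebra]
    region_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_REGION_COUNTS)
    )

    def __post_init__(self) -> None:
        order = {lab: i for i, lab in enumerate(make_labels(self.region_counts))}
        seen: set[str] = set()
        prev = -1
        for v in self.vertebrae:
            if v.label not in order:
                raise ValueError(f"unknown vertebra label {v.label!r}")
            if v.label in seen:
                raise ValueError(f"duplicate vertebra label {v.label!r}")
            if order[v.label] <= prev:
                raise ValueError("vertebrae must be ordered cranial to caudal")
            prev = order[v.label]
            seen.add(v.label)
        self._ordinals = {v.label: order[v.label] + 1 for v in self.vertebrae}

    def labels(self) -> list[str]:
        return [v.label for v in self.vertebrae]

    def ordinal(self, label: str) -> int:
        """1-based position of a label in the full regional layout."""
        return self._ordinals[label]

    def get(self, label: str) -> Vertebra | None:
        for v in self.vertebrae:
            if v.label == label:
                return v
        return None

    def window(self, start: str = ANALYSIS_WINDOW[0], end: str = ANALYSIS_WINDOW[1]) -> list[Vertebra]:
        """Vertebrae present within [start, end] inclusive, in order."""
        order = {lab: i for i, lab in enumerate(make_labels(self.region_counts))}
        lo, hi = order[start], order[end]
        return [v for v in self.vertebrae if lo <= order[v.label] <= hi]

    def centres(self) -> np.ndarray:
        return np.stack([v.centre for v in self.vertebrae])


@dataclasses.dataclass
class CurvatureProfile:
    """Per-vertebra geometric curvature (mm^-1) over the analysis window.

    ``values`` holds the absolute GC keyed by label (NaN where a vertebra was
    missing); ``signed_values`` the signed sagittal curvature (+ kyphotic,
    - lordotic by the package convention).
    """

    specimen_id: str
    group: str
    stage: int
    values: dict[str, float]
    signed_values: dict[str, float]
    curve: SplineCurve


def compute_gc_profile(
    spine: Spine,
    smoothing: float | None = None,
    window: tuple[str, str] = ANALYSIS_WINDOW,
) -> CurvatureProfile:
    """Geometric curvature at each vertebra of the analysis window.

    A cubic (smoothing) spline is fitted through the available vertebral
    centres, parameterised by vertebra ordinal, and the sagittal
    osculating-circle curvature is evaluated at each knot. Labels missing
    from the window are reported as NaN.
    """
    verts = spine.window(*window)
    if len(verts) < 4:
        raise GeometryError("insufficient points: need >= 4 vertebrae in the window")
    knots = np.array([spine.ordinal(v.label) for v in verts], dtype=float)
    centres = np.stack([v.centre for v in verts])
    curve = fit_smoothing_spline(centres, knots=knots, smoothing=smoothing)
    gc = np.asarray(curvature_at(curve, knots, plane="sagittal"), dtype=float)
    signed = np.asarray(signed_curvature_at(curve, knots, plane="sagittal"), dtype=float)

    order = make_labels(spine.region_counts)
    lo = order.index(window[0])
    hi = order.index(window[1])
    values: dict[str, float] = {lab: float("nan") for lab in order[lo : hi + 1]}
    signed_values = dict(values)
    present = {v.label for v in verts}
    missing = [lab for lab in values if lab not in present]
    if missing:
        warnings.warn(
            f"{spine.specimen_id}: vertebrae missing in window, GC marked NaN: {missing}",
            stacklevel=2,
        )
    for v, g, s in zip(verts, gc, signed):
        values[v.label] = float(abs(g))
        signed_values[v.label] = float(s)
    return CurvatureProfile(
        specimen_id=spine.specimen_id,
        group=spine.group,
        stage=spine.stage,
        values=values,
        signed_values=signed_values,
        curve=curve,
    )


def spine_height(spine: Spine, window: tuple[str, str] = ANALYSIS_WINDOW) -> float:
    """Straight-line distance (mm) between the C8 and L7 centres, sagittal view."""
    top = spine.get(window[0])
    bottom = spine.get(window[1])
    if top is None or bottom is None:
        raise ValueError("window endpoints absent: both C8 and L7 centres are required")
    a = project_to_plane(top.centre, "sagittal")
    b = project_to_plane(bottom.centre, "sagittal")
    return float(np.linalg.norm(a - b))


def align_outlines(spines: Iterable[Spine], at: str = "T1") -> dict[str, np.ndarray]:
    """Translate each centre trace so the reference vertebra sits at the origin.

    Returns ``{specimen_id: (n, 3) translated centres}``. Translation only —
    no rotation or scaling — so curvature and inter-landmark distances are
    untouched. Specimens lacking the reference vertebra are excluded with a
    warning.
    """
    traces: dict[str, np.ndarray] = {}
    for spine in spines:
        ref = spine.get(at)
        if ref is None:
            warnings.warn(
                f"{spine.specimen_id}: no {at} vertebra, excluded from alignment",
                stacklevel=2,
            )
            continue
        traces[spine.specimen_id] = spine.centres() - ref.centre
    return traces
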