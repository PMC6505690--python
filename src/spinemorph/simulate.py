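"""Seeded generator of synthetic chick-embryo spine/rib specimens.

The generator emulates control and immobilised (rigid-paralysis) embryos at
stages E5-E9 and is the package's calibration surface: the defaults are set
so that the measurement pipeline, run on generated cohorts, returns the
group statistics of the immobilisation study this package quantifies —
control spine height 6.2 mm at E6 growing to 10.9 mm at E9, fifth-left-rib
curved length 2.7 mm (control E9) vs 1.7 mm (immobilised-at-E5), mean
wedged-vertebra counts rising from 2.8 at E7 to 8 at E9 after E4
immobilisation, about five abnormal vertebrae in the E3/E4 groups of the
single-harvest arm, and absent ribs in 5 of 6 immobilised-at-E5 specimens.

Two study arms exist as a ``design`` axis, because the same (group, stage)
cell was measured in both with different severity:

* ``critical_timings`` — immobilise once at E3/E4/E5/E6, harvest all at E9,
  compare to one pooled control.
* ``ontogenetic`` — immobilise once at E4, harvest daily E5-E9, compare to
  age-matched controls.

A specimen is built by laying vertebral centres along a gently curved
sagittal template plus Gaussian-bump deformities, scaling so the C8-L7
chord equals the target height exactly before noise; endplates sit
perpendicular to the local tangent except at planted wedges, where the
superior endplate is rotated by the planted angle in the sagittal plane;
ribs launch laterally from their thoracic vertebrae with exact target arc
length and optional sinusoidal waviness. I.i.d. Gaussian noise (default
5 um, an optical-projection-tomography-scale landmark error) is added to
every landmark last.

Cohort-level variability is *stratified*: per-specimen heights, rib lengths
and wedge counts are jittered with mean-preserving normal quantiles (and
zero-sum integer jitter for counts) so that cohort means sit on the
calibration targets even at n = 6-10 while the spread approximates the
published SDs. Generation is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm as _norm

from .geometry import Polyline3
from .ribs import Rib
from .specimen import Specimen
from .spine import DEFAULT_REGION_COUNTS, Spine, Vertebra, make_labels

__all__ = [
    "GROUPS",
    "STAGES",
    "DeformitySpec",
    "WedgeSpec",
    "RibSpec",
    "GeneratorConfig",
    "default_config",
    "generate_spine",
    "generate_ribs",
    "generate_specimen",
    "generate_cohort",
    "generating_curvature",
]

GROUPS = ("control", "Im3", "Im4", "Im5", "Im6")
STAGES = (5, 6, 7, 8, 9)
DESIGNS = ("critical_timings", "ontogenetic")

DEFAULT_NOISE_SD_MM = 0.005
DEFAULT_WEDGE_ANGLE_DEG = 15.0

# ---------------------------------------------------------------------------
# calibration tables; values marked (published) are the study's printed group
# statistics, the rest is generator calibration chosen once (see docs/methods)

CONTROL_HEIGHT_MM = {5: 4.8, 6: 6.2, 7: 7.8, 8: 9.3, 9: 10.9}  # 6.2/10.9 published
HEIGHT_SD_MM = {5: 0.4, 6: 0.4, 7: 0.45, 8: 0.5, 9: 0.6}       # 0.4/0.6 published
IM4_HEIGHT_FACTOR = {5: 1.0, 6: 1.0, 7: 1.0, 8: 0.9, 9: 0.9}   # deficit from E8

CONTROL_RIB_L5_MM = {6: 0.6, 7: 1.3, 8: 2.1, 9: 2.7}           # 2.7 published
CONTROL_RIB_SD_MM = {6: 0.1, 7: 0.2, 8: 0.3, 9: 0.36}          # 0.36 published
IM5_RIB_L5_MM, IM5_RIB_SD_MM = 1.7, 0.22                       # published
IM4_ONT_RIB_L5_MM = {7: 0.9, 8: 1.9, 9: 2.3}
IM4_ONT_RIB_SD_MM = {7: 0.2, 8: 0.3, 9: 0.3}
IM4_ONT_WAVE_AMP_MM = {5: 0.0, 6: 0.0, 7: 0.06, 8: 0.10, 9: 0.04}
WAVE_WAVELENGTH_MM = 0.8

#: relative curved length of vertebral ribs 1..7 (index 5 is the reference)
RIB_INDEX_PROFILE = {1: 0.62, 2: 0.78, 3: 0.90, 4: 0.97, 5: 1.00, 6: 0.94, 7: 0.84}

#: planting order for wedged vertebrae; a specimen with k wedges uses the first k
WEDGE_POOL_LABELS = (
    "C9", "T2", "L1", "C11", "T4", "L3", "C13", "T6", "L5", "C10", "T3", "L2",
)

IM4_ONT_WEDGE_MEAN = {5: 0.0, 6: 1.0, 7: 2.8, 8: 5.0, 9: 8.0}  # 2.8/8 published
IM4_ONT_WEDGE_SD = {5: 0.0, 6: 0.0, 7: 1.8, 8: 0.0, 9: 1.2}    # 1.8/1.2 published

# single-harvest arm at E9: wedge mean, fused pairs, absent-rib specimen fraction
CRITICAL_WEDGE_MEAN = {"Im3": 3.0, "Im4": 3.0, "Im5": 3.0, "Im6": 2.0}
CRITICAL_FUSION = {
    "Im3": (("T5", "T6"),),
    "Im4": (("L5", "L6"),),
    "Im5": (),
    "Im6": (),
}
CRITICAL_ABSENT_FRACTION = {"Im3": 1 / 7, "Im4": 2 / 9, "Im5": 5 / 6, "Im6": 1 / 6}


@dataclasses.dataclass(frozen=True)
class DeformitySpec:
    """A Gaussian sagittal bump: centre label, amplitude (mm), width
    (vertebra ordinals), and sign (+1 kyphotic / -1 lordotic)."""

    centre_label: str
    amplitude_mm: float
    width_vertebrae: float
    sign: int = 1


@dataclasses.dataclass(frozen=True)
class WedgeSpec:
    label: str
    angle_deg: float = DEFAULT_WEDGE_ANGLE_DEG


@dataclasses.dataclass(frozen=True)
class RibSpec:
    side: str
    index: int
    present: bool = True
    target_length_mm: float = 2.7
    waviness_amplitude_mm: float = 0.0
    waviness_wavelength_mm: float = WAVE_WAVELENGTH_MM


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of one synthetic specimen type."""

    stage: int
    group: str
    design: str
    target_height_mm: float
    height_sd_mm: float = 0.0
    region_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_REGION_COUNTS)
    )
    baseline_gc_mm_inv: float = 0.03
    deformities: tuple[DeformitySpec, ...] = ()
    wedge_pool: tuple[WedgeSpec, ...] = tuple(
        WedgeSpec(lab) for lab in WEDGE_POOL_LABELS
    )
    wedge_count_mean: float = 0.0
    wedge_count_sd: float = 0.0
    fusion_plan: tuple[tuple[str, str], ...] = ()
    rib_plan: tuple[RibSpec, ...] = ()
    rib_length_sd_mm: float = 0.0
    absent_specimen_fraction: float = 0.0
    absent_rib: tuple[str, int] = ("left", 3)
    noise_sd_mm: float = DEFAULT_NOISE_SD_MM

    def __post_init__(self) -> None:
        if self.target_height_mm <= 0:
            raise ValueError("target height must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise SD must be non-negative")
        for w in self.wedge_pool:
            if w.angle_deg <= 0:
                raise ValueError("planted wedge angles must be positive")
        for r in self.rib_plan:
            if r.target_length_mm <= 0:
                raise ValueError("rib target lengths must be positive")


def _default_rib_plan(l5_mm: float, amp_mm: float, wavelength_mm: float,
                      n_thoracic: int = 7) -> tuple[RibSpec, ...]:
    plan = []
    for side in ("left", "right"):
        for idx in range(1, n_thoracic + 1):
            plan.append(
                RibSpec(
                    side=side,
                    index=idx,
                    present=True,
                    target_length_mm=l5_mm * RIB_INDEX_PROFILE[idx],
                    waviness_amplitude_mm=amp_mm,
                    waviness_wavelength_mm=wavelength_mm,
                )
            )
    return tuple(plan)


_CRITICAL_DEFORMITIES = {
    "Im3": (DeformitySpec("L5", 0.35, 1.5, +1),),
    "Im4": (
        DeformitySpec("T3", 0.35, 1.5, +1),
        DeformitySpec("T6", 0.3, 1.5, -1),
        DeformitySpec("L4", 0.35, 1.5, +1),
    ),
    "Im5": (DeformitySpec("C10", 0.3, 1.5, +1), DeformitySpec("T4", 0.25, 1.5, -1)),
    "Im6": (),
}

_ONT_DEFORMITIES = {
    5: (DeformitySpec("C5", 0.2, 1.5, +1),),
    6: (DeformitySpec("C10", 0.2, 1.5, +1), DeformitySpec("T3", 0.2, 1.5, -1),
        DeformitySpec("L2", 0.2, 1.5, +1)),
    7: (DeformitySpec("C7", 0.25, 1.5, +1), DeformitySpec("L5", 0.3, 1.5, -1)),
    8: (DeformitySpec("C9", 0.35, 1.5, +1), DeformitySpec("T3", 0.35, 1.5, -1),
        DeformitySpec("T6", 0.3, 1.5, +1), DeformitySpec("L4", 0.35, 1.5, -1)),
    9: (DeformitySpec("C9", 0.4, 1.5, +1), DeformitySpec("T3", 0.4, 1.5, -1),
        DeformitySpec("T6", 0.3, 1.5, +1), DeformitySpec("L4", 0.4, 1.5, -1)),
}


def default_config(stage: int, group: str, design: str | None = None) -> GeneratorConfig:
    """Deterministic calibrated configuration for a (stage, group) cell.

    ``design`` selects the study arm. It defaults per group: Im3/Im5/Im6 only
    exist in the single-harvest ``critical_timings`` arm (stage 9); Im4 and
    control default to the ``ontogenetic`` arm, where Im4 was followed over
    stages — pass design="critical_timings" explicitly for the E9
    single-harvest Im4 calibration (about five abnormal vertebrae) instead of
    the ontogenetic one (eight wedged).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if design is None:
        design = "critical_timings" if group in ("Im3", "Im5", "Im6") else "ontogenetic"
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    if group in ("Im3", "Im5", "Im6") or (group != "control" and design == "critical_timings"):
        if stage != 9:
            raise ValueError(f"group {group} in the {design} arm is only harvested at E9")

    if group == "control":
        rib_plan = ()
        if stage >= 6:
            rib_plan = _default_rib_plan(CONTROL_RIB_L5_MM[stage], 0.0, WAVE_WAVELENGTH_MM)
        return GeneratorConfig(
            stage=stage,
            group=group,
            design=design,
            target_height_mm=CONTROL_HEIGHT_MM[stage],
            height_sd_mm=HEIGHT_SD_MM[stage],
            rib_plan=rib_plan,
            rib_length_sd_mm=CONTROL_RIB_SD_MM.get(stage, 0.0),
        )

    if design == "critical_timings":
        if group == "Im5":
            l5, l5_sd = IM5_RIB_L5_MM, IM5_RIB_SD_MM
        else:
            l5, l5_sd = CONTROL_RIB_L5_MM[9], CONTROL_RIB_SD_MM[9]
        return GeneratorConfig(
            stage=9,
            group=group,
            design=design,
            target_height_mm=CONTROL_HEIGHT_MM[9],
            height_sd_mm=HEIGHT_SD_MM[9],
            deformities=_CRITICAL_DEFORMITIES[group],
            wedge_count_mean=CRITICAL_WEDGE_MEAN[group],
            wedge_count_sd=0.0,
            fusion_plan=CRITICAL_FUSION[group],
            rib_plan=_default_rib_plan(l5, 0.0, WAVE_WAVELENGTH_MM),
            rib_length_sd_mm=l5_sd,
            absent_specimen_fraction=CRITICAL_ABSENT_FRACTION[group],
        )

    # ontogenetic Im4
    rib_plan = ()
    rib_sd = 0.0
    if stage >= 7:
        rib_plan = _default_rib_plan(
            IM4_ONT_RIB_L5_MM[stage], IM4_ONT_WAVE_AMP_MM[stage], WAVE_WAVELENGTH_MM
        )
        rib_sd = IM4_ONT_RIB_SD_MM[stage]
    elif stage == 6:
        rib_plan = _default_rib_plan(0.4, 0.0, WAVE_WAVELENGTH_MM)
        rib_sd = 0.1
    return GeneratorConfig(
        stage=stage,
        group=group,
        design=design,
        target_height_mm=CONTROL_HEIGHT_MM[stage] * IM4_HEIGHT_FACTOR[stage],
        height_sd_mm=HEIGHT_SD_MM[stage],
        deformities=_ONT_DEFORMITIES[stage],
        wedge_count_mean=IM4_ONT_WEDGE_MEAN[stage],
        wedge_count_sd=IM4_ONT_WEDGE_SD[stage],
        rib_plan=rib_plan,
        rib_length_sd_mm=rib_sd,
    )


# ---------------------------------------------------------------------------
# spine construction


def _deformity_indices(config: GeneratorConfig, labels: list[str]) -> list[tuple[int, float, float]]:
    terms = []
    for d in config.deformities:
        if d.centre_label not in labels:
            raise ValueError(f"invalid deformity location {d.centre_label!r}")
        terms.append((labels.index(d.centre_label), d.sign * d.amplitude_mm, d.width_vertebrae))
    return terms


def _centre_x(i: np.ndarray, n: int, A: float,
              bumps: Sequence[tuple[int, float, float]]) -> np.ndarray:
    x = A * np.sin(2 * np.pi * (i - (n - 1) / 2) / n)
    for c, amp, w in bumps:
        x = x + amp * np.exp(-((i - c) ** 2) / (2 * w**2))
    return x


def _centre_x_derivs(i: np.ndarray, n: int, A: float,
                     bumps: Sequence[tuple[int, float, float]]) -> tuple[np.ndarray, np.ndarray]:
    k = 2 * np.pi / n
    ph = k * (i - (n - 1) / 2)
    d1 = A * k * np.cos(ph)
    d2 = -A * k**2 * np.sin(ph)
    for c, amp, w in bumps:
        g = amp * np.exp(-((i - c) ** 2) / (2 * w**2))
        d1 = d1 + g * (-(i - c) / w**2)
        d2 = d2 + g * (((i - c) ** 2 - w**2) / w**4)
    return d1, d2


def _solve_geometry(config: GeneratorConfig) -> tuple[list[str], float, np.ndarray]:
    """Vertebral spacing and sagittal x offsets with the C8-L7 chord pinned
    exactly to the target height (before noise)."""
    labels = make_labels(config.region_counts)
    n = len(labels)
    i_top = labels.index("C8")
    i_bot = labels.index("L7")
    span = i_bot - i_top
    bumps = _deformity_indices(config, labels)
    h = config.target_height_mm
    idx = np.arange(n, dtype=float)
    s = h / span
    x = np.zeros(n)
    for _ in range(8):
        # baseline amplitude giving the configured template curvature at the
        # sine extremum: GC ~ A (2 pi / n)^2 / s^2 there
        A = config.baseline_gc_mm_inv * s**2 * (n / (2 * np.pi)) ** 2
        x = _centre_x(idx, n, A, bumps)
        dx = x[i_bot] - x[i_top]
        if abs(dx) >= h:
            raise ValueError("deformities too large for the target height")
        s = math.sqrt(h * h - dx * dx) / span
    # freeze x, final exact spacing: chord = hypot(span*s, dx) = h
    dx = x[i_bot] - x[i_top]
    s = math.sqrt(h * h - dx * dx) / span
    return labels, s, x


def _wedge_plan(config: GeneratorConfig) -> tuple[WedgeSpec, ...]:
    k = int(round(config.wedge_count_mean))
    k = max(0, min(k, len(config.wedge_pool)))
    return config.wedge_pool[:k]


def generate_spine(config: GeneratorConfig, seed: int,
                   specimen_id: str | None = None) -> Spine:
    """Build one spine: centres on the template curve, endplates perpendicular
    to the local tangent, planted wedges and fusions, then landmark noise."""
    rng = np.random.default_rng([int(seed), 0])
    labels, s, x = _solve_geometry(config)
    n = len(labels)
    centres = np.column_stack([x, -s * np.arange(n, dtype=float), np.zeros(n)])

    # local cranial unit tangents from central differences
    diffs = np.empty_like(centres)
    diffs[1:-1] = centres[:-2] - centres[2:]
    diffs[0] = centres[0] - centres[1]
    diffs[-1] = centres[-2] - centres[-1]
    cranial = diffs / np.linalg.norm(diffs, axis=1, keepdims=True)

    wedge_by_label = {w.label: w for w in _wedge_plan(config)}
    fused_next = {a for a, _ in config.fusion_plan}
    extended = set()
    for a, b in config.fusion_plan:
        if a not in labels or b not in labels or labels.index(b) != labels.index(a) + 1:
            raise ValueError(f"fusion plan pair {(a, b)} is not adjacent")
        extended.add((a, "inf"))
        extended.add((b, "sup"))

    half_w = 0.7 * s     # endplate half-width in the sagittal plane
    off = 0.4 * s        # endplate offset from the centre along the axis
    off_fused = 0.55 * s # overlapping offset for planted fusions (gap < 0)

    vertebrae = []
    for i, lab in enumerate(labels):
        u = cranial[i]
        e = np.array([u[1], -u[0], 0.0])
        e /= np.linalg.norm(e)
        sup_off = off_fused if (lab, "sup") in extended else off
        inf_off = off_fused if (lab, "inf") in extended else off
        sup_mid = centres[i] + sup_off * u
        inf_mid = centres[i] - inf_off * u
        e_sup = e
        if lab in wedge_by_label:
            theta = math.radians(wedge_by_label[lab].angle_deg)
            if len(vertebrae) % 2:  # alternate wedge orientation down the spine
                theta = -theta
            c_t, s_t = math.cos(theta), math.sin(theta)
            e_sup = np.array([c_t * e[0] - s_t * e[1], s_t * e[0] + c_t * e[1], 0.0])
        vertebrae.append(
            Vertebra(
                label=lab,
                centre=centres[i].copy(),
                superior_endplate=np.stack([sup_mid - half_w * e_sup,
                                            sup_mid + half_w * e_sup]),
                inferior_endplate=np.stack([inf_mid - half_w * e,
                                            inf_mid + half_w * e]),
                fused_with_next=lab in fused_next,
            )
        )

    if config.noise_sd_mm > 0:
        for v in vertebrae:
            v.centre = v.centre + rng.normal(0.0, config.noise_sd_mm, 3)
            v.superior_endplate = v.superior_endplate + rng.normal(
                0.0, config.noise_sd_mm, (2, 3)
            )
            v.inferior_endplate = v.inferior_endplate + rng.normal(
                0.0, config.noise_sd_mm, (2, 3)
            )

    if specimen_id is None:
        specimen_id = f"{config.group}_E{config.stage}_s{seed}"
    return Spine(
        specimen_id=specimen_id,
        stage=config.stage,
        group=config.group,
        vertebrae=vertebrae,
        region_counts=dict(config.region_counts),
    )


def generating_curvature(config: GeneratorConfig) -> dict[str, float]:
    """Analytic sagittal curvature of the generating centre curve at each
    vertebra (mm^-1) — the ground truth that measured GC profiles should
    recover on noise-free specimens."""
    labels, s, _ = _solve_geometry(config)
    n = len(labels)
    A = config.baseline_gc_mm_inv * s**2 * (n / (2 * np.pi)) ** 2
    bumps = _deformity_indices(config, labels)
    idx = np.arange(n, dtype=float)
    d1, d2 = _centre_x_derivs(idx, n, A, bumps)
    # curve (x(i), -s i): kappa = s |x''| / (x'^2 + s^2)^(3/2)
    kappa = s * np.abs(d2) / (d1**2 + s**2) ** 1.5
    return dict(zip(labels, kappa.tolist()))


# ---------------------------------------------------------------------------
# rib construction

_RIB_POINTS = 31
_RIB_SWEEP_RAD = 1.2


def _rib_curve(origin: np.ndarray, z_sign: float, spec: RibSpec,
               rng: np.random.Generator, noise_sd: float) -> Polyline3:
    u = np.linspace(0.0, 1.0, _RIB_POINTS)
    base = np.column_stack(
        [
            (1.0 - np.cos(u * _RIB_SWEEP_RAD)) / _RIB_SWEEP_RAD,  # anterior wrap
            -0.25 * u,                                            # caudal droop
            z_sign * np.sin(u * _RIB_SWEEP_RAD) / _RIB_SWEEP_RAD, # lateral sweep
        ]
    )
    base -= base[0]
    scale = spec.target_length_mm / np.linalg.norm(np.diff(base, axis=0), axis=1).sum()
    # wave period count pinned by the target length so the inflection count
    # depends only on the wavelength setting, not on the amplitude
    n_periods = spec.target_length_mm / spec.waviness_wavelength_mm
    pts = base
    for _ in range(8):
        pts = origin + scale * base
        if spec.waviness_amplitude_mm > 0:
            seg = np.linalg.norm(np.diff(scale * base, axis=0), axis=1)
            t = np.concatenate([[0.0], np.cumsum(seg)])
            pts = pts.copy()
            pts[:, 1] += spec.waviness_amplitude_mm * np.sin(
                2 * np.pi * n_periods * t / t[-1]
            )
        length = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        scale *= spec.target_length_mm / length
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return Polyline3(pts)


def generate_ribs(config: GeneratorConfig, spine: Spine, seed: int) -> list[Rib]:
    """Build the planned ribs, launched from their thoracic vertebral centres.

    Present ribs get arc length equal to the plan target (well within 0.5 %
    before noise); planned-absent ribs are returned with no centerline.
    """
    rng = np.random.default_rng([int(seed), 1])
    ribs = []
    for spec in config.rib_plan:
        if not spec.present:
            ribs.append(Rib(side=spec.side, index=spec.index, centerline=None))
            continue
        anchor = spine.get(f"T{spec.index}")
        if anchor is None:
            raise ValueError(f"no thoracic vertebra T{spec.index} for rib {spec}")
        z_sign = 1.0 if spec.side == "left" else -1.0
        ribs.append(
            Rib(
                side=spec.side,
                index=spec.index,
                centerline=_rib_curve(anchor.centre, z_sign, spec, rng, config.noise_sd_mm),
            )
        )
    return ribs


def generate_specimen(config: GeneratorConfig, seed: int,
                      specimen_id: str | None = None) -> Specimen:
    spine = generate_spine(config, seed, specimen_id=specimen_id)
    return Specimen(spine=spine, ribs=generate_ribs(config, spine, seed))


# ---------------------------------------------------------------------------
# cohorts


def _stratified_normal(n: int) -> np.ndarray:
    """Symmetric mid-quantile normal deviates (sum exactly balances to 0)."""
    z = _norm.ppf((np.arange(n) + 0.5) / n)
    return z - z.mean()


def _balanced_counts(mean: float, sd: float, n: int,
                     rng: np.random.Generator, lo: int = 0, hi: int = 10**6) -> np.ndarray:
    """Integer counts with cohort mean pinned to round(mean*n)/n and spread
    approximating ``sd`` via zero-sum jitter; order shuffled by ``rng``."""
    total = int(round(mean * n))
    base = np.full(n, total // n, dtype=int)
    base[: total - int(base.sum())] += 1
    base = np.sort(base)[::-1]
    if sd > 0 and n >= 2:
        deltas = np.rint(sd * _stratified_normal(n)).astype(int)
        drift = int(deltas.sum())
        order = np.argsort(deltas)
        k = 0
        while drift != 0:
            idx = order[-1 - (k % n)] if drift > 0 else order[k % n]
            deltas[idx] -= int(np.sign(drift))
            drift = int(deltas.sum())
            k += 1
        counts = base + np.sort(deltas)  # most negative jitter on largest base
    else:
        counts = base.copy()
    # repair any clipping while preserving the total
    deficit = int(np.sum(np.maximum(lo - counts, 0)))
    counts = np.maximum(counts, lo)
    while deficit > 0:
        i = int(np.argmax(counts))
        if counts[i] <= lo:
            break
        counts[i] -= 1
        deficit -= 1
    counts = np.minimum(counts, hi)
    return counts[rng.permutation(n)]


def generate_cohort(config: GeneratorConfig, n: int, base_seed: int) -> list[Specimen]:
    """Generate ``n`` specimens with seeds ``base_seed + i``.

    Heights and rib lengths take mean-preserving stratified jitter at the
    configured SDs; wedge counts take zero-sum integer jitter; absent-rib
    planting is assigned deterministically to the first
    ``round(absent_specimen_fraction * n)`` specimens in seed order.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng([int(base_seed), 2])
    zq = _stratified_normal(n)
    hz = zq[rng.permutation(n)]
    rz = zq[rng.permutation(n)]
    counts = _balanced_counts(
        config.wedge_count_mean, config.wedge_count_sd, n, rng,
        hi=len(config.wedge_pool),
    )
    n_absent = int(round(config.absent_specimen_fraction * n))
    ref_l5 = next(
        (r.target_length_mm for r in config.rib_plan
         if (r.side, r.index) == ("left", 5)),
        None,
    )
    specimens = []
    for i in range(n):
        height = config.target_height_mm + config.height_sd_mm * hz[i]
        height = max(height, 0.2 * config.target_height_mm)
        if ref_l5:
            factor = max((ref_l5 + config.rib_length_sd_mm * rz[i]) / ref_l5, 0.1)
        else:
            factor = 1.0
        plan = []
        for r in config.rib_plan:
            present = r.present and not (
                i < n_absent and (r.side, r.index) == config.absent_rib
            )
            plan.append(
                replace(r, present=present,
                        target_length_mm=r.target_length_mm * factor)
            )
        cfg_i = replace(
            config,
            target_height_mm=height,
            height_sd_mm=0.0,
            wedge_count_mean=float(counts[i]),
            wedge_count_sd=0.0,
            rib_plan=tuple(plan),
            rib_length_sd_mm=0.0,
            absent_specimen_fraction=0.0,
        )
        sid = f"{config.group}_E{config.stage}_{config.design[:4]}_{i:02d}"
        specimens.append(generate_specimen(cfg_i, base_seed + i, specimen_id=sid))
    return specimens
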