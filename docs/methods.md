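# Methods

This note documents the models, numerical choices and calibration behind
`spinemorph`: what each measure computes, which parameters matter, what the
synthetic generator does and does not emulate, and the design decisions
taken where the methodology was genuinely open.

## Coordinates, units and anatomy

All coordinates are millimetres in a right-handed frame: +x anterior,
+y cranial, +z left. The sagittal plane is x–y, frontal y–z, axial x–z.
The default vertebral layout is the chick embryonic one — 14 cervical (C),
7 thoracic (T), 7 lumbar (L) — with labels C1…C14, T1…T7, L1…L7 and
quantitative analysis restricted to the window C8…L7, the range reliably
visible in optical projection tomography scans of whole-mount cleared
specimens. Internal indices are 0-based; anatomical labels are 1-based.

## Vertebral-line curvature

A piecewise-cubic spline is fitted per coordinate through the ordered
vertebral-body centres, parameterised by vertebra ordinal (p = 1, 2, …).
The default fit is the interpolating extreme (not-a-knot boundary, zero
residual at every knot); a penalised smoothing fit is available either by
passing the penalty weight directly or by capping the RMS knot residual, in
which case the largest admissible penalty is found by bisection. Leaving
noise handling to an explicit, user-visible knob keeps the default fully
reproducible.

Geometric curvature GC(p) = 1/R(p) is the reciprocal of the osculating
circle radius. Although the defining formula |C′×C″|/|C′|³ is the 3D one,
reported spinal curvature is sagittal, and the curvature evaluator defaults
to the planar specialisation |x′y″ − y′x″|/(x′²+y′²)^{3/2} on the sagittal
projection; the 3D cross-product form is exposed for genuinely 3D curves
such as rib centerlines. GC is parameterisation-invariant, so the ordinal
parameter does not affect the mm⁻¹ scale. Profiles report absolute GC at
the knots of the window vertebrae; a signed sagittal curvature is also
exposed, with the convention that positive bows the column posteriorly
(kyphotic) and negative anteriorly (lordotic) when traversing cranial to
caudal. No automatic kyphosis/lordosis call is made: published region calls
of that kind are qualitative, and any threshold here would be invented.
Whether the historical pipeline evaluated curvature at knots or at
arc-length midpoints of vertebrae is not documented; knots were chosen.

Missing vertebrae inside the window: the spline is fitted through the
available centres at their true ordinals and the profile carries NaN at the
missing labels, with a warning.

Spine height is the Euclidean C8–L7 centre distance after sagittal
projection. Outline overlays are aligned by translating each centre trace
so T1 sits at the origin — translation only, no rotation or scaling, so
curvature and distances are untouched.

## Wedging and fusion

The wedge angle of a vertebra is the angle between its superior and
inferior endplate lines in the sagittal projection, computed from the
absolute cosine of the endplate direction vectors. This equals the
intersection angle of the two undirected lines but remains defined when
they are parallel (0°). A vertebra is wedged when its angle strictly
exceeds the threshold, default 10°, a value reflecting normal variability
in vertebral shape; the strict comparison carries a 1e-9° guard so an angle
constructed at exactly the threshold can never flip the classifier through
float rounding. A single global threshold is used for all regions.

Fusion is annotation-first (a `fused_with_next` flag, mirroring visual
calls on 3D data) complemented by a geometric criterion: the signed gap
between the facing endplate midpoints of adjacent vertebrae, projected on
the axis joining their centres, is non-positive (overlapping endplates).
Both members of a fused pair are flagged. A vertebra is abnormal when
wedged or fused; cohort summaries report mean and sample SD (n−1) of the
wedged/fused/abnormal counts per (group, stage), with SD missing for
single-specimen groups.

## Rib metrics

Only the dorsal (vertebral) rib portion is modelled — one centerline per
(side, index). Curved length L_C is the polyline arc length, L_S the
endpoint chord, and tortuosity the inflection count metric
ICM = N·L_C/L_S. N = 0 gives ICM = 0 exactly (no N+1 variant): a single
smooth arc is not tortuous.

Inflection counting works on the centerline resampled to n = 100 points
uniform in arc length (default) and proceeds in three steps, all scaled to
arc-length fractions so the result is independent of the resampling
density:

1. *Noise guard.* Landmark noise that is negligible for length estimates
   can dominate the direction of the second derivative on gently curved
   segments, making a smooth rib read as tortuous. The resampled points are
   smoothed with a Gaussian kernel of σ = 2 % of the arc length, which
   suppresses that noise while preserving waviness at wavelengths an order
   of magnitude above the landmark spacing.
2. *Discrete Frenet frame.* First and second derivatives come from central
   differences with a stencil of ~10 % of the arc length; the principal
   normal is the tangent-orthogonal component of the second derivative.
   Samples whose curvature magnitude falls below a floor of 1e-4 mm⁻¹
   carry no normal. Endpoint regions inside the stencil are excluded.
3. *Flip detection.* Normals are compared at a stride of ~5 % of the arc
   length; a jump with ΔN·ΔN > 1 (rotation > 60°) marks an inflection.
   Because a base arc can hold curvature above the floor through a wave
   crossing, one flip may resolve into several consecutive above-threshold
   steps; runs of adjacent jumps are merged into a single inflection event.
   A smoothly rotating frame (a helix) stays far below the threshold at
   this stride and yields N = 0.

The scale choices bound the resolvable waviness: wavelengths must exceed
roughly ten times the landmark spacing and twice the stencil width, and
crossings closer than ~5 % of the arc length to an endpoint are inside the
excluded boundary region and may or may not be counted. For planar curves
the count is cross-checked in the tests against sign changes of the signed
curvature. Tortuosity is computed in 3D (whether the historical measurement
was 3D or projected is not documented; 3D discards nothing).

The rib census reports per-slot presence (both sides × thoracic count),
the specimen-level "has at least one absent rib" flag, and fused pairs —
annotation or sustained geometric contact (minimum inter-centerline
distance below 0.05 mm over ≥ 10 % of the arc length of an adjacent
same-side pair). Cohort summaries use the fifth left vertebral rib as the
reference (the rib present in essentially all specimens); specimens whose
reference rib is absent are excluded from length/ICM means but counted in
the absent-rib proportion. A mean nearest-neighbour inter-rib spacing
statistic is exposed as a clearly-labelled descriptive extension and takes
no part in calibration.

## Segmentation proportions

Histological joint status enters as count tables: per region (cervical /
thoracic / lumbar) and joint type (vertebral body / spinous process), the
number of fused-or-partially-segmented joints over the total visible across
sections. The fused proportion is the plain ratio; pooling across sections
or specimens sums counts, so pooled proportions equal count-weighted
combinations. With one to three usable specimens per group, no statistics
are attached — exports are per-specimen, dot-plot style.

## Group statistics

Two designs: *critical timings* (all groups harvested at one stage,
one-way ANOVA + Tukey HSD per vertebral location against a single pooled
control) and *ontogenetic* (two-tailed unpaired t-test per location between
the immobilised group and its age-matched control). The t-test is the
pooled-variance Student test — the plain reading of "unpaired t-test" —
with Welch available via scipy if a caller needs it. Significance is
α = 0.05 with no multiplicity correction across locations, mirroring how
such profiles are conventionally reported; the output is a per-location
table, and readers must treat the family of locations accordingly.
Degenerate inputs are handled explicitly (zero variance everywhere → F = 0,
p = 1; zero pooled variance with unequal means → p = 0 with a warning;
groups with fewer than two values are excluded with a warning). Pooling
controls treated on different days is supported by a descriptive
per-location ANOVA across the treatment-day subgroups — no formal
equivalence test, since none is standard here. At k = 2 the Tukey
comparison reduces to the pooled t-test, which the suite checks to 1e-6,
and the per-location false-positive rate on null cohorts is verified to sit
at 5 % ± 2 points.

## The synthetic generator

No 3D landmark data were deposited with the chick immobilisation study the
pipeline quantifies, so the generator is the package's validation surface:
its defaults *are* the study conditions, and the round-trip property —
measurement pipeline applied to generated cohorts returns the calibration
targets — is what the acceptance tests check.

A spine is built by placing the 28 vertebral centres at uniform ordinal
spacing along −y, adding a sagittal x-profile that is the sum of a gentle
sinusoidal template (amplitude set so the template curvature is
0.03 mm⁻¹ — control curvature magnitudes are not published as numbers, so
a "gentle but nonzero" template was chosen once) and Gaussian deformity
bumps (centre label, amplitude in mm, width in vertebrae, kyphotic or
lordotic sign). The inter-vertebral spacing is then solved so the C8–L7
chord equals the target height *exactly* before noise. Endplates are
segments of width 1.4× the spacing, offset ±0.4× the spacing from the
centre along the local tangent and perpendicular to it, except: planted
wedges rotate the superior endplate by the planted angle (default 15°,
alternating orientation down the column), and planted fusions extend the
two facing endplates so their gap is negative, plus the annotation flag.
I.i.d. Gaussian noise (default σ = 5 µm, an OPT-scale landmark error) is
added to every landmark last. Whether real control variance is correlated
along the spine is unknowable from published group statistics; i.i.d.
landmark noise is the one-parameter choice.

Ribs launch laterally from their thoracic vertebral centre as a fixed
planar arc (1.2 rad sweep) with a caudal droop, uniformly scaled so the
curved length equals the per-rib target exactly before noise; sinusoidal
waviness of configurable amplitude is superimposed with the period count
pinned by the target length (so the inflection count depends only on the
wavelength setting, default 0.8 mm, and ICM is non-decreasing in
amplitude). Relative rib lengths across indices 1–7 follow a fixed profile
peaking at the reference rib 5.

### Calibration table

Published group statistics (verbatim targets) are marked •; the rest is
generator calibration chosen once to interpolate plausibly between them.

| Quantity | Values |
|---|---|
| Control spine height (mm) | E5 4.8, E6 **6.2** •, E7 7.8, E8 9.3, E9 **10.9** • |
| Height SD (mm) | 0.4 • (E6) … 0.6 • (E9); intermediates interpolated |
| Immobilised-at-E4 height factor | 1.0 through E7, 0.9 at E8/E9 (a significant decrease is published, no value; 0.9 invented) |
| Control fifth-left-rib L_C (mm) | E6 0.6, E7 1.3, E8 2.1, E9 **2.7** • (SD 0.36 •) |
| Immobilised-at-E5 rib L_C (mm) | **1.7** • (SD 0.22 •) |
| Immobilised-at-E4 rib L_C (mm) | E7 0.9, E8 1.9, E9 2.3; waviness amplitude 0.06/0.10/0.04 mm (tortuosity is significantly raised at E8 only; no numeric targets exist) |
| Wedged vertebrae, immobilised at E4 | E6 1, E7 **2.8** • (SD 1.8 •), E8 5, E9 **8** • (SD 1.2 •) |
| Single-harvest arm at E9 | E3/E4 groups: 3 wedged + 1 fused pair = **5 abnormal** •; E5 group ~3 wedged, E6 group ~2 wedged, no fusion |
| Absent-rib specimen fractions | E3 1/7, E4 2/9, E5 **5/6** •, E6 1/6 |

The same (group, stage) cell was measured in two arms with different
severity (notably the immobilised-at-E4, harvested-E9 cohort: eight wedged
vertebrae in the ontogenetic arm, about five abnormal in the single-harvest
arm), so configurations carry a `design` axis; the default per group is the
arm in which that group primarily exists, and the other is selected
explicitly.

### Cohort variability is stratified, not i.i.d.

Per-specimen heights and rib lengths are jittered by mean-preserving
stratified normal quantiles at the published SDs, and wedge counts by
zero-sum integer jitter around the target mean; absent-rib planting is
assigned deterministically to the first ⌈fraction·n⌉ specimens in seed
order. The generator is a calibration artifact whose cohort means must sit
on the published group statistics at n as small as 6–10; i.i.d. draws at
the published SDs would leave the cohort mean itself ~±0.6 wedged vertebrae
off target at n = 10. The cost is that *between-cohort* variability is
understated: generated cohorts emulate the published means and approximate
the published spreads, not sampling variability of real replicate
experiments. Consequently, passing round-trip tests demonstrate that the
measurement chain is unbiased and correctly scaled — not that it was
validated against independent biological replication, which no synthetic
data can provide.

Other simplifications: spinous processes are not given geometry (nothing in
the measurement chain consumes them; their fusion enters as histology
counts only); no growth dynamics, somite or sclerotome structure; wedge
plans draw from a fixed label pool in a fixed order, so which vertebrae are
wedged is deterministic given the count; rib absence is planted at a fixed
slot (left 3) distinct from the reference rib, matching its near-universal
presence. Generation is a pure function of (config, seed): the same seed
reproduces a cohort bit-for-bit.

## Problem sizes and determinism

Default analyses use 28-vertebra spines, 14 ribs of 31 landmarks each,
rib resampling n = 100, cohorts of 6–10 specimens, and 10-cohort
calibration checks; these sizes keep the full test suite and the
acceptance script in the seconds-to-a-minute range while leaving every
statistic well inside its asymptotic regime. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; pipeline runs
log the seeds and parameters needed for exact replay, and re-running on
identical inputs produces byte-identical CSVs.

## Known limitations

- The wedge threshold, fusion gap criterion and contact thresholds are
  global; region-specific thresholds are not supported.
- Inflection counting has finite resolution: waviness below ~10× the
  landmark spacing, below twice the stencil width, or within ~5 % of the
  arc length of an endpoint is not reliably resolved.
- The statistics module implements exactly the published comparison scheme;
  it does not add multiplicity control, equivalence testing or mixed
  models, and per-location p-value profiles should be read with that in
  mind.
- The generator emulates group statistics, not biological shape variation;
  see above for what round-trip recovery does and does not establish.
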