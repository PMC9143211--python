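# Methods

## Problem

After radiotherapy for head-and-neck cancer, mandibular osteoradionecrosis
(ORN) may require a segmental resection of the affected bone. Where to place
the bone cuts is an open surgical question: margins placed inside heavily
irradiated bone appear to carry a higher risk of ORN recurrence. `orndose`
implements the 3D dosimetric–surgical analysis behind that question: it fuses
the radiotherapy dose distribution with a CT-derived bone model, reconstructs
isodose volumes, applies the performed (or planned) resection virtually, and
quantifies how much irradiated mandibular bone was removed and how much
remains — per patient, and compared between recurrent and non-recurrent
groups.

## Quantities

All volumes are in mL; every region is a voxel mask in one common patient
frame (DICOM LPS, millimetres). A voxel belongs to a region iff its *center*
is inside; this rule is simple, deterministic, and converges to the true
volume as spacing shrinks (verified on closed-form phantoms).

| symbol | meaning |
|---|---|
| Vm | total mandible volume |
| V56, V-PTV | whole-grid volume receiving >= 56 Gy, resp. the PTV dose |
| Vm56, Vm-PTV | mandibular portion of those regions |
| VmR | resected mandibular volume |
| Vm56R, Vm-PTV-R | residual irradiated mandibular volume after resection |

V56 and V-PTV are reported over the full dose grid (not the mandible): this
is the only reading consistent with published whole-cohort values of several
hundred mL, far larger than any mandible. The mandibular portions carry the
`Vm` prefix.

The 56 Gy threshold is inclusive (`dose >= 56`), applied to the dose grid
after trilinear resampling onto the CT frame. Voxels outside the dose grid's
support get 0 Gy — conservative, and irrelevant in practice because dose
grids cover the treated region. Isodose volumes can alternatively be built
from exported structure contours (the vendor route); both routes are
first-class, thresholding is the default because it is reproducible and
vendor-independent.

The PTV region comes from the RTSTRUCT contour when available, because the
PTV prescription varies per patient (56–72 Gy) and is not recoverable from a
single dose threshold; synthetic cases use the case's own PTV dose level.

## Resection model

A segmental resection is one or more oriented planes (point + unit normal,
normal pointing into the removed segment). Two modes:

* **half-space** (default): removed = mandible voxels on the positive side of
  *all* planes — the natural encoding of a two-plane segmental resection;
* **seed**: planes act as pure cuts; the removed piece is the connected
  component containing a seed point. This covers resections that are not an
  intersection of half-spaces, and (with no planes) removals without a bone
  cut such as an isolated condylectomy.

`apply_resection` partitions the mandible mask *exactly*: resected and
residual are disjoint and their union is the mandible, so volume accounting
is exact by construction, not within tolerance.

Cut planes can also be *recovered* from a pre/post-operative mask pair:
faces between kept and removed voxels are clustered (k-means on position +
scaled face normal) and a total-least-squares plane is fitted per cluster.
Fitting face *midpoints* rather than voxel centers keeps the plane offset
accurate to roughly half a voxel; recovery on convex phantoms is within 1
degree and 0.5 mm at 0.5 mm spacing.

## Registration

Post-operative bone models are mapped back into the RT frame by rigid
point-to-plane ICP over mesh vertices (correspondences from a KD-tree,
linearized normal-distance minimization per step). Point-to-*plane* matters:
the mandibular arch is locally a surface of revolution, and point-to-point
correspondences lock into poses slid a few degrees along the arch; the
normal-distance objective lets points slide tangentially and converges to
the exact pose on phantoms. Because partial, near-symmetric shapes still
offer misleading local minima, the initial pose is chosen from a dense start
set (centroid + principal-axes alignments spun in 6-degree steps about each
principal axis, plus identity), screened by subsampled mean nearest-neighbour
distance with a translation-settling step, and the best few starts are
refined in full. Runs are ranked by *untrimmed* mean distance — trimming
would hide exactly the asymmetric landmarks (condyles, angles) that
disambiguate the pose. Correspondences beyond 3x the median distance are
trimmed within each iteration, which tolerates partial overlap (a resected
specimen against the full pre-operative model); an inlier fraction below 25%
sets a warning. When the mandible was reconstructed and its two residual
segments moved independently, each segment is registered on its own
(`register_two_segment`).

## Osteotomy-plane classification

Each osteotomy plane is classified against the 56 Gy mandibular volume:
`outside` (cut entirely through bone below 56 Gy), `lingual_only`,
`buccal_only`, or `bicortical`. The test set is: Vm56 voxels within half a
voxel diagonal of the plane (so a plane cannot slip between voxel centers)
and within the outer cortical shell of the mandible (default 2 mm, a
conventional cortical-plate thickness; the distinction between cortex and
medullary bone is anatomical, not imaged here). Contact areas are estimated
as slab voxel volume divided by slab thickness.

Lingual vs buccal requires a midline of the arch, for which no standard
definition exists; ours is automatic: skeletonize the axial projection of
the mandible mask, fit a circle to the skeleton, and describe the midline in
polar form as the per-angle-bin (10 degrees) median skeleton radius. Binned
medians both smooth the curve and prune the radial spurs skeletonization
produces at the arc ends. "Lingual" is the concave side — radially inside
the midline. A self-intersecting midline (multivalued radius within a bin)
is rejected as degenerate. `buccal_only` is kept as its own category even
though published tabulations list only outside / lingual-only / bicortical;
collapsing it would silently lose information.

Resections with no bone cut that leave irradiated bone behind are classified
bicortical by convention (`classify_resection_without_cut`), matching how
such cases are counted clinically; likewise cuts through grafts are
classified against the residual Vm56 exactly as native-bone cuts.

## Statistics

Group comparisons (recurrent vs non-recurrent) are normality-gated, matching
standard practice in this literature: a Kolmogorov–Smirnov test screens each
group for normality, Student's two-sample t-test (pooled variance; Welch by
flag) when both pass, Mann–Whitney U otherwise. Two deliberate refinements:

* Because the normal's mean and SD are estimated from the sample, the plain
  KS null is anticonservative; the p-value is therefore taken from a
  **Lilliefors Monte-Carlo null** (10^4 seeded draws, cached per sample
  size). The internal seed is a fixed constant: the null table is a
  deterministic property of the test, not of the data.
* Mann–Whitney p-values are **exact** (full enumeration) whenever sample
  sizes permit and there are no ties, and use the tie-corrected normal
  approximation otherwise (scipy's standard policy). Groups too small for
  the normality screen (n < 4) go to Mann–Whitney directly.

All tests are two-sided at alpha = 0.05 with no multiplicity correction (a
Holm option exists nowhere because the analysis reports per-metric
comparisons the way the field does); calibration is verified by simulation:
type-I error 5% within Monte-Carlo error at 2000 null replicates, and >= 90%
rejection at the study-scale effect (means 10.9 vs 30.7 mL, SDs 5 vs 8, n 5
vs 28).

Per-patient percentage metrics are computed per patient and then averaged;
mean percentages therefore need not equal ratios of mean volumes. Every
metric record is validated against its internal invariants (Vm56 <= Vm,
Vm56R <= Vm56, ratios recomputing from the mL fields within 0.5 points, ...)
before being reported.

## Synthetic data

No patient imaging ships with the package; the synthetic module generates
everything the pipeline consumes, with known ground truth:

* **Phantoms.** Spheres (volume 4/3 pi r^3) and horseshoes — circular-arc
  tubes with volume given exactly by Pappus' theorem (pi r_tube^2 x arc
  length). Default horseshoe draws (arch radius 28–35 mm, tube radius
  9–11.5 mm, span 220–275 degrees) give mandible-scale volumes of roughly
  27–60 mL, inside the 26–95 mL range reported for real cohorts. The tube
  radius is generous relative to a real mandibular cross-section; it is the
  price of reaching realistic total volumes with a single tube.
* **Dose.** A Gaussian point source, `dose = peak * exp(-d^2 / 2 sigma^2)`,
  peak constrained to the 56–72 Gy prescription envelope. This is *not* a
  beam model; the analysis only needs a smooth monotone field whose >= 56 Gy
  mandibular fraction is controllable. Focus positions on the arch and
  falloff scales are drawn so that fraction varies across cases (roughly
  10–40%).
* **Resections.** Two planes transversal to the arch, each tilted 5–14
  degrees off vertical about the local radial direction (real osteotomies
  are rarely vertical, and tilted planes also avoid the coherent
  voxel-rounding that axis-aligned planes produce on a regular grid). Two
  scenarios: *bracketing* resections that remove the >= 56 Gy bone entirely
  with >= 6 mm geometric margin (residual irradiated volumes exactly zero),
  and *partial* resections cutting through the hot region.
* **Ground truth** is computed by direct analytic membership tests on a
  4x-finer voxel grid covering the same extent — one oracle for all shapes,
  and its convergence is itself verified against the closed-form cases.
  Cases in which any nonzero metric falls below 2.5 mL on the fine grid are
  redrawn: at such scales voxel counting is dominated by surface ambiguity
  (absolute discretization scale ~0.1 mL at millimetre spacing) and no
  meaningful relative comparison exists. Published per-patient volumes of
  interest are an order of magnitude larger.
* **Cohorts.** Group-structured tables (default 5 recurrent vs 28
  non-recurrent) in two sampling modes: *parametric* (metric values drawn
  from group-dependent truncated normals — recurrent Vm ~ N(47.8, 10),
  non-recurrent ~ N(65.4, 15), truncated to [25, 95] mL; Vm56 ~ N(10.9, 5)
  vs N(30.7, 8) — cheap enough for thousands of statistical replicates) and
  *voxel* (a full phantom per patient, measured by the actual pipeline).
  All randomness flows from one explicit seed; generation is byte-
  deterministic.

### Problem sizes

The standard analysis grid for random cases is 0.85 mm isotropic (typical RT
planning CT in-plane resolution), giving a fine oracle grid of ~0.21 mm.
Sphere-phantom checks use 0.5 and 0.25 mm; registration and unit-test
phantoms use 1.0–1.5 mm, where sub-voxel behavior is not the question. The
100-case oracle comparison completes in a few minutes on one CPU.

### What passing does and does not show

The phantoms share the topology of the anatomy (a horseshoe arch, nested
dose regions, transversal cuts) but none of its texture: no teeth, no
cortical/trabecular HU gradient, no metal artefacts, no contour noise, and a
Gaussian ball instead of an IMRT dose. Passing therefore demonstrates that
the geometry, volumetrics, registration and statistics are *correct as
algorithms* — not that bone segmentation at HU 300 or a 2 mm cortical shell
are clinically optimal settings for any particular scanner or patient.

## Numerical choices and edge cases

* Marching cubes runs at the 0.5 level of the (optionally smoothed) binary
  indicator, padded by one background voxel so border-touching masks still
  close. Mesh-enclosed volume agrees with voxel counting within 2% on smooth
  phantoms at <= 0.5 mm spacing. A single-voxel mask yields the octahedral
  dual cell (1/6 of the voxel volume) — marching cubes' exact behavior for
  an isolated interior point.
* Bone segmentation keeps the largest 26-connected component above the HU
  threshold; an empty result is an error, not an empty mask.
* Contour rasterization assigns each contour to the nearest voxel plane
  (ties to the lower index, for determinism) and applies the even-odd rule,
  so nested polygons produce holes.
* Voxel centers exactly on a cutting plane stay with the residual (strict
  `> 0` on the resected side).
* Dose values are physical Gy: file scaling factors are applied at read
  time, never propagated.
* Oblique frames are supported by the geometry layer (direction matrices are
  general); contour rasterization and midline extraction require
  axis-aligned frames and say so.

## Known limitations

* Point-to-plane ICP with dense multi-start is a heuristic, not a global
  optimizer: a featureless (purely tubular) segment has a genuinely
  ambiguous pose, and registration of such shapes can settle into a slid
  pose. Real mandibles and the landmark phantoms carry enough asymmetry.
* The seed-mode resection assumes the cut planes actually separate the seed
  from the rest of the bone at voxel connectivity; pathological plane sets
  that graze the mask can leave the partition trivial.
* `fit_cut_planes` expects a roughly planar cut; saw-curve or stepped
  osteotomies will be approximated by the nearest plane.
* Manual plane digitization from panoramic radiographs carries an unknown
  accuracy; such planes enter the pipeline as given, and no accuracy
  contract is inherited for them.
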