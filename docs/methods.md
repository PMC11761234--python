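# Methods

## Scope and model

`faceasym` quantifies bilateral soft-tissue facial asymmetry on a
triangulated surface scan with named landmarks, two ways:

1. **Wireframe template.** Fifteen angular parameters — one per
   (region, axis) cell over five regions (labial, mandibular angle,
   cheek, chin, articular) and three axes — are defined as ordered
   landmark triplets (A, B, C) with B the vertex. The measured quantity is
   the full 3D angle `arccos(⟨A−B, C−B⟩ / (|A−B||C−B|))` in degrees (the
   dot product is clamped to [−1, 1] before the arccosine). The axis label
   of a parameter is a clinical attribution carried by the registry, not a
   projection rule: angles are not projected onto coordinate planes, so
   every parameter is invariant under rigid motion of the whole landmark
   set. Two triplets legitimately serve two cells each (∠Tr-Zg-Go for
   mandibular-angle Y and articular Y; ∠Me-Go-Mt for mandibular-angle X
   and chin Z); they are measured once and referenced twice.

   Asymmetry per parameter is the angle asymmetry index
   `AAI = |R − L| / L × 100 %`. The denominator is the anatomical-left
   angle exactly as the index is defined, which makes the index
   asymmetric in its arguments (AAI(L,R) ≠ AAI(R,L) in general); a config
   switch `aai_denominator="min"` provides the symmetric variant but is
   not the default. Grading is half-open: mild [0, 1)%, moderate [1, 3)%,
   severe [3, ∞)%.

2. **Mirroring and overlapping.** In the normalized frame the mesh is
   reflected across the midsagittal plane X = 0 (face winding reversed to
   preserve orientation), the reflection is rigidly aligned back onto the
   original, and for every original vertex the closest point on the
   aligned reflection is found by exact point-to-triangle projection. The
   deviation field stores the displacement vector, its norm, and a sign
   (positive where the mirrored surface lies outside the original along
   its vertex normal). Deviations are sampled one-way
   (original → mirrored). Region summaries report RMSE
   (`sqrt(mean d²)`) and MFM (`max d`) overall, and per axis on the
   absolute displacement components. Three criteria grade the summaries:
   RMSE 0.5/1 mm, MFM 3/6 mm, MFM 1/2 mm (half-open, like all bands).

A region's grade is mild only when its X, Y and Z parameters are all
mild; otherwise it is the worst axis grade.

## Standard frame

A true Frankfort horizontal needs skeletal porion and orbitale, which a
surface scan cannot supply. The package defines its standard frame from
soft-tissue surrogates: origin at the tragion midpoint, X along
Tr_R → Tr_L (anatomical left positive), Y the unit normal of the plane
through Tr_L, Tr_R and the exocanthion midpoint (signed superior, using
menton when present), Z = X × Y (anterior positive). The construction is
idempotent — recomputing the pose of posed landmarks yields the identity —
and equivariant under rigid motions, which the tests exercise directly.
This *defines* "normalized"; all axis-labelled outputs (per-axis
deviations, region boundary planes) refer to this frame. The midsagittal
plane is X = 0 by construction of the tragion pair.

## Regions of interest

The five clinical regions are bounded by anatomy (mentolabial and
nasofacial grooves, zygomatic and mandibular edges, earlobe and helix
levels) that a bare mesh does not label. Every curved boundary is
operationalized as a landmark-derived threshold in the normalized frame,
each one a named `RoiConfig` value:

| surrogate | default |
|---|---|
| mentolabial groove level | halfway from labiale inferius down to menton |
| labial/chin lateral extent | cheilion / mental-tubercle |x| + 5 mm |
| nasofacial groove plane | cheilion |x| + 5 mm |
| cheek lower edge | halfway from the gonion level down to the menton level |
| earlobe level | tragion y − 15 mm |
| mandibular-angle fan | radius 28 mm around gonion, behind the zygion plane |
| articular strip | helix-top to earlobe level, tragion-z to zygion-z |
| chin depth | 20 mm behind menton/gnathion |

Selection is half-open (lower bound inclusive) so masks are
deterministic. The regions intentionally overlap — in particular the
cheek, which reaches the mandible's lower edge, contains most of the
mandibular-angle fan, so a deformation at the mandibular angle also
registers in the cheek summary. That mirrors how the regions are defined
verbally in clinical use; the toolkit does not force a partition.

## Registration

`best_fit_align` is a trimmed rigid ICP with two stages. A coarse stage
matches source vertices to nearest target vertices (after centroid
pre-alignment) with closed-form Kabsch updates. Pure vertex-to-vertex
matching, however, stalls on lattice-shifted local minima once residuals
fall below the mesh spacing, and point-to-point updates converge only
linearly in the tangential directions — measured on planted transforms,
residual errors of 1–4° persisted after hundreds of iterations. The
refinement stage therefore matches against exact closest points on the
target *surface* and applies point-to-plane updates (the standard
linearized 6-DOF normal equations, re-orthonormalized through Rodrigues'
formula). Each iteration drops the worst `trim_fraction` (default 0.10)
of correspondences for robustness to non-overlapping geometry; iteration
stops when the trimmed point-to-closest-point RMS changes by less than
`tolerance_mm` (default 1e-6 mm) or at `max_iterations` (default 100,
shared across both stages; non-convergence still returns the best
transform, flagged). The algorithm is deterministic — exact nearest
neighbours, no subsampling unless requested, and subsampling requires an
explicit seed. On planted rigid motions up to 8° / 8 mm the recovered
transform is accurate to ~1e-4 degrees and ~1e-3 mm.

Closest-point queries never fall back to vertex distances: candidate
triangles come from a k-d tree over triangle centroids plus all faces
incident to the nearest vertices, and the exact point-in-triangle /
edge / vertex Voronoi-region projection is evaluated vectorized over the
candidate set.

## Concordance statistics

Recognition rate = fraction of subjects graded moderate-or-severe, kept
as an exact rational. Consistency rate = `min(ra, rb)/max(ra, rb) × 100`
— a single expression covering both directions of the published ratio
(the smaller recognition rate is always the numerator). Rates are
computed on exact fractions and rounded half-up to one decimal only for
table output (22/23 → 95.7, 3/23 → 13.0); the overall table's average row
is the mean of the *rounded* per-region cells, the convention the source
tables demonstrably follow. Consistency of two zero rates is undefined
and reported as missing rather than 0 or 100. Agreement of repeated
gradings uses unweighted Cohen's kappa (via scikit-learn), with the
degenerate all-identical case fixed at 1.0. The "good consistency"
threshold is exposed as a constant, default 85 %.

Four printed cells of the source consistency tables do not follow from
the printed recognition counts (labial Z under the second criterion,
printed 76.2 where the counts give 66.7 — the printed value corresponds
to a wrong denominator — and chin X/Y/Z under the third criterion,
printed 90.1/95.7/90.1 where the counts give 90.9/95.5/90.9); likewise
the first-criterion chin count appears as both 18 and 20 in the source.
The toolkit always computes from counts; the acceptance tests treat these
cells as documented discrepancies rather than targets.

## Synthetic faces

The generator emulates the study condition — a clinic population in which
every subject shows measurable asymmetry — with an analytic, face-like
open shell: a blended half-ellipsoid (75 × 110 × 90 mm half-axes) with
symmetric midline features (nose ridge, chin boss, brow) added along the
ellipsoid normal. Bit-exact symmetry is guaranteed by construction: right
-half vertices are the x-negations of their left-half partners, and
bilateral landmark pairs are exact mirror images planted at analytic
surface positions. Regeneration with the same resolution and seed is
bit-identical.

Planted asymmetry is right-sided only (the left side is the AAI
denominator, keeping the planted truth analytic):

* `surface_bump` — a C¹ compact-support radial cosine bump (default
  radius 10 mm) displacing mesh vertices along the outward normal at the
  region's bump centre; height = magnitude, so the expected MFM
  approximates the planted height. Landmarks are untouched.
* `landmark_shift` — the region's designated right-side landmark
  (labial → Ch, mandibular angle → Go, cheek → He, chin → Mt,
  articular → Zg; five distinct landmarks, never the pose-defining
  tragion/exocanthion) moves by the magnitude along the named axis. The
  mesh is untouched.
* `combined` — both, with an optional separate bump height.

Because several landmarks appear in triplets of more than one region,
landmark shifts couple regions (e.g. a gonion shift perturbs labial Y and
the articular parameters). Cohort generation therefore calibrates each
region sequentially by bisection against the analytic angle response of
the current landmark state, targeting an AAI drawn from bands set well
inside the criterion intervals (mild 0.05–0.4 %, moderate 1.3–2.7 %,
severe 3.5–7 %); bump heights are drawn inside the corresponding
narrow-MFM bands (0.2–0.6 / 1.25–1.85 / 2.8–5 mm). Every synthetic
subject carries a deformation in all five regions, matching a referred
clinical population. One seeded generator drives all draws.

What passing tests on these fixtures show: the geometry, registration,
angle and grading arithmetic recover planted asymmetry of known magnitude
and location on clean surfaces. What they do not show: robustness to
scanner noise, holes, expression change, hair occlusion, or landmark
placement error on real faces — none of which the generator emulates.

## Numerical choices and problem sizes

* Angles in degrees throughout; criteria are unit-free ratios, so this is
  presentation-only.
* All grading bands half-open, boundary values falling upward
  (AAI = 1.0 % is moderate, MFM = 2.0 mm is severe under the 1/2 mm
  criterion).
* Grade matrices are always complete 5 × 3 grids; region aggregates are
  derived from axis cells by the all-mild/worst-axis rule, so matrix and
  rule cannot disagree.
* OBJ faces are fan-triangulated; indices converted from OBJ's 1-based to
  0-based at the boundary; round-trips preserve coordinates to ≤ 1e-6 mm
  and topology exactly.
* Default working resolution 40 (≈ 6.6 k vertices, 12.8 k faces) keeps a
  full mirror analysis under a second per subject; registration-heavy
  validation uses resolution 20 (≈ 1.7 k vertices). The 24-subject
  validation cohort at resolution 40 completes both pipelines in well
  under a minute.
* The deviation colormap PLY uses a symmetric diverging scale centred at
  zero with endpoints at ± max |signed distance| unless overridden.

## Known limitations

* The soft-tissue Frankfort surrogate tilts relative to the skeletal
  Frankfort plane by the tragion–exocanthion height difference; axis
  attributions of per-axis deviations inherit that tilt.
* Region boundaries are planar/radial surrogates of curved anatomy;
  absolute per-region vertex counts depend on them, though symmetric
  left/right treatment is exact by construction.
* One-way deviation sampling slightly understates asymmetry where the
  mirrored surface folds; the symmetric two-way option exists behind a
  flag (`compute_deviation` applied both ways) but is not the default.
* AAI with the left denominator is scale-dependent on the left angle;
  very small template angles inflate the index. The template's triplets
  avoid near-degenerate angles on realistic geometry.
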