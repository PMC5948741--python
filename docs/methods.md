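# Methods

## Problem setting

A single weed plant is photographed from a circular orbit and
reconstructed by SfM-MVS software into a dense point cloud (and,
optionally, a triangle mesh) in arbitrary scene units. The package
estimates two traits from that reconstruction — plant height and
one-sided leaf area (LA) — and validates them against ground truth.
Ground-truth LA for real plants comes from a 2D procedure: detached
leaves photographed on a white sheet with a 100 cm² black reference
square. Since no field data ship with the package, a synthetic module
generates plants with exactly known traits and emulates the
reconstruction's failure modes; all quantitative claims are
parameter-recovery results under those synthetic conditions.

## Synthetic plants

Both morphotypes are built so leaf area has a closed form, giving an
independent oracle for the mesh-based estimator.

**Dicot leaf.** A planar ovate sheet with half-width profile
`hw(u) = (W/2)·u^a(1−u)^b / max(u^a(1−u)^b)` along the normalised
midrib coordinate `u`, with `a = 1`, `b = 1.8` (widest ≈ 36% from the
base). One-sided area is `W·L·B(a+1, b+1)/max(·)` with `B` the Beta
function. The sheet is folded along the midrib by 15°; the fold is an
isometry of each half, so area is preserved, and rigid placement on the
stem preserves it again. Leaves attach at 30–72% of stem height with
elevations in [−8°, 30°], golden-angle azimuths, and lower leaves
larger — chosen so the stem tip remains the highest structure near the
plant axis, the property the cylindrical height convention relies on in
broad-leaved weeds.

**Monocot leaf.** A tapered strap, width
`w(t) = w₀(1 − (t/L)^1.5)`, swept along a circular arc in a vertical
plane with the rule direction a constant horizontal unit vector
perpendicular to that plane. With arclength parameterisation the
surface is developable and its area is exactly `∫w dt = w₀L·p/(p+1)`.
Base elevation 55–75°, tip elevation −70…−30° (rising then drooping);
aspect ratio L:w₀ ≥ 10 is enforced. The monocot stem is a tube of the
requested arclength whose tangent tilts linearly up to 12° at the tip;
stem curvature plus steep leaf insertions is what makes the cylindrical
height convention genuinely harder for grassy plants, and the pipeline
reproduces that difficulty rather than hiding it.

Stems are open tubes (radius 0.2–0.25 cm); leaves are open single
sheets, so the mesh triangle sum equals one-sided LA plus the stem
tube's lateral area, which the generator records per plant.
Tessellation defaults (96 rows per dicot leaf, 120 stations per strap,
24-gon tubes) keep the triangle sum within 0.1% of the closed forms.
All generators are bit-deterministic in (parameters, seed).

## Degradation model

`DegradationSpec` controls four defects, applied in a fixed seeded
order:

* **Sampling density** (default 40 pts/cm²) — area-weighted sampling
  over mesh faces.
* **Noise** (default σ = 0.1 cm) — isotropic Gaussian displacement per
  point; on meshes, a *smooth* random field (six sinusoidal modes,
  3–8 cm wavelengths, 0.05 cm RMS) is used instead, because independent
  per-vertex jitter at sub-triangle scale crumples the tessellation and
  inflates area by tens of percent, which is not how multi-view
  reconstruction error behaves.
* **Ghost points** (default 2%) — a seeded subset of samples displaced
  2–10 cm off-surface in random directions, mimicking MVS ghosting near
  surfaces rather than uniform box noise.
* **Tip dropout** — each leaf loses its distal `f_i` fraction of area,
  removed tip-inward along the leaf axis, with
  `f_i ~ f·(1 + jitter·U[−1,1])` (jitter 1 by default, so U[0, 2f]).
  The per-leaf variability is deliberate: end-detail loss in real
  reconstructions varies strongly between leaves, and it is this
  variability — not the mean loss — that degrades R², producing the
  expected dicot-over-monocot accuracy ordering when dropout is applied
  to monocots only. Setting jitter to 0 recovers a deterministic
  fraction.

Scenes embed the plant cloud in a 24 cm ground patch at z = 0 (uniform
random samples; points under the three 10 cm markers are coloured
dark), with the markers' exact endpoints recorded, optional neighbour
plants beyond an 8 cm exclusion radius sharing the same continuous
ground, and all coordinates divided by the true scale factor so the
scene arrives uncalibrated.

## Cloud processing

* **Statistical outlier removal**: drop points whose mean distance to
  their k = 12 nearest neighbours exceeds the global mean by more than
  2 standard deviations. This rule is not strictly idempotent on
  arbitrary data (removal shifts the global statistics); it is on
  homogeneous structures with isolated outliers, which is the regime it
  is used in.
* **Off-surface ("grid") filter**: remove points farther than 0.5 cm
  (closed interval — exactly 0.5 cm survives) from the reference
  surface. With no mesh available the reference is the
  total-least-squares plane of each point's k = 12 nearest neighbours,
  the point itself excluded so isolated points are measured against the
  surface, not themselves. Point-to-mesh distance, when a mesh is
  given, is exact (vectorised barycentric region classification).
* **Ground plane**: 300 random 3-point hypotheses scored by inlier
  count at 0.3 cm, best set refined by total least squares, normal
  oriented toward the off-plane majority (the plant).
* **Scale calibration**: per-marker ratio true length / observed
  endpoint separation; the estimate is the unweighted mean (all markers
  share one printed length, so weighting adds nothing) and the worst
  single-marker deviation is reported as a consistency check. On
  noiseless scenes recovery is exact to float precision for any scale.

The processing chain runs calibration first — both distance filters
have metric thresholds and refuse uncalibrated input — then statistical
removal, off-surface filtering, the user-supplied crop box (neighbour
removal is manual by design: colour cannot separate adjacent plants of
the same species connected through the ground), ground fitting and
trait extraction.

## Trait estimators

**Height.** The stem axis is located as the densest vertical column:
points more than 0.5 cm above the fitted ground vote in a 1 cm
ground-plan grid (the above-ground restriction stops the uniformly
dense ground patch from outvoting the stem), the winning cell's mean
position is the axis, and height is the maximum signed ground distance
among points within `stem_radius_cm` (default 1.0 cm — configurable;
the field convention does not fix a radius) of that axis. By default
the plant is assumed to stand on the fitted ground plane, so the base
level is the plane itself; the extreme-point alternative
(`base_mode="lowest"`) is available for cropped or floating clouds but
is biased low under noise — the minimum of many near-ground points sits
~2.5σ below the plane, which would inflate every height by a constant
~0.4 cm. A `max_extent` method (maximum ground distance over all
points) is reported alongside as the fallback for strongly tilted
stems, which the vertical cylinder truncates. Degenerate clouds (one
point, or no vertical extent) yield height 0.

**Leaf area.** The triangle sum of the supplied mesh, each face counted
once (one-sided); a `two_sided_input` flag halves the sum for closed
thin-solid meshes, and generator metadata lets experiments subtract the
stem tube's area so LA compares to leaf truth.

## Image-based leaf area

The index image `cR·R + cG·G + cB·B` is kept real-valued — no 8-bit
clipping, which would destroy bimodality for negative-coefficient
indices. Otsu's threshold is computed on an equal-width histogram over
[min, max] (256 bins), returning the interior bin edge maximising
between-class variance with ties broken toward the smallest edge; edges
separated only by empty bins are mathematically tied and are resolved
to the smallest edge explicitly, so float summation order cannot flip
the choice. Foreground is the above-threshold class (vegetation is
bright in these indices; the rendered layouts follow the same
convention, so the binary masks show leaves as foreground). The
reference square is detected in the *raw* image — it is not green — as
the largest 4-connected component of pixels with max channel ≤ 40 whose
bounding-box fill ratio is ≥ 0.9 (thin scale bars fail the fill test);
its pixels are withheld from the Otsu histogram because the square is a
calibration object, not scene content. A layout with no vegetation then
leaves the withheld index constant, which reads as 0 cm². Rendered
layouts rasterise flattened leaf outlines (exact flattening — both leaf
surfaces are developable) with a pixel-centre inclusion rule, which is
unbiased, so recovered areas track truth to a few tenths of a percent
at 20 px/cm.

## Validation statistics

Estimates are regressed on actuals (actual on the x axis) by OLS;
Pearson r, R² = r², RMSE (trait units), signed MPE and absolute MAPE
are reported together. MPE and MAPE are labelled distinctly because
systematic signed deviations (tip loss under-estimates LA) are
scientifically meaningful and an "absolute" error cannot be negative.
Regression p-values are descriptive, flagged at p < 0.01, with no
multiple-testing correction across traits or species.

## Problem sizes and defaults

The canned experiments use 30 plants (height recovery, full cloud
pipeline at 40 pts/cm², σ = 0.1 cm, 2% ghosts, heights uniform on
4–30 cm), 10 + 10 plants (LA recovery with 5% mean tip dropout on
monocots only), and 20 plants (2D LA at 20 px/cm); the pipeline default
of 10 plants per species class across three classes (two broad-leaved
centred near 12 cm and 7 cm, one grass-like up to 30 cm) mirrors the
typical field sampling design for this kind of validation. A full
acceptance run completes in under a minute on one core.

## Known limitations

* Synthetic morphotypes are architectural stand-ins, not species
  replicas; no published geometry exists for the target species, so
  passing recovery tests demonstrates correctness of the estimators
  under the stated degradation model, not field accuracy.
* The degradation model omits several real-world effects: illumination
  and colour variation, leaf overlap merging surfaces into solid
  blobs, ground roughness (the synthetic ground patch is exactly
  planar), and spatially correlated point noise.
* Neighbour-plant removal is a manual crop box, as in practice; no
  automatic 3D plant/soil or plant/plant segmentation is attempted.
* Stem diameter, leaf inclination, leaf counting and biomass models are
  out of scope.
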