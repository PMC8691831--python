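# Methods

## The geometric model

cleavekit analyses how mitotic-spindle pose and cell-shape anisotropy
position the cleavage plane in early embryonic blastomeres. Cells are
represented in two complementary ways:

* a **2D contour** — a closed simple polygon in micrometres, as traced on
  a single confocal section, stored counter-clockwise with an attached
  animal-vegetal (AV) frame (unit AV direction pointing vegetal → animal,
  plus a `sign_reference` unit vector defining which lateral side counts
  as positive tilt: toward the posterior pole in sagittal views, away
  from the midline in transversal views);
* a **3D triangle mesh** — a closed, consistently outward-oriented
  surface standing in for a reconstructed cell.

The spindle is two pole points plus the chromosomal-plate (midzone)
point on the pole-pole segment; the plate defaults to the segment
midpoint when not measured.

Three per-cell metrics are defined on a contour and pose:

* **Spindle angle** θ ∈ (−90°, 90°]: the minimal angle between the
  (apolar) pole-pole line and the AV direction, signed positive when the
  vegetal pole deviates toward `sign_reference`. Computed with atan2 so
  precision does not degrade near 0°.
* **Centering ratio** c = d_a/(d_a + d_v), where d_a and d_v are the
  distances along the spindle line from the plate to the nearest boundary
  intersection on the animal and vegetal sides. 0.5 means a centred
  spindle; above 0.5 the spindle is off-centred toward the vegetal pole.
  An equivalent convention in circulation divides d_a by d_v directly
  (making "centred" = 1); the ratio-of-sums form is used here because
  under it 0.5 denotes a centred spindle — the form such measurements
  are conventionally plotted in — and the raw distances are exposed so
  the plain quotient is recoverable.
* **Division prediction**: the cleavage line passes through the plate,
  perpendicular to the spindle; the relative animal area
  A_a/(A_a + A_v) is 0.5 for an equal division and below 0.5 when the
  vegetal daughter is predicted larger.

In 3D, sphericity is Ψ = π^(1/3)(6V)^(2/3)/A (1 for a sphere), the
standard definition used by commercial reconstruction software; the
relative animal daughter volume is V_a/(V_a + V_v).

## Virtual experiments

**Virtual repositioning** separates the effect of tilt from the effect of
off-centring. The spindle is first aligned with the AV axis and centred
along it: the plate is placed at the midpoint of the AV-parallel chord
through the area centroid (*not* at the centroid itself). A tilt is then
applied while the spindle stays centred along its own axis, found by
fixed-point iteration: rotate about the current plate, recompute the
boundary chord of the tilted line, move the plate to the chord midpoint,
repeat until the plate moves < 1e-9 µm (cap 100 iterations; convex
shapes converge in a handful). The chord-midpoint reading of "centred"
is the only one under which a circle divides equally at every tilt and
both reference shapes divide equally at zero tilt, which is the
behaviour the procedure is meant to isolate.

**Chord-pivot sweep**: the top (animal) pole is pinned to the boundary
where the AV line through the centroid exits the cell; for each tilt
angle the vegetal pole is the next boundary intersection along the
rotated ray, the plate the chord midpoint, the cut perpendicular to the
chord. On the circle the perpendicular bisector of any chord passes
through the centre, so the relative top area is 0.5 at every angle. On
the half-disc (flat edge parallel to the zero-tilt axis) the same
argument applied to the full disc gives a closed form while both chord
ends lie on the arc: relative_top = 1/2 − α/180 (α in degrees) — a
useful independent oracle. Angles whose ray grazes a vertex are
perturbed by 1e-7° before evaluation; rays that fail to re-enter the
shape are reported as NaN.

The half-disc is oriented with its flat edge *parallel* to the zero-tilt
spindle, i.e. the flat edge models a lateral cell-cell contact. This is
required for the shape to be mirror-symmetric about the zero-tilt
cleavage direction and hence divide equally at zero tilt. The lateral
sign of tilt is not dictated by the geometry; numerically (and by the
closed form above) the vegetal side becomes the larger daughter when the
vegetal pole tilts *away* from the flat contact, which matches the
reported anterior-blastomere behaviour (vegetal pole displaced away from
the midline contact, vegetal daughter larger). Sweeps over both signs
are supported; the generator uses the vegetal-larger orientation.

## Numerical choices

* Polygon splitting and line-boundary intersection use shapely
  (half-plane clipping); areas, centroids, perimeter, circularity
  (4πA/P²) are direct shoelace computations. Non-convex contours may
  yield several pieces per side; per-side areas are sums over pieces and
  conserve the parent area to 1e-9 relative.
* Coincidence/dedup tolerance 1e-9 µm; degenerate-area threshold
  1e-12 µm². A line tangent at a single vertex is a no-split error.
* Half-body volumes after a plane cut are computed by slicing the
  surface open at the plane and evaluating the divergence-theorem sum
  with the reference point **on the cutting plane**: every face of the
  planar cap would be coplanar with the reference point and contribute
  zero signed volume, so the volumes are exact without triangulating a
  cap. The two halves sum to the mesh volume within 1e-6 relative.
* Parametric shapes default to 720 vertices; the inscribed-polygon area
  deficit is O(n⁻²) (≈ 6.3e-6 relative at n = 720, far below the 1e-3
  tolerances used in shape-level checks).
* Statistics go through scipy.stats behind the module surface: exact
  Wilcoxon signed-rank for n ≤ 25 tie-free effective differences (zeros
  dropped first, standard practice), exact Mann-Whitney for tie-free
  groups of ≤ 10 each, continuity-corrected normal approximations
  otherwise. Quartiles use linear interpolation. An all-zero-differences
  sample reports p = 1 with a degenerate flag and a warning rather than
  an exception, so batch reports do not abort.

## The synthetic generator

`synthetic_data.generate_population` emulates the measured blastomere
populations so the whole pipeline is testable without imaging data. Per
cell it samples a shape (superellipse half-width ~N(25, 2.5) µm, AV
elongation ~N(1.6, 0.15), contact flattening ~N(0.35, 0.08), truncated
to valid ranges), builds the contour, then per stage samples a true tilt
and centering, constructs the exact pose realising them (tilt via the
centred-tilt procedure, centering by moving the plate along the tilted
chord), and finally jitters poles and plate with isotropic Gaussian
noise (default sd 0.5 µm; the plate is re-projected onto the jittered
pole axis so pose invariants hold). Measured values in
`ground_truth_table` are recomputed from the jittered poses through the
spindle metrics — recovery tests exercise the measurement pipeline, not
the sampler.

Stage means follow the reported values: B3 (sagittal) tilt 9.6° at
metaphase, 21.3° at anaphase onset; A3 (transversal) 0° and 5.67°;
metaphase centering 0.5. Quantities the source data do not print are
package defaults, chosen once: tilt sds 4° (metaphase) and 6°
(anaphase), a realistic between-embryo spread for such angle
measurements;
anaphase centering 0.52 for B3 (vegetal-ward) and 0.48 for A3
(animal-ward), sd 0.03-0.04. The anaphase off-centring magnitude is
constrained by the reported structure itself: on the default shapes a
21.3° tilt shifts the division prediction by ≈ −0.04 while a centering
shift of +d shifts it by ≈ +d, so the off-centring must stay below
~0.04 for the anaphase prediction to remain below 0.5 (vegetal daughter
larger) even though the spindle is off-centred toward the vegetal pole —
the hallmark of the posterior lineage. The "isolated" lineage keeps the
B3 tilt/centering program but draws nearly round shapes (elongation
~1.05, flattening ~0.02), reproducing the observation that the same
spindle behaviour fails to generate unequal division once shape
anisotropy is removed.

Randomness is a single seed; each cell uses a counter-keyed substream
(`SeedSequence(seed, spawn_key=(i,))`), so enlarging a population never
reshuffles earlier cells, and identical configs regenerate bit-identical
datasets.

What the generator does **not** emulate: real cortical mechanics (tilt
angles are sampled, not produced by forces), segmentation error
structure (noise is isotropic Gaussian on landmarks), curvature detail
of real contours (superellipse family), or 3D shape (the population is
2D; meshes are built separately). Passing recovery tests therefore shows
the measurement pipeline is unbiased and correctly calibrated on shapes
of this class — not that real segmentation noise is harmless.

## Problem sizes in the test suite

The bundled checks run at sizes chosen to keep the full suite quick
while leaving Monte-Carlo error well below the effects measured:
720-vertex parametric shapes for closed-form comparisons, 10⁶-sample
Monte-Carlo splits for the half-disc sweep (3σ ≈ 1.5e-3), 100 random
polygons plus 5 random ellipsoid/voxel-oracle cuts for the splitting
primitives, populations of 50-200 cells for recovery, and 2000
replicates of n = 25 for the Wilcoxon size check (3σ Monte-Carlo band
±1.5%, plus a small allowance for exact-test discreteness).

## Known limitations

* 2D metrics assume the section contains the true spindle axis;
  out-of-plane tilt is invisible, as in any single-section measurement.
* The centred-tilt fixed point is not guaranteed unique on strongly
  non-convex contours (the iteration converges to the fixed point
  reachable from the aligned start; the cap raises a convergence error
  otherwise).
* Mesh bisection requires watertight, consistently wound input; no
  repair is attempted.
* No multiple-testing correction is applied in `report` (matching the
  reporting practice the module reproduces).
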