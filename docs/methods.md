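# Methods

## The measurement problem

A semicircular canal is a thin curved tube; its functionally meaningful
descriptors are one-dimensional profiles along the tube (cross-sectional
area, bony–membranous separation, endolymph/bony area ratio) and a single
best-fit plane per canal whose normal approximates the axis of maximal
rotational sensitivity. The package turns a segmented label volume
(0 background, 1 perilymph, 2 endolymph; bony = 1 ∪ 2) into those
descriptors. All coordinates are world millimeters with
`world = origin + index · voxel_size`, axes (x, y, z), right-handed.

## Phantom model

Real segmentations of this kind are not publicly available, so validation
rests on voxel phantoms with closed-form ground truth.

Each canal is a pair of nested tubes around circular arcs. The bony
centerline is an arc of radius R spanning θ ∈ [0, Θ]; the membranous
centerline is the concentric arc of radius R + δ (δ = centrifugal duct
offset, i.e. away from the arc center), optionally rotated out of the canal
plane by a tilt τ about the radial direction through the 0 % end. Tube
cross-sections perpendicular to the tangent are circles with percent-
dependent radius r(p) (base value plus Gaussian bulges), so

- arc length = R·Θ (membranous: (R+δ)·Θ),
- area(p) = π r(p)²,
- plane normals and inter-canal angles are construction inputs.

Default dimensions (mm, degrees) encode the cohort means of the study this
models: bony lengths 16.716 / 15.047 / 12.571 (posterior / superior /
lateral), crus 2.683; bony pairwise plane angles 90.374 / 87.158 / 91.801,
realized exactly by taking the three normals from the Cholesky factor of the
Gram matrix of pairwise cosines; slender radii r_b = 0.57, r_m = 0.18
(so the slender endolymph area is ≈0.10 mm² and the area ratio
(0.18/0.57)² ≈ 10 %); duct offsets 0.25 / 0.20 / 0.25; membranous plane
tilts 3.37 / 4.23 / 2.36; ampullary bulge at 95 % (duct peak 0.35, bony
peak 0.85); lateral bony end-widening (the "parabolic" perilymph course);
optional lateral duct widening over 0–20 % with peak radius 0.33 at 5 %
(area ≥ 3× the slender value). The common crus is a straight tube
(r_b = √2·0.57, so its area is about twice a canal's) along the
intersection line of the posterior and superior planes: points on it are
coplanar with both canals, so appending it to either plane fit is unbiased.
The membranous centerline length follows from the geometry
((R+δ)Θ ≈ 18 mm posterior) rather than being matched independently; with a
shared arc span, bony and membranous lengths cannot both be pinned, and the
bony values are the validated ones.

Cohort jitter (one seed drives everything) perturbs lengths, plane
orientations, tilts and crus length with the corresponding cohort SDs, and
assigns the lateral widening to ~29 % of specimens. Circular nested tubes
cannot host every drawn (offset, tilt) pair — real ducts evade this by
being non-circular and wall-hugging — so infeasible draws shrink the offset
first, then the tilt, until the duct nests (deterministic, documented in
the generator).

Rasterization decides membership at voxel centers (no anti-aliasing; the
consumers are label images). Tubes extend `end_margin_mm` (default 1.2)
beyond both measurement ends with flat caps, so skeletons can be cut back
at the exact ground-truth end planes — the phantom analogue of cutting all
centerlines at a shared anatomical locus. The voxel grid origin is offset
by fixed sub-voxel fractions per axis so that object symmetry planes never
coincide with inter-voxel planes, where thinning of exactly symmetric
tubes is degenerate. Total voxel volume converges to the analytic tube
volume (within 3 % for voxels ≤ r/5, monotone under refinement).

What the phantom does *not* emulate: non-circular (reniform) real
cross-sections, grayscale/noise/beam-hardening, preparation damage
(detached or collapsed ducts — damage enters only as quality scores), and
the vestibule/cochlea. Passing tests therefore demonstrate correctness of
the measurement chain on ideal tubes at known geometry, not robustness to
segmentation error.

## Centerlines

1. **Thinning** (`_thinning.py`): sequential deletion of simple points
   (Bertrand's T26 = T6 = 1 criterion, 26-connectivity foreground / 6
   background) in increasing Euclidean-distance-transform order, keeping
   curve endpoints. Sequential deletion guarantees topology preservation
   and a non-empty result; distance ordering centers the skeleton. This is
   implemented in-package (numba) because the available parallel
   directional thinner deletes entire tubes whose cross-section is
   exactly symmetric about inter-voxel planes.
2. **Tracing/pruning**: skeleton voxels become graph nodes with 26-neighbor
   edges weighted by Euclidean length. Leaf branches shorter than 10 % of
   the current diameter path are deleted iteratively; the polyline is the
   weighted diameter path (double-sweep Dijkstra). Loops are resolved by
   the shortest-path weighting taking one side; parasitic diagonal cycles
   are shortcut the same way. This replaces interactive filament editing
   with a deterministic rule.
3. **Cutting**: each cut locus is a plane (point + normal). The cut is
   anchored at the polyline point nearest the plane's reference point; the
   exact crossing is searched within 1.5 mm of arc length around the anchor
   and interpolated onto the plane. If the line only grazes the plane
   (tangential approach — this happens where the crus runs parallel to a
   canal's end plane), the in-window point nearest the plane is projected
   onto it, provided it is within 0.3 mm; otherwise the plane misses the
   line and the error names it.
4. **Smoothing**: per iteration each interior point moves toward the
   midpoint of its neighbors by `smoothing` (0.8), then back toward its
   original position by `adherence` (0.05); 100 iterations; endpoints
   fixed. Collinear chains are exact fixed points; the scheme's equilibrium
   radial shrinkage on a 101-point arc of these radii is ≈0.005 mm
   (≈0.15 % of length). The parameter names and defaults mirror the
   conventional lineset-smoothing settings; the two-step update rule is
   this package's normative definition of them.
5. **Parameterization**: orientation is canonical (100 % = ampullary end,
   chosen by proximity to a supplied ampulla point or end selector),
   cumulative length is the sum of Euclidean segment norms, and the line is
   resampled to 101 points uniform in arc length (1 % steps; resampling
   changes total length by <0.5 %).

Pipeline length error on phantoms with tube radius ≥ 6 voxels is well
inside 2 % (measured ≤0.5 % at 60 µm); the pipeline extracts each
structure's centerline from its own tube — the medial axis of the fused
canal+crus union detours through the junction blob and would bias lengths
by up to +4 %.

## Cross-sections

Frames sit at every percent point of the *bony* centerline (membranous
sections share these frames so ratios are position-matched). Tangents are
central differences; the in-plane basis is propagated by parallel transport
(no frame flips; areas are basis-invariant). The transport is seeded with a
fixed 27.59° in-plane rotation: a canonical start basis is often exactly
grid-aligned, and with pixel size = voxel size the sampling lattice then
resonates with the voxel lattice, aliasing areas by several percent.
Pixels are nearest-neighbor label lookups over a 2 mm ROI (pixel size
defaults to the voxel size); frames whose ROI leaves the volume near
foreground are flagged `edge_of_volume`.

Adjacent-structure rejection works on the 8-connected components of the
target compartment: the component containing the image center (searched
outward ≤5 px) is the lumen; any other component ≥20 % of the lumen's area
invalidates the frame (`adjacent_region`), smaller specks are erased. Two
additional guards handle junctions, where the adjacent lumen *merges* with
the canal lumen into one component that the component rule cannot see: a
lumen touching the ROI border, or extending farther than 0.45·ROI from the
pierce point, is likewise invalid. On phantoms this flags the frames within
~6 % of the crus junction and the widest ampullary frames — the analogue of
the reduced-sample hatched regions in per-position plots. The single frame
adjacent to a rejected junction run can retain a few percent of residual
contamination; accuracy assertions therefore target the 10–88 % span.
Area = pixel count × pixel size² exactly; on phantoms, valid slender-span
areas match π r(p)² within 5 % (bony radius ≥ 6 px).

The bony–membranous distance at each bony frame is the Euclidean distance
from the frame origin to the nearest intersection of the membranous
polyline with the frame plane, falling back (flagged) to the nearest
membranous point when no intersection lies within the ROI.

## Plane fits and angles

Weights are w = 1/A² from each point's cross-sectional area (the common
crus contributes its own area-derived weights; points with invalid areas
are dropped, not imputed). The weighted total-least-squares plane comes
from the SVD of the √w-scaled centered point matrix; the weighted RMS
point–plane distance is reported. Normals are oriented by the right-hand
rule around the canal's 0 % → 100 % traversal, so inter-canal angles are
meaningful beyond 90°. Uniform weights reduce the fit exactly to the
unweighted TLS plane; fits agree with a 0.1°-resolution spherical grid
search within 0.2°; rigid motions rotate fitted normals equivariantly.
On the default phantom at 60 µm, pairwise bony angles are recovered within
0.2° and the constructed membranous plane tilts within 0.25°.

## Alignment

Signed distance maps (Euclidean, negative inside, mm) of the merged bony
label drive rigid registration: mean-squared difference between the fixed
map and the resampled moving map, Euler angles + translation, coarse-to-
fine pyramid (shrink 4/2/1), gradient-descent steps, optional seeded random
restarts for large misalignments. On signed distance maps this objective is
smooth and well-conditioned near the optimum, serving the same role as an
information-theoretic metric on raw labels. Alignment quality is scored on
maps clamped to ±0.6 mm (≈ canal radius) so far-field distances cannot
dominate. Known rigid motions of a phantom are recovered within 0.5° and
0.5 voxel; failure to improve on the initialization returns a flagged
non-convergence result carrying the best transform found. Anatomical
(Reid's-frame) orientation is restored by composing the registration with
an externally supplied 4×4 matrix — without it, absolute plane orientations
are frame-dependent and the package refuses to pretend otherwise. Left
ears are mirrored (grid flip about the volume center; determinant −1)
before registration; mirroring preserves all magnitudes and flips
chirality.

## Cohort statistics

Sections (three canals, three ampullae, crus) carry 0–3 damage scores;
multi-rater disagreement resolves to the maximum (most conservative) by
default and is flagged. Inclusion: bony ≤ 2, membranous = 0. Envelopes
report mean, sample SD (n−1; masked for n < 2), min/max and quartiles
(linear interpolation between closest ranks) per percent point over the
specimens with a valid frame there; points where fewer than 66 % of
included specimens contribute are flagged `reduced_n`. Average centerlines
are pointwise means over the percent grid and assume co-registered inputs.

## Problem sizes and numerical choices

The package's own runs use a reduced-resolution tier — 60 µm voxels, tube
radii ≥ 9 voxels, cohorts of 3 (tests) to 10 (acceptance script) — chosen
so the whole validation chain stays cheap on a single core; 15 µm is the
full-fidelity setting and scales cost by (60/15)³ = 64× per specimen. All
stated tolerances were verified at the tier actually run. Determinism:
identical seeds give bit-identical volumes and byte-identical CSV outputs;
all randomness (jitter, damage scores, optimizer restarts) derives from the
single config seed.

Degenerate inputs are rejected with diagnostics rather than repaired:
multi-component or empty compartments (thinning), non-nested duct
geometries (rasterization), collinear point sets (plane fits), empty
foreground (distance maps), missing anatomical matrix (reorientation).

## Known limitations

- Circular cross-sections make areas analytic but understate the real
  sections' eccentricity; the electrode-clearance interpretation of area
  profiles is optimistic for non-circular lumina.
- The duct offset + tilt parameterization cannot reproduce the full
  observed distance range (0.3–0.7 mm in the posterior canal) while
  keeping circular tubes nested; defaults reproduce the range
  qualitatively at its lower end.
- The spur/loop pruning rule and the adjacency guards are declared
  definitions, not inferences from any particular interactive workflow.
- Quality scores are synthetic bookkeeping: phantoms are never actually
  damaged, so the inclusion machinery is exercised, not stress-tested.
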