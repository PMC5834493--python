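# canalmorph

Morphometry of the human semicircular canals — bony and membranous — from
segmented 3D label volumes.

The three semicircular canals (posterior, superior, lateral) of the
vestibular labyrinth sense angular head acceleration. Each bony canal
contains a slender membranous duct (the endolymphatic compartment) suspended
in perilymph; the duct's geometry, not the bone's, sets the functional
response plane and the space available to a prospective vestibular-implant
electrode. Given micro-CT-style segmentations with integer codes for the
endolymphatic and perilymphatic spaces, this package computes, per specimen:

- **centerlines** per canal and compartment: topology-preserving
  distance-ordered 3D thinning, graph tracing with automatic spur/loop
  pruning, cutting at shared end loci, constrained Laplacian smoothing
  (smoothing 0.8, adherence 0.05, 100 iterations), and resampling onto a
  common 0–100 % arc-length grid (100 % = ampullary end);
- **cross-section profiles**: 2 mm regions of interest resampled
  perpendicular to the bony centerline at every percent point,
  with automatic rejection of frames showing adjacent structures
  (e.g. at the common crus), giving per-position endolymph, perilymph and
  bony areas (*area = pixel count × pixel size²*), bony–membranous
  perpendicular distances, and endolymph/bony area ratios;
- **canal planes**: the weighted total-least-squares plane through each
  canal's centerline points (common crus appended to posterior and
  superior), each point weighted by the inverse square of its
  cross-sectional area, solved by SVD: the normal **n** minimizes
  `Σᵢ wᵢ (nᵀ(pᵢ − c̄w))²` with `wᵢ = 1/Aᵢ²`; pairwise inter-canal angles
  and per-canal bony-vs-membranous plane disparities follow from the
  oriented normals;
- **cohort statistics**: four-point damage scoring with inclusion
  thresholds (≤2 bony / 0 membranous), per-position envelopes
  (mean, SD, min–max, quartiles, contributing n), average centerlines and
  summary tables.

Because no segmentations of this kind are publicly deposited, the package
includes a first-class phantom generator: nested circular-arc tube pairs
(duct offset toward the centrifugal wall, optionally tilted out of the canal
plane), a straight common crus along the posterior–superior plane
intersection, ampullary bulges and an optional lateral-duct widening — all
with closed-form centerlines, lengths, area profiles, plane normals and
angles, so every pipeline stage is validated against analytic ground truth.
Alignment tooling (signed-distance-map rigid registration via a
coarse-to-fine pyramid, mirroring left ears to right, anatomical
reorientation by a supplied 4×4 matrix) is included for cohorts scanned in
arbitrary orientations.

## Worked example

```python
from canalmorph import default_labyrinth_spec, rasterize
from canalmorph.pipeline import RunConfig, run_specimen

spec = default_labyrinth_spec(seed=0)      # exact cohort-mean geometry
cfg = RunConfig(n_specimens=1, voxel_size_mm=0.06)
res = run_specimen(cfg, spec)
print(res.lengths[("posterior", "bony")])
print(res.angles[res.angles.compartment == "bony"])
```

prints a posterior bony centerline of `16.674` mm (the generator's analytic
value is 16.716 mm — the voxel pipeline recovers it within 0.3 %) and the
fitted bony plane angles

```
  compartment                pair  angle_deg
0        bony  posterior-superior     90.350
1        bony   posterior-lateral     87.323
2        bony    superior-lateral     91.919
```

against constructed values of 90.374 / 87.158 / 91.801°: the bony labyrinth
is nearly a Cartesian triad, and the recovered bony-vs-membranous plane
disparities (4.44° superior, 3.48° posterior, 2.25° lateral at this voxel
size) show the duct planes are measurably tilted relative to the bone.

The numbered drivers run the same machinery as a small study:

```sh
python analysis/01_generate_phantoms.py     # phantoms + ground truth
python analysis/02_run_cohort.py --n 10     # full pipeline, cohort tables
python analysis/03_summarize.py             # envelope figures
```

`02_run_cohort.py` draws a jittered cohort (lengths, plane orientations and
duct tilts vary around the cohort means; ~29 % of specimens carry the
lateral-duct widening), scores and filters damaged sections, and writes
length/angle summary tables plus per-position envelope CSVs under
`results/cohort/`. The figures from `03_summarize.py` show the slender-duct
endolymph/bony area ratio holding near 10 % along the canals (about 20 % in
the common crus), rising at the ampulla, with hatched spans where
junction-adjacent frames reduced the sample.

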