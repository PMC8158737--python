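# Methods

This note records the measurement model, the conventions and defaults, the
synthetic phantom's construction, and the numerical choices behind
`spinegrader`. It documents what the code computes; every empirical number
quoted here is produced by the test suite or `scripts/acceptance.py`.

## Coordinate and raster conventions

All geometry runs in physical millimetres. A pixel at `(row, col)` has its
centre at `(row * spacing_row, col * spacing_col)`; the origin is the
centre of pixel (0, 0). Orientations are fixed by the file format rather
than inferred: axial slices have anterior toward decreasing row and
patient-left toward increasing column (radiological display); sagittal
slices have superior toward decreasing row and anterior toward decreasing
column. The conversion from pixels to millimetres happens in exactly one
place (I/O boundary); everything downstream is unit-safe.

Label maps are stored as 16-bit PNG (one per slice) or NIfTI volumes, with
a single JSON sidecar carrying the label dictionary, plane, spacing and
segment assignments. The sidecar is written with sorted keys, so identical
studies serialize to byte-identical metadata.

## Disc excess measurement

The two vertebral bodies adjacent to a disc are projected onto the disc
slice by nearest-neighbour lookup in millimetre space; the footprint is
the **union** of the two body masks. Union is the conservative choice (it
yields the smallest excess) where either union or intersection could be
read into "the projected contour of the neighbouring vertebral bodies".

Excess regions are the 8-connected components of `disc AND NOT footprint`
whose centroid lies posterior to the disc centroid; anterior excess is
ignored because every finding of interest concerns the spinal-canal side.
Per region:

* **max excess** — the maximum over the region's pixels of the Euclidean
  distance to the footprint (exact distance transform, anisotropic spacing
  respected). This is the perpendicular-to-contour reading of the
  "anterior–posterior distance"; a pure row-axis variant is available via
  `ap_axis_only` / `--ap-axis`.
* **angular span fraction** — the fraction of the full circle the region
  subtends about the disc centroid (largest angular gap complement).
* **base width** — the arc length of the footprint contour adjacent to the
  region. The arc is measured along the *sub-pixel* (marching-squares)
  contour, not along a chain of boundary pixels: the pixel-chain staircase
  inflates arc lengths by up to ~40 %, which is enough to flip the
  protrusion/extrusion call.
* **dome width** — the widest chord, parallel to the local footprint
  tangent, of the **outer half** of the region (pixels farther than half
  the maximal excess). Measuring the chord over the whole region would
  make dome ≈ base for any tapering bump (the widest chord sits at the
  base), so the dome-versus-base comparison would be decided by
  rasterization noise; the outer-half chord captures the width of the
  displaced material away from its neck, which is what the extrusion
  definition ("edges of the herniating material wider than the base")
  intends.

Per segment, excess regions are pooled across that segment's disc-level
slices and the maxima are used; the dural-sac area uses the per-segment
minimum over slices that contain sac pixels. One finding per segment is
reported.

## Decision thresholds

| Parameter | Default | Origin |
| --- | --- | --- |
| `excess_min_mm` | 3.0 mm | standard reporting default |
| `bulging_circumference_fraction` | 0.25 | disc-nomenclature consensus |
| `stenosis_relative_mm2` | 100 mm² | published threshold |
| `stenosis_absolute_mm2` | 75 mm² | published threshold |
| `root_deviation_min_mm` | 2.0 mm | **this package's default** — "deviated" has no published magnitude |
| `listhesis_report_min_percent` | 4.0 % | **this package's default** — reporting floor against rasterization-noise slips |

Boundary conventions: a sac area of exactly 75 mm² is *relative* stenosis
("less than 75" is strict), exactly 100 mm² is still relative. Meyerding
grades are the quartiles of the slip percentage (≤ 25 → I, ≤ 50 → II,
≤ 75 → III, > 75 → IV), with slips under the reporting floor as grade 0.
A disc can be simultaneously herniated and bulging when distinct regions
satisfy the two rules. Nerve-root contact is tested against herniated disc
regions only (the open-ended "other tissues" of clinical practice is
deliberately narrowed); deviation is taken as the maximum over the
segment's slices.

## Spondylolisthesis construction

Posterior tangents are total-least-squares lines through the posterior
20 % (by anterior–posterior extent) of each body's boundary points; the
endplate line uses the superior 15 % of the lower body. Both bands are
selected in the body's own principal-axis frame, and the 30 % of each band
nearest the corners is excluded from the line fit (corner points have high
leverage and tilt the fitted tangent; with trimming the construction is
invariant under joint rigid rotation to within 0.1 percentage points at
15°). The endplate length is the extent of the full superior band
projected on the endplate line. The slip percentage is the distance
between the two tangent–endplate intersections divided by the endplate
length.

## Segment labeling

Vertebral bodies on the sagittal midline slice are the 8-connected
components of the vertebral-body class, ordered by centroid height and
named upward from the sacrum: L5, L4, … TH12 (further bodies continue up
the thoracic spine). Interspaces between adjacent named bodies give the
segments TH12/L1 … L5/S1. Fewer than six bodies produce a partial labeling
with a warning; extra bodies do not add segments.

## The phantom

The phantom renders exactly the cross-sections the rules consume, as
analytically parameterized shapes, so the measurement error of the whole
pipeline can be bounded against known ground truth:

* **Axial stacks** (per segment, three slices: upper body / disc / lower
  body, 128 × 128 px at 0.5 mm/px): disc and vertebral footprint are one
  ellipse (semi-axes 24 × 17 mm); the dural sac is a 2:1 ellipse scaled to
  the target area, 11 mm behind the disc; nerve roots are 1.5 mm-radius
  dots lateral to the sac.
* **Pathology rendering**: protrusions are raised-cosine radial bumps of
  given depth and angular width on the posterior disc boundary (dome
  narrower than base by construction); extrusions are a stalk of given
  base width capped by a wider elliptical dome (`dome_base_ratio` > 1);
  bulges are wide raised-cosine bumps (> 90° so that the rendered span
  stays above the 25 % circumference rule after the sub-half-pixel tail of
  the profile is lost to rasterization). When a herniation and a bulge
  share a disc they are placed at separated angles (35° and 138°) so they
  remain distinct regions and the ground truth stays exact. A compressed
  root is placed at the herniation apex with its expected course displaced
  by `root_offset_mm`.
* **Sagittal slice** (0.5 mm/px): sacrum and six (or more) rectangular
  bodies, 24 mm tall, 32 mm endplate, 8 mm disc gaps. Spondylolisthesis is
  an anterior offset of the slipping body *and everything above it* by
  `listhesis_percent` of the endplate length — the cumulative shift keeps
  each interspace's relative offset equal to its own slip, so listhesis
  does not leak into adjacent segments.

Determinism: a fixed spec renders bit-identical studies; cohort sampling
draws everything from one seed. Truth-recovery tolerances at 0.5 mm/px,
verified by the tests: herniation depth ± 0.5 mm, sac area ± 2 %, slip
percentage ± 2 points, root deviation ± 1.5 mm.

Cohort sampling uses the prevalences of a routine low-back-pain population
(herniation 8.7 % of segments, 60 % of them extrusions, bulging 15.0 %,
stenosis 3.9 %, root compression 5.7 %, listhesis 2.3 %, all grade I) and
samples pathology magnitudes with ≥ 1 mm / ≥ 5 mm² / ≥ 3-point margins
from the decision thresholds, so that noiseless rendering must be
recovered exactly — the round trip is a correctness gate, not a
statistical claim. Nerve-root compression is sampled only on herniated
segments, since the rule requires herniated tissue contact. A degraded
prediction table (per-pathology false-negative / false-positive flip
rates) emulates an imperfect grader for testing the statistics layer.

What the phantom does **not** emulate: MR intensities and noise,
segmentation errors, anatomical shape variation beyond the sampled
parameters, partial-volume effects, oblique slices, and 3D continuity
beyond three axial slices. Passing the round trip therefore demonstrates
the correctness of measurement + diagnosis on clean label maps; it says
nothing about the performance of any upstream segmentation model on real
patients — which is exactly why the clinical accuracies (86.8 % for
herniation etc.) are reproduced here only at the arithmetic level, from
their published confusion counts.

## Evaluation statistics

Rates are percentages rounded half-up to two decimals for display (raw
doubles kept internally); zero-denominator rates render as "NA", never as
0 or 100. The accuracy interval is exact Clopper–Pearson. McNemar's test
defaults to the continuity-corrected χ² with the correction clamped at
zero, `χ² = max(|FP−FN|−1, 0)² / (FP+FN)`, p = 1 when no discordant pairs
exist — this is the variant whose p-values match the published ones
(p = 1 for 9 vs 8 discordant stenosis segments); an exact binomial variant
is available by flag. Two published metric cells (herniation sensitivity,
stenosis specificity) differ by 0.01 percentage points from their own
confusion counts and are treated as print-rounding slips; the published
spondylolisthesis accuracy interval's upper bound is likewise not
Clopper–Pearson-consistent with its counts and is not asserted.

## Problem sizes

The test suite uses 64×64 grids for brute-force oracle comparisons
(500 random masks), a 200-study phantom cohort for the noiseless round
trip, and 10 000 sampled segments (truth tables only, no rendering) for
prevalence and flip-rate calibration; the acceptance script uses 100
phantoms for labeling and a 100-study cohort for recovery. These sizes
give binomial 3σ bounds tight enough to detect calibration errors of a
few per mille while keeping the whole suite under a minute.

## Known limitations

* The dome/base estimator is 2D and in-plane; craniocaudal migration of
  extruded material (visible sagittally) is not used.
* Stenosis uses the dural-sac area only; cauda-equina aggregation or CSF
  signal criteria are not modelled.
* The nerve-root rule requires the root to be segmented on the disc-level
  slice; a root fully obliterated by disc material (a failure mode of real
  segmentation models) would be scored as not evaluable rather than
  compressed.
* `label_segments` assumes the sacrum is present and bodies are separable
  components; fused bodies would merge segments.
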