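# spinegrader

Rule-based grading of degenerative lumbar-spine pathologies from
multi-class segmentation label maps, with a synthetic anatomical phantom
and the diagnostic-accuracy statistics used to evaluate such systems.

Automated lumbar-spine MRI readers typically work in three stages:
segmentation of the tissues (vertebral bodies, intervertebral discs, dural
sac, nerve roots, sacrum), geometric measurement of clinically used
distances, and diagnosis by fixed rules. `spinegrader` implements the
second and third stages plus the evaluation layer. It consumes 2D integer
label maps — from any upstream segmentation model, or from the bundled
phantom generator — and produces per-segment findings for the six
intervertebral levels TH12/L1 … L5/S1.

## Decision rules

For each segment, on the axial slice at disc level:

* **Disc herniation / bulging.** The contours of the two adjacent
  vertebral bodies are projected over the disc; connected regions of disc
  material posterior to the disc centroid and outside that footprint are
  measured. A region whose maximal excess distance *d* exceeds 3 mm is a
  **herniation** if it subtends ≤ 25 % of the disc circumference and a
  **bulge** if it subtends more; both may coexist on one disc.
* **Protrusion vs extrusion.** A herniation is an **extrusion** when the
  width of its dome exceeds the width of its base at the vertebral margin
  (standard disc nomenclature), otherwise a protrusion.
* **Spinal canal stenosis.** From the dural-sac cross-sectional area *A*:
  relative stenosis for 75 mm² ≤ *A* ≤ 100 mm², absolute stenosis for
  *A* < 75 mm²; both count as a positive finding.
* **Nerve root compression.** Positive when disc tissue is in contact with
  a nerve root **and** the root deviates by more than 2 mm from its
  expected course, interpolated from its position on the adjacent axial
  slices.
* **Spondylolisthesis.** On the sagittal view, tangents through the
  posterior aspects of the adjacent vertebral bodies are intersected with
  the superior-endplate line of the lower body; the offset between the
  intersection points relative to the endplate length gives the slip
  percentage, graded on the Meyerding scale (I–IV by quartile).

The evaluation layer compares two per-segment readings: confusion
matrices per pathology, sensitivity / specificity / accuracy / PPV / NPV,
exact Clopper–Pearson 95 % intervals on accuracy, and McNemar's test
(continuity-corrected χ² by default, exact binomial optional) on the
discordant classifications.

## Worked example

Render a phantom carrying the textbook constellation — a 6.5 mm focal
posterior herniation with a dome wider than its base, a broad 4 mm bulge,
and a 201 mm² dural sac — and grade it:

```python
from spinegrader import io, phantom, report
from spinegrader.phantom import PhantomSpec, SegmentPathology

spec = PhantomSpec(study_id="example", segments={"L5/S1": SegmentPathology(
    herniation_depth_mm=6.5, dome_base_ratio=1.5, bulge_depth_mm=4.0,
    bulge_width_deg=150.0, dural_sac_area_mm2=201.0)})
study, truth = phantom.generate_study(spec)
print(report.render_report(report.build_report(study), "text"))
```

```
Study example (spinegrader 0.1.0)

Segment L1/L2:
  no findings
Segment L2/L3:
  no findings
Segment L3/L4:
  no findings
Segment L4/L5:
  no findings
Segment L5/S1:
  disc herniation (extrusion, 6.52 mm)
  disc bulging
Segment TH12/L1:
  no findings

Most severe segment: L5/S1
```

The herniation is measured at 6.52 mm (6.5 mm was rendered; the half-pixel
discrepancy is rasterization at 0.5 mm/px), classified as an extrusion, the
broad bulge is reported separately, and the 201 mm² sac correctly produces
no stenosis finding.

The same pipeline is available from the shell:

```sh
spinegrader-phantom --out cohort/ --cohort 20 --seed 1   # studies + truth.csv
spinegrader batch --cohort cohort/ --out predictions.csv
spinegrader-eval --pred predictions.csv --truth cohort/truth.csv --out table.csv
```

`spinegrader grade --study dir/ --config thresholds.json --out report.json`
grades a single study; every decision threshold can be overridden through
the JSON config.

## Scope

The package grades label maps; it does not segment images. MR intensity
simulation, DICOM ingestion, Pfirrmann/Modic grading and foraminal
stenosis are out of scope. See `docs/methods.md` for the measurement
conventions, parameter defaults and known limitations.
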