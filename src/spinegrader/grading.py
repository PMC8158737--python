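"""Per-segment pathology rules: from geometric measurements to diagnoses.

The decision rules mirror routine radiological criteria:

* **Herniation / bulging** — disc material more than ``excess_min_mm``
  (default 3 mm) beyond the projected vertebral footprint; focal
  displacement (at most 25 % of the disc circumference) is a herniation,
  broad-based displacement (more than 25 %) a bulge.  Both may coexist on
  one disc as distinct regions.
* **Protrusion / extrusion** — a herniation whose dome is wider than its
  base at the vertebral margin is an extrusion, otherwise a protrusion.
* **Spinal canal stenosis** — dural-sac cross-sectional area below
  100 mm² is a relative, below 75 mm² an absolute stenosis.
* **Nerve root compression** — disc tissue in contact with a root *and*
  the root deviated from its expected course by more than
  ``root_deviation_min_mm``.
* **Spondylolisthesis** — slip percentage from the posterior-tangent
  construction, graded on the Meyerding scale (I–IV by quartile).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import geometry
from .datamodel import SEGMENTS, LabelMap, ReferenceReading, Study, ValidationError
from .geometry import ExcessRegion, GeometryError

__all__ = [
    "Thresholds",
    "RootFinding",
    "SegmentMeasurements",
    "SegmentDiagnosis",
    "classify_disc",
    "classify_stenosis",
    "classify_root",
    "meyerding",
    "label_segments",
    "label_vertebral_bodies",
    "measure_segment",
    "grade_study",
    "diagnoses_to_reading",
]

log = logging.getLogger(__name__)

#: Vertebral body names from the sacrum upward.
_BODY_NAMES_UP = ("L5", "L4", "L3", "L2", "L1", "TH12", "TH11", "TH10")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds, all exposed in the JSON config.

    ``excess_min_mm``, ``bulging_circumference_fraction`` and the stenosis
    areas follow the published defaults; ``root_deviation_min_mm`` and
    ``listhesis_report_min_percent`` are this package's own defaults (a
    deviation magnitude and a reporting floor that suppresses
    rasterization-noise slips) and are documented as such.
    """

    excess_min_mm: float = 3.0
    bulging_circumference_fraction: float = 0.25
    stenosis_relative_mm2: float = 100.0
    stenosis_absolute_mm2: float = 75.0
    root_deviation_min_mm: float = 2.0
    listhesis_report_min_percent: float = 4.0

    def __post_init__(self) -> None:
        vals = asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValidationError("all thresholds must be positive")
        if not self.stenosis_absolute_mm2 < self.stenosis_relative_mm2:
            raise ValidationError("absolute stenosis area must be below relative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Thresholds":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RootFinding:
    """Contact/deviation measurements for one nerve root (one side)."""

    contact: bool = False
    deviation_mm: float = 0.0


@dataclass
class SegmentMeasurements:
    """Raw geometric quantities for one spine segment."""

    segment_id: str
    excess_regions: list[ExcessRegion] = field(default_factory=list)
    dural_sac_area_mm2: Optional[float] = None
    listhesis_percent: float = 0.0
    roots: dict[str, RootFinding] = field(default_factory=dict)  # side -> finding


@dataclass
class SegmentDiagnosis:
    """Boolean/graded findings for one spine segment."""

    segment_id: str
    herniation: bool = False
    herniation_subtype: Optional[str] = None  # "protrusion" | "extrusion"
    bulging: bool = False
    stenosis: str = "none"  # "none" | "relative" | "absolute"
    nerve_root_compression: dict[str, bool] = field(default_factory=dict)
    listhesis_grade: int = 0
    listhesis_percent: float = 0.0
    evaluable: bool = True
    error: Optional[str] = None
    measurements: Optional[SegmentMeasurements] = None

    @property
    def stenosis_present(self) -> bool:
        # both relative and absolute stenosis count as a positive finding
        return self.stenosis != "none"

    @property
    def any_root_compression(self) -> bool:
        return any(self.nerve_root_compression.values())


def classify_disc(
    regions: Sequence[ExcessRegion], thr: Thresholds
) -> tuple[bool, Optional[str], bool]:
    """Herniation / subtype / bulging decision from the disc's excess regions.

    A region deeper than ``excess_min_mm`` counts as a herniation when it is
    focal (angular span at most ``bulging_circumference_fraction`` of the
    circumference) and as a bulge when broad-based; distinct regions can
    make a disc simultaneously herniated and bulging.  The deepest
    herniated region decides the subtype: extrusion iff its dome is wider
    than its base.
    """
    herniated = [
        r
        for r in regions
        if r.max_excess_mm > thr.excess_min_mm
        and r.angular_span_fraction <= thr.bulging_circumference_fraction
    ]
    bulging = any(
        r.max_excess_mm > thr.excess_min_mm
        and r.angular_span_fraction > thr.bulging_circumference_fraction
        for r in regions
    )
    if not herniated:
        return False, None, bulging
    deepest = max(herniated, key=lambda r: r.max_excess_mm)
    subtype = "extrusion" if deepest.dome_width_mm > deepest.base_width_mm else "protrusion"
    return True, subtype, bulging


def classify_stenosis(area_mm2: float, thr: Thresholds) -> str:
    """Stenosis class from the dural-sac area: none / relative / absolute.

    The 75 mm² boundary belongs to the relative class ("less than 75" is
    strict); the 100 mm² boundary is included in the relative class.
    """
    if area_mm2 < 0:
        raise ValidationError("dural sac area cannot be negative")
    if area_mm2 < thr.stenosis_absolute_mm2:
        return "absolute"
    if area_mm2 <= thr.stenosis_relative_mm2:
        return "relative"
    return "none"


def classify_root(contact: bool, deviation_mm: float, thr: Thresholds) -> bool:
    """Compression iff tissue contact *and* deviation beyond the threshold."""
    return bool(contact) and deviation_mm > thr.root_deviation_min_mm


def meyerding(listhesis_percent: float, thr: Thresholds) -> int:
    """Meyerding grade (0–4) from the slip percentage.

    Grades I–IV are the quartiles of the slip percentage; slips below the
    reporting floor are grade 0.
    """
    if listhesis_percent < thr.listhesis_report_min_percent:
        return 0
    if listhesis_percent <= 25.0:
        return 1
    if listhesis_percent <= 50.0:
        return 2
    if listhesis_percent <= 75.0:
        return 3
    return 4


def label_vertebral_bodies(
    sagittal: LabelMap, dictionary
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Name the vertebral bodies on a sagittal slice, counting up from the sacrum.

    Bodies are the 8-connected components of the vertebral-body class,
    ordered inferior to superior by centroid row and named L5, L4, ...
    upward.  Returns (name -> body mask, sacrum mask).
    """
    sacrum = sagittal.class_mask(dictionary, "sacrum")
    if not sacrum.any():
        raise GeometryError("no sacrum label on the sagittal slice")
    vb = sagittal.class_mask(dictionary, "vertebral_body")
    labels, n = ndimage.label(vb, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise GeometryError("no vertebral bodies on the sagittal slice")
    centroids = ndimage.center_of_mass(vb, labels, index=np.arange(1, n + 1))
    # inferior = larger row; order from the sacrum upward
    order = np.argsort([-c[0] for c in centroids])
    if n < 6:
        log.warning("only %d vertebral bodies found; partial labeling", n)
    bodies: dict[str, np.ndarray] = {}
    for rank, idx in enumerate(order):
        if rank >= len(_BODY_NAMES_UP):
            break
        bodies[_BODY_NAMES_UP[rank]] = labels == (idx + 1)
    return bodies, sacrum


def label_segments(sagittal_stack: Sequence[LabelMap], dictionary) -> list[str]:
    """Ordered intervertebral segment names found on the sagittal view.

    The lowest six interspaces are named TH12/L1 … L5/S1 (superior to
    inferior); fewer bodies give a partial list, extra bodies are named
    on up the thoracic spine and their interspaces are not reported.
    """
    mid = sagittal_stack[len(sagittal_stack) // 2]
    bodies, _ = label_vertebral_bodies(mid, dictionary)
    present = [name for name in _BODY_NAMES_UP if name in bodies]
    segments = ["L5/S1"] if "L5" in bodies else []
    for lower, upper in zip(present, present[1:]):
        seg = f"{upper}/{lower}"
        if seg in SEGMENTS:
            segments.append(seg)
    return [s for s in SEGMENTS if s in segments]


def _root_sides(root_mask: np.ndarray, mid_col: float) -> dict[str, np.ndarray]:
    """Split the nerve-root mask into left/right instances about the midline."""
    sides: dict[str, np.ndarray] = {}
    labels, n = ndimage.label(root_mask, structure=np.ones((3, 3), dtype=bool))
    for k in range(1, n + 1):
        comp = labels == k
        _, ccc = np.nonzero(comp)
        side = "left" if ccc.mean() >= mid_col else "right"
        sides[side] = sides.get(side, np.zeros_like(comp)) | comp
    return sides


def _root_centroids_mm(lm: LabelMap, dictionary, mid_col: float) -> dict[str, np.ndarray]:
    sides = _root_sides(lm.class_mask(dictionary, "nerve_root"), mid_col)
    out = {}
    sr, sc = lm.spacing_mm
    for side, mask in sides.items():
        rr, cc = np.nonzero(mask)
        out[side] = np.array([rr.mean() * sr, cc.mean() * sc])
    return out


def measure_segment(
    study: Study, segment_id: str, thr: Thresholds, ap_axis_only: bool = False
) -> SegmentMeasurements:
    """All geometric measurements for one segment of a study.

    Aggregation across the segment's axial slices is per-segment maximum
    for disc excess and root deviation and per-segment minimum for the
    dural-sac area, so that one finding is reported per segment.
    """
    d = study.label_dictionary
    stack = list(study.axial_stacks.get(segment_id, []))
    meas = SegmentMeasurements(segment_id=segment_id)

    disc_slices = [lm for lm in stack if lm.class_mask(d, "intervertebral_disc").any()]
    vb_slices = [lm for lm in stack if lm.class_mask(d, "vertebral_body").any()]

    sac_areas = []
    all_regions: list[ExcessRegion] = []
    roots: dict[str, RootFinding] = {}
    for disc_lm in disc_slices:
        disc_mask = disc_lm.class_mask(d, "intervertebral_disc")
        upper = [lm for lm in vb_slices if lm.slice_index < disc_lm.slice_index]
        lower = [lm for lm in vb_slices if lm.slice_index > disc_lm.slice_index]
        if upper or lower:
            upper_lm = upper[-1] if upper else lower[0]
            lower_lm = lower[0] if lower else upper[-1]
            footprint = geometry.project_vertebral_footprint(
                upper_lm, lower_lm, disc_lm, d["vertebral_body"]
            )
            regions = geometry.disc_excess(
                disc_mask, footprint, disc_lm.spacing_mm, ap_axis_only=ap_axis_only
            )
            all_regions.extend(regions)

            # nerve roots: expected course interpolated between the slices
            # adjacent to the disc level, deviation measured against it
            _, cc = np.nonzero(disc_mask)
            mid_col = cc.mean()
            actual = _root_centroids_mm(disc_lm, d, mid_col)
            above = _root_centroids_mm(upper_lm, d, mid_col) if upper else {}
            below = _root_centroids_mm(lower_lm, d, mid_col) if lower else {}
            sides = _root_sides(disc_lm.class_mask(d, "nerve_root"), mid_col)
            hern_mask = np.zeros_like(disc_mask)
            for r in regions:
                hern_mask |= r.mask
            for side, centroid in actual.items():
                a, b = above.get(side), below.get(side)
                if a is None and b is None:
                    continue
                expected = geometry.expected_root_position(a, b, 0.5)
                dev = float(np.linalg.norm(centroid - expected))
                touch = geometry.contact(hern_mask, sides[side])
                prev = roots.setdefault(side, RootFinding())
                prev.contact = prev.contact or touch
                prev.deviation_mm = max(prev.deviation_mm, dev)

        sac = disc_lm.class_mask(d, "dural_sac")
        if sac.any():
            sac_areas.append(geometry.region_area(sac, disc_lm.spacing_mm))

    meas.excess_regions = sorted(all_regions, key=lambda r: r.max_excess_mm, reverse=True)
    meas.dural_sac_area_mm2 = min(sac_areas) if sac_areas else None
    meas.roots = roots

    # spondylolisthesis from the sagittal view
    mid = study.sagittal_stack[len(study.sagittal_stack) // 2]
    bodies, sacrum = label_vertebral_bodies(mid, d)
    upper_name, lower_name = segment_id.split("/")
    upper_mask = bodies.get(upper_name)
    lower_mask = sacrum if lower_name == "S1" else bodies.get(lower_name)
    if upper_mask is not None and lower_mask is not None:
        tc = geometry.posterior_tangent_construction(
            geometry.extract_contour(upper_mask, mid.spacing_mm),
            geometry.extract_contour(lower_mask, mid.spacing_mm),
        )
        meas.listhesis_percent = tc.listhesis_percent
    return meas


def diagnose_segment(meas: SegmentMeasurements, thr: Thresholds) -> SegmentDiagnosis:
    """Apply every decision rule to one segment's measurements."""
    herniation, subtype, bulging = classify_disc(meas.excess_regions, thr)
    diag = SegmentDiagnosis(
        segment_id=meas.segment_id,
        herniation=herniation,
        herniation_subtype=subtype,
        bulging=bulging,
        listhesis_percent=meas.listhesis_percent,
        listhesis_grade=meyerding(meas.listhesis_percent, thr),
        measurements=meas,
    )
    if meas.dural_sac_area_mm2 is not None:
        diag.stenosis = classify_stenosis(meas.dural_sac_area_mm2, thr)
    for side, rf in meas.roots.items():
        diag.nerve_root_compression[side] = classify_root(
            rf.contact, rf.deviation_mm, thr
        )
    return diag


def grade_study(
    study: Study, thr: Thresholds | None = None, ap_axis_only: bool = False
) -> list[SegmentDiagnosis]:
    """Grade every segment of a study; deterministic for fixed input.

    Geometry errors in one segment do not abort the others: the failed
    segment is returned flagged not-evaluable with the error message.
    """
    thr = thr or Thresholds()
    segments = label_segments(study.sagittal_stack, study.label_dictionary)
    for seg in study.axial_stacks:
        if seg not in segments:
            segments.append(seg)
    diagnoses = []
    for seg in sorted(segments, key=SEGMENTS.index):
        try:
            meas = measure_segment(study, seg, thr, ap_axis_only=ap_axis_only)
            diagnoses.append(diagnose_segment(meas, thr))
        except GeometryError as exc:
            log.warning("segment %s not evaluable: %s", seg, exc)
            diagnoses.append(
                SegmentDiagnosis(segment_id=seg, evaluable=False, error=str(exc))
            )
    return diagnoses


def diagnoses_to_reading(
    study_id: str, diagnoses: Sequence[SegmentDiagnosis]
) -> ReferenceReading:
    """Collapse per-segment diagnoses into the binary-findings table form."""
    reading = ReferenceReading(study_id=study_id)
    for diag in diagnoses:
        if not diag.evaluable:
            continue
        seg = diag.segment_id
        reading.set(seg, "herniation", diag.herniation)
        reading.set(seg, "extrusion", diag.herniation_subtype == "extrusion")
        reading.set(seg, "bulging", diag.bulging)
        reading.set(seg, "stenosis", diag.stenosis_present)
        reading.set(seg, "nerve_root_compression", diag.any_root_compression)
        reading.set(
            seg,
            "spondylolisthesis",
            diag.listhesis_grade >= 1,
            grade=diag.listhesis_grade,
        )
    return reading
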