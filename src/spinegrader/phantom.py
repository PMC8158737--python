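"""Synthetic label-map phantom of the lumbar spine with exact ground truth.

The phantom renders the 2D cross-sections every grading rule operates on:

* per-segment axial stacks of three slices (upper vertebral body, disc
  level, lower vertebral body) with the disc as an ellipse, the adjacent
  vertebral-body footprints as the same ellipse, the dural sac as an
  ellipse scaled to a target area, and two nerve roots;
* one sagittal midline slice with the sacrum and six (or more) vertebral
  bodies as rectangles, spondylolisthesis applied as an anterior offset of
  the slipping vertebra and everything above it.

Pathologies are parameterized continuously — herniation depth and angular
width, dome/base ratio, bulge depth/width, dural-sac area, slip
percentage, nerve-root displacement — so that rendering followed by
measurement recovers the generating parameters up to rasterization error.
Focal herniations are raised-cosine deformations of the posterior disc
boundary (dome narrower than base: protrusions); extrusions are rendered
as a stalk capped by a wider dome.  Everything is deterministic for a
fixed spec; cohort sampling is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .datamodel import (
    PATHOLOGIES,
    SEGMENTS,
    LabelDictionary,
    LabelMap,
    ReferenceReading,
    Study,
)

__all__ = [
    "PhantomSpecError",
    "SegmentPathology",
    "PhantomSpec",
    "GroundTruth",
    "CohortResult",
    "generate_study",
    "generate_cohort",
    "TABLE1_PREVALENCES",
    "TABLE1_ERROR_RATES",
]


class PhantomSpecError(ValueError):
    """Pathology parameters that cannot be rendered on the requested grid."""


@dataclass(frozen=True)
class SegmentPathology:
    """Continuous pathology parameters for one segment.

    Depths of zero mean the finding is absent.  ``dome_base_ratio`` > 1
    renders the herniation as an extrusion (dome wider than base), otherwise
    as a raised-cosine protrusion.  Angles are measured in the axial plane
    from patient-left over posterior (90 deg) to patient-right.
    """

    herniation_depth_mm: float = 0.0
    herniation_width_deg: float = 30.0
    herniation_angle_deg: float = 90.0
    herniation_base_mm: float = 6.0
    dome_base_ratio: float = 0.0
    bulge_depth_mm: float = 0.0
    bulge_width_deg: float = 140.0
    bulge_angle_deg: float = 90.0
    dural_sac_area_mm2: float = 180.0
    listhesis_percent: float = 0.0
    root_compression: bool = False
    root_offset_mm: float = 3.0

    @property
    def herniated(self) -> bool:
        return self.herniation_depth_mm > 0

    @property
    def bulged(self) -> bool:
        return self.bulge_depth_mm > 0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameter set for one synthetic study.

    Default rendering resolution is 0.5 mm/px in both planes; the
    truth-recovery tolerances stated in the docs are tied to it.
    """

    seed: int = 0
    study_id: str = "phantom"
    axial_shape: tuple[int, int] = (128, 128)
    axial_spacing_mm: tuple[float, float] = (0.5, 0.5)
    sagittal_spacing_mm: tuple[float, float] = (0.5, 0.5)
    sagittal_cols: int = 160
    disc_semi_axes_mm: tuple[float, float] = (24.0, 17.0)  # (lateral, AP)
    vb_height_mm: float = 24.0
    vb_ap_mm: float = 32.0  # superior endplate length
    disc_gap_mm: float = 8.0
    sacrum_height_mm: float = 30.0
    extra_thoracic_bodies: int = 0
    segments: Mapping[str, SegmentPathology] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seg, p in self.segments.items():
            if seg not in SEGMENTS:
                raise PhantomSpecError(f"unknown segment {seg!r}")
            if p.herniation_depth_mm < 0 or p.bulge_depth_mm < 0:
                raise PhantomSpecError("pathology depths must be >= 0")
            for w in (p.herniation_width_deg, p.bulge_width_deg):
                if not (0 < w <= 360):
                    raise PhantomSpecError("angular widths must be in (0, 360]")
            if p.herniation_depth_mm > 12 or p.bulge_depth_mm > 8:
                raise PhantomSpecError("bump depth exceeds renderable range")
            if not (40.0 <= p.dural_sac_area_mm2 <= 280.0):
                raise PhantomSpecError("dural sac area outside renderable range")
            if p.listhesis_percent < 0 or p.listhesis_percent > 60:
                raise PhantomSpecError("listhesis percent outside renderable range")

    def pathology(self, segment: str) -> SegmentPathology:
        return self.segments.get(segment, SegmentPathology())


@dataclass
class GroundTruth:
    """Exact per-segment findings implied by a :class:`PhantomSpec`."""

    reading: ReferenceReading
    parameters: dict[str, SegmentPathology]


@dataclass
class CohortResult:
    specs: list[PhantomSpec]
    studies: Optional[list[Study]]
    truth: dict[str, ReferenceReading]
    degraded: dict[str, ReferenceReading]


# --------------------------------------------------------------------------
# rendering


def _ellipse_radius(a: float, b: float, phi: np.ndarray) -> np.ndarray:
    """Polar radius of an axis-aligned ellipse (a along x, b along y)."""
    return a * b / np.hypot(b * np.cos(phi), a * np.sin(phi))


def _grid_mm(shape, spacing):
    rows = np.arange(shape[0])[:, None] * spacing[0]
    cols = np.arange(shape[1])[None, :] * spacing[1]
    return rows, cols


def _render_axial_segment(
    spec: PhantomSpec, seg: str, p: SegmentPathology, dictionary: LabelDictionary
) -> list[LabelMap]:
    shape, spacing = spec.axial_shape, spec.axial_spacing_mm
    a, b = spec.disc_semi_axes_mm
    cy = 20.0  # disc centre, mm (row: anterior-posterior axis)
    cx = shape[1] * spacing[1] / 2.0

    rows, cols = _grid_mm(shape, spacing)
    dy, dx = rows - cy, cols - cx
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)  # posterior = (0, pi)

    # when herniation and bulge coexist, they are separated angularly so
    # that they stay distinct excess regions
    hern_angle = np.deg2rad(
        35.0 if (p.herniated and p.bulged and p.herniation_angle_deg == p.bulge_angle_deg)
        else p.herniation_angle_deg
    )
    bulge_angle = np.deg2rad(
        138.0 if (p.herniated and p.bulged and p.herniation_angle_deg == p.bulge_angle_deg)
        else p.bulge_angle_deg
    )

    r_disc = _ellipse_radius(a, b, phi)
    bump = np.zeros_like(rho)
    if p.bulged:
        w = np.deg2rad(p.bulge_width_deg)
        off = np.angle(np.exp(1j * (phi - bulge_angle)))
        inside = np.abs(off) <= w / 2
        bump[inside] += p.bulge_depth_mm * np.cos(np.pi * off[inside] / w) ** 2
    mushroom = np.zeros(shape, dtype=bool)
    if p.herniated:
        if p.dome_base_ratio > 1.0:
            # extrusion: stalk of width `base` capped by a wider dome
            d = p.herniation_depth_mm
            base_w = p.herniation_base_mm
            dome_w = base_w * p.dome_base_ratio
            cap_b = min(d / 2.0, 3.0)
            r0 = float(_ellipse_radius(a, b, np.array([hern_angle]))[0])
            u = np.array([np.cos(hern_angle), np.sin(hern_angle)])  # (x, y)
            px, py = cx + r0 * u[0], cy + r0 * u[1]
            s = (dx - (px - cx)) * u[0] + (dy - (py - cy)) * u[1]
            t = -(dx - (px - cx)) * u[1] + (dy - (py - cy)) * u[0]
            stalk = (s >= -2.0) & (s <= d - cap_b) & (np.abs(t) <= base_w / 2)
            cap = ((s - (d - cap_b)) / cap_b) ** 2 + (t / (dome_w / 2)) ** 2 <= 1.0
            mushroom = stalk | cap
        else:
            w = np.deg2rad(p.herniation_width_deg)
            off = np.angle(np.exp(1j * (phi - hern_angle)))
            inside = np.abs(off) <= w / 2
            bump[inside] += p.herniation_depth_mm * np.cos(np.pi * off[inside] / w) ** 2

    disc_mask = (rho <= r_disc + bump) | mushroom
    vb_mask = rho <= r_disc  # vertebral footprint = baseline disc ellipse

    # dural sac: 2:1 ellipse scaled to the target area, behind the disc
    sac_b = np.sqrt(p.dural_sac_area_mm2 / (2.0 * np.pi))
    sac_a = 2.0 * sac_b
    sac_cy = cy + b + 11.0 + sac_b
    sac_mask = ((cols - cx) / sac_a) ** 2 + ((rows - sac_cy) / sac_b) ** 2 <= 1.0

    # nerve roots: nominal positions lateral to the sac; a compressed root
    # sits at the herniation apex, its expected course (adjacent slices)
    # displaced back by root_offset_mm
    root_r = 1.5
    nominal = {
        "left": np.array([cx + 19.0, cy + 27.0]),  # (x, y) mm
        "right": np.array([cx - 19.0, cy + 27.0]),
    }
    disc_pos = dict(nominal)
    adj_pos = dict(nominal)
    if p.root_compression and p.herniated:
        u = np.array([np.cos(hern_angle), np.sin(hern_angle)])
        r0 = float(_ellipse_radius(a, b, np.array([hern_angle]))[0])
        apex = np.array([cx, cy]) + (r0 + p.herniation_depth_mm) * u
        side = "left" if u[0] >= 0 else "right"
        disc_pos[side] = apex + 1.0 * u
        adj_pos[side] = disc_pos[side] - p.root_offset_mm * u

    def roots_mask(positions) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        for pos in positions.values():
            m |= (cols - pos[0]) ** 2 + (rows - pos[1]) ** 2 <= root_r**2
        return m

    def compose(layers) -> np.ndarray:
        px = np.zeros(shape, dtype=np.int64)
        for name, mask in layers:
            px[mask] = dictionary[name]
        return px

    vb_px = compose([("nerve_root", roots_mask(adj_pos)), ("vertebral_body", vb_mask)])
    disc_px = compose(
        [
            ("dural_sac", sac_mask),
            ("nerve_root", roots_mask(disc_pos)),
            ("intervertebral_disc", disc_mask),
        ]
    )
    common = dict(plane="axial", spacing_mm=spacing, segment_id=seg)
    return [
        LabelMap(pixels=vb_px, slice_index=0, **common),
        LabelMap(pixels=disc_px, slice_index=1, **common),
        LabelMap(pixels=vb_px.copy(), slice_index=2, **common),
    ]


def _render_sagittal(spec: PhantomSpec, dictionary: LabelDictionary) -> LabelMap:
    sr, sc = spec.sagittal_spacing_mm
    n_bodies = 6 + spec.extra_thoracic_bodies
    height_mm = 12.0 + n_bodies * (spec.vb_height_mm + spec.disc_gap_mm) + spec.sacrum_height_mm
    shape = (int(np.ceil(height_mm / sr)), spec.sagittal_cols)
    rows, cols = _grid_mm(shape, (sr, sc))

    anterior_x = 28.0  # anterior edge of the column, mm (x grows posteriorly)

    # anterior slip of each body = sum of the slips of the segments below it
    listhesis = {seg: spec.pathology(seg).listhesis_percent for seg in SEGMENTS}
    names_up = ["L5", "L4", "L3", "L2", "L1", "TH12"] + [
        f"TH{11 - i}" for i in range(spec.extra_thoracic_bodies)
    ]
    segs_up = ["L5/S1", "L4/L5", "L3/L4", "L2/L3", "L1/L2", "TH12/L1"]
    offsets: dict[str, float] = {}
    cum = 0.0
    for name, seg in zip(names_up, segs_up + [None] * spec.extra_thoracic_bodies):
        if seg is not None:
            cum += listhesis[seg] / 100.0 * spec.vb_ap_mm
        offsets[name] = cum
    if cum > anterior_x - 2.0:
        raise PhantomSpecError("cumulative listhesis offset exceeds the grid margin")

    px = np.zeros(shape, dtype=np.int64)

    # sacrum at the bottom
    sac_top = height_mm - 6.0 - spec.sacrum_height_mm
    sac = (
        (rows >= sac_top)
        & (rows < sac_top + spec.sacrum_height_mm)
        & (cols >= anterior_x)
        & (cols < anterior_x + spec.vb_ap_mm)
    )
    px[sac] = dictionary["sacrum"]

    vb = np.zeros(shape, dtype=bool)
    disc = np.zeros(shape, dtype=bool)
    top = sac_top
    for name in names_up:
        gap_top = top - spec.disc_gap_mm
        body_top = gap_top - spec.vb_height_mm
        x0 = anterior_x - offsets[name]
        body = (
            (rows >= body_top)
            & (rows < body_top + spec.vb_height_mm)
            & (cols >= x0)
            & (cols < x0 + spec.vb_ap_mm)
        )
        d = (
            (rows >= gap_top + spec.disc_gap_mm / 4)
            & (rows < top - spec.disc_gap_mm / 4)
            & (cols >= x0)
            & (cols < x0 + spec.vb_ap_mm)
        )
        vb |= body
        disc |= d
        top = body_top
    px[disc] = dictionary["intervertebral_disc"]
    px[vb] = dictionary["vertebral_body"]
    return LabelMap(pixels=px, plane="sagittal", spacing_mm=(sr, sc), slice_index=0)


def generate_study(spec: PhantomSpec) -> tuple[Study, GroundTruth]:
    """Render a study from a spec, with the implied ground truth.

    Deterministic: the same spec always yields bit-identical label maps.
    """
    dictionary = LabelDictionary.default()
    axial = {
        seg: _render_axial_segment(spec, seg, spec.pathology(seg), dictionary)
        for seg in SEGMENTS
    }
    study = Study(
        study_id=spec.study_id,
        sagittal_stack=[_render_sagittal(spec, dictionary)],
        axial_stacks=axial,
        label_dictionary=dictionary,
    )

    _, reading = _truth_only(spec)
    params = {seg: spec.pathology(seg) for seg in SEGMENTS}
    return study, GroundTruth(reading=reading, parameters=params)


def _meyerding_truth(percent: float) -> int:
    if percent < 4.0:
        return 0
    for grade, hi in ((1, 25.0), (2, 50.0), (3, 75.0)):
        if percent <= hi:
            return grade
    return 4


# --------------------------------------------------------------------------
# cohort sampling

#: Per-segment prevalences of the six findings in a routine low-back-pain
#: cohort (herniations 77/888, thereof 46 extrusions; bulgings 133/888;
#: stenoses 35/888; root compressions 59/1036; listheses 20/888).
TABLE1_PREVALENCES: dict[str, float] = {
    "herniation": 77 / 888,
    "extrusion_given_herniation": 46 / 77,
    "bulging": 133 / 888,
    "stenosis": 35 / 888,
    "nerve_root_compression": 59 / 1036,
    "spondylolisthesis": 20 / 888,
}

#: Per-pathology (false-negative, false-positive) flip rates of an imperfect
#: grader, derived from the published confusion counts.
TABLE1_ERROR_RATES: dict[str, tuple[float, float]] = {
    "herniation": (19 / 77, 98 / 811),
    "extrusion": (5 / 46, 115 / 842),
    "bulging": (64 / 133, 153 / 755),
    "stenosis": (8 / 35, 9 / 853),
    "nerve_root_compression": (17 / 59, 81 / 977),
    "spondylolisthesis": (4 / 20, 106 / 868),
}


def _sample_segment(rng: np.random.Generator, prevalences: Mapping[str, float]) -> SegmentPathology:
    p = SegmentPathology()
    if rng.random() < prevalences.get("herniation", 0.0):
        extruded = rng.random() < prevalences.get("extrusion_given_herniation", 0.0)
        compressed = rng.random() < min(
            1.0,
            prevalences.get("nerve_root_compression", 0.0)
            / max(prevalences.get("herniation", 1.0), 1e-12),
        )
        p = replace(
            p,
            herniation_depth_mm=float(rng.uniform(4.5, 9.0)),
            herniation_width_deg=float(rng.uniform(25.0, 55.0)),
            dome_base_ratio=1.5 if extruded else 0.0,
            root_compression=compressed,
            root_offset_mm=float(rng.uniform(3.0, 5.0)),
        )
    if rng.random() < prevalences.get("bulging", 0.0):
        p = replace(
            p,
            bulge_depth_mm=float(rng.uniform(4.5, 7.5)),
            bulge_width_deg=float(rng.uniform(125.0, 135.0 if p.herniated else 160.0)),
        )
    if rng.random() < prevalences.get("stenosis", 0.0):
        p = replace(p, dural_sac_area_mm2=float(rng.uniform(60.0, 95.0)))
    else:
        p = replace(p, dural_sac_area_mm2=float(rng.uniform(130.0, 220.0)))
    if rng.random() < prevalences.get("spondylolisthesis", 0.0):
        p = replace(p, listhesis_percent=float(rng.uniform(8.0, 22.0)))
    return p


def _degrade(
    truth: ReferenceReading,
    error_rates: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
) -> ReferenceReading:
    pred = ReferenceReading(study_id=truth.study_id, segments=truth.segments)
    for seg in truth.segments:
        for path in PATHOLOGIES:
            present = truth.get(seg, path)
            fn_rate, fp_rate = error_rates.get(path, (0.0, 0.0))
            if present:
                out = rng.random() >= fn_rate
            else:
                out = rng.random() < fp_rate
            pred.set(seg, path, out, grade=1 if (out and path == "spondylolisthesis") else None)
    return pred


def generate_cohort(
    n_studies: int,
    prevalences: Mapping[str, float] | None = None,
    error_rates: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    render: bool = True,
) -> CohortResult:
    """Sample a cohort of phantom studies plus a degraded prediction table.

    Pathologies are sampled independently per segment at the stated
    prevalences (nerve-root compression only on herniated segments, as the
    contact rule requires).  ``DegradedPredictions`` flips each ground-truth
    finding at the per-pathology false-negative / false-positive rates,
    emulating an imperfect grader for evaluation-statistics testing.  With
    ``render=False`` only the spec and the two tables are produced.
    """
    prevalences = dict(prevalences or TABLE1_PREVALENCES)
    error_rates = dict(error_rates or {})
    rng = np.random.default_rng(seed)

    specs, studies, truth, degraded = [], [] if render else None, {}, {}
    for i in range(n_studies):
        sid = f"phantom-{i:04d}"
        spec = PhantomSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            study_id=sid,
            segments={seg: _sample_segment(rng, prevalences) for seg in SEGMENTS},
        )
        specs.append(spec)
        if render:
            study, gt = generate_study(spec)
            studies.append(study)
            truth[sid] = gt.reading
        else:
            _, gt = _truth_only(spec)
            truth[sid] = gt
        degraded[sid] = _degrade(truth[sid], error_rates, rng)
    return CohortResult(specs=specs, studies=studies, truth=truth, degraded=degraded)


def _truth_only(spec: PhantomSpec) -> tuple[None, ReferenceReading]:
    reading = ReferenceReading(study_id=spec.study_id)
    for seg in SEGMENTS:
        p = spec.pathology(seg)
        grade = _meyerding_truth(p.listhesis_percent)
        reading.set(seg, "herniation", p.herniated)
        reading.set(seg, "extrusion", p.herniated and p.dome_base_ratio > 1.0)
        reading.set(seg, "bulging", p.bulged)
        reading.set(seg, "stenosis", p.dural_sac_area_mm2 <= 100.0)
        reading.set(seg, "nerve_root_compression", p.root_compression and p.herniated)
        reading.set(seg, "spondylolisthesis", grade >= 1, grade=grade)
    return None, reading
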