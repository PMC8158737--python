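"""Structured per-study reports: the end product of the grading pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .datamodel import Study
from .grading import SegmentDiagnosis, Thresholds, grade_study

__all__ = ["SegmentReport", "StudyReport", "build_report", "render_report"]

REPORT_SCHEMA_VERSION = 1

_SEVERITY_ORDER = ("absolute", "relative", "none")


@dataclass
class SegmentReport:
    """Findings and measured magnitudes for one segment."""

    segment_id: str
    evaluable: bool
    herniation: bool = False
    herniation_subtype: Optional[str] = None
    max_excess_mm: Optional[float] = None
    bulging: bool = False
    stenosis: str = "none"
    dural_sac_area_mm2: Optional[float] = None
    nerve_root_compression: dict = field(default_factory=dict)
    listhesis_percent: float = 0.0
    listhesis_grade: int = 0
    error: Optional[str] = None


@dataclass
class StudyReport:
    study_id: str
    thresholds: dict
    segments: list[SegmentReport]
    most_severe_segment: Optional[str]
    schema_version: int = REPORT_SCHEMA_VERSION
    tool_version: str = __version__


def _severity(seg: SegmentReport) -> tuple:
    """Sort key: more severe segments first."""
    return (
        _SEVERITY_ORDER.index(seg.stenosis),
        -int(any(seg.nerve_root_compression.values())),
        -int(seg.herniation_subtype == "extrusion"),
        -int(seg.herniation),
        -(seg.max_excess_mm or 0.0),
        -int(seg.bulging),
        -seg.listhesis_grade,
    )


def build_report(
    study: Study,
    thresholds: Thresholds | None = None,
    diagnoses: Sequence[SegmentDiagnosis] | None = None,
) -> StudyReport:
    """Grade a study (unless diagnoses are given) and assemble the report."""
    thresholds = thresholds or Thresholds()
    if diagnoses is None:
        diagnoses = grade_study(study, thresholds)
    segments = []
    for d in diagnoses:
        m = d.measurements
        segments.append(
            SegmentReport(
                segment_id=d.segment_id,
                evaluable=d.evaluable,
                herniation=d.herniation,
                herniation_subtype=d.herniation_subtype,
                max_excess_mm=(
                    round(m.excess_regions[0].max_excess_mm, 2)
                    if m and m.excess_regions
                    else None
                ),
                bulging=d.bulging,
                stenosis=d.stenosis,
                dural_sac_area_mm2=(
                    round(m.dural_sac_area_mm2, 2)
                    if m and m.dural_sac_area_mm2 is not None
                    else None
                ),
                nerve_root_compression=dict(sorted(d.nerve_root_compression.items())),
                listhesis_percent=round(d.listhesis_percent, 2),
                listhesis_grade=d.listhesis_grade,
                error=d.error,
            )
        )
    segments.sort(key=lambda s: s.segment_id)
    evaluable = [s for s in segments if s.evaluable]
    flagged = min(evaluable, key=_severity) if evaluable else None
    abnormal = flagged is not None and (
        flagged.herniation
        or flagged.bulging
        or flagged.stenosis != "none"
        or any(flagged.nerve_root_compression.values())
        or flagged.listhesis_grade >= 1
    )
    return StudyReport(
        study_id=study.study_id,
        thresholds=asdict(thresholds),
        segments=segments,
        most_severe_segment=flagged.segment_id if abnormal else None,
    )


def _text_lines(report: StudyReport) -> list[str]:
    lines = [
        f"Study {report.study_id} (spinegrader {report.tool_version})",
        "",
    ]
    for s in report.segments:
        lines.append(f"Segment {s.segment_id}:")
        if not s.evaluable:
            lines.append(f"  NOT EVALUABLE: {s.error}")
            continue
        findings = []
        if s.herniation:
            findings.append(
                f"disc herniation ({s.herniation_subtype}, {s.max_excess_mm} mm)"
            )
        if s.bulging:
            findings.append("disc bulging")
        if s.stenosis != "none":
            findings.append(
                f"{s.stenosis} spinal canal stenosis ({s.dural_sac_area_mm2} mm^2)"
            )
        for side, comp in s.nerve_root_compression.items():
            if comp:
                findings.append(f"nerve root compression ({side})")
        if s.listhesis_grade >= 1:
            findings.append(
                f"spondylolisthesis Meyerding grade {s.listhesis_grade}"
                f" ({s.listhesis_percent}%)"
            )
        if not findings:
            lines.append("  no findings")
        else:
            lines.extend(f"  {f}" for f in findings)
    if report.most_severe_segment:
        lines += ["", f"Most severe segment: {report.most_severe_segment}"]
    return lines


def render_report(report: StudyReport, format: str = "json") -> str:
    """Serialize a report deterministically as JSON or plain text."""
    if format == "json":
        return json.dumps(asdict(report), sort_keys=True, indent=2) + "\n"
    if format == "text":
        return "\n".join(_text_lines(report)) + "\n"
    raise ValueError(f"unknown report format {format!r}")


def write_report(report: StudyReport, path: str | Path, format: str = "json") -> Path:
    path = Path(path)
    path.write_text(render_report(report, format))
    return path
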