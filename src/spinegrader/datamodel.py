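"""Core domain types for label-map studies of the lumbar spine.

A *study* is a collection of 2D integer label maps (one sagittal stack plus
one axial stack per intervertebral segment) together with a dictionary that
maps tissue-class names to pixel labels.  All physical quantities downstream
of I/O are expressed in millimetres; a pixel at (row, col) has its centre at
``(row * spacing_row, col * spacing_col)`` with the origin at the centre of
pixel (0, 0).

Orientation conventions (fixed, carried by the file format):

* axial: anterior = decreasing row, patient-left = increasing column
  (radiological display);
* sagittal: superior = decreasing row, anterior = decreasing column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SEGMENTS",
    "PATHOLOGIES",
    "REQUIRED_CLASSES",
    "OPTIONAL_CLASSES",
    "ValidationError",
    "FormatError",
    "LabelDictionary",
    "LabelMap",
    "Study",
    "ReferenceReading",
]

#: Intervertebral segments graded by the pipeline, superior to inferior.
SEGMENTS: tuple[str, ...] = (
    "TH12/L1",
    "L1/L2",
    "L2/L3",
    "L3/L4",
    "L4/L5",
    "L5/S1",
)

#: Binary findings evaluated per segment.
PATHOLOGIES: tuple[str, ...] = (
    "herniation",
    "extrusion",
    "bulging",
    "stenosis",
    "nerve_root_compression",
    "spondylolisthesis",
)

REQUIRED_CLASSES: tuple[str, ...] = (
    "background",
    "vertebral_body",
    "intervertebral_disc",
    "dural_sac",
    "nerve_root",
    "sacrum",
)
OPTIONAL_CLASSES: tuple[str, ...] = ("spinous_process", "ligamentum_flavum")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class FormatError(IOError):
    """Raised when an on-disk study directory or table is malformed."""


@dataclass(frozen=True)
class LabelDictionary:
    """Mapping of tissue-class name to positive integer pixel label.

    ``background`` is always label 0.  Labels must be unique and every class
    used by a study must be present here.
    """

    classes: Mapping[str, int]

    def __post_init__(self) -> None:
        classes = dict(self.classes)
        object.__setattr__(self, "classes", classes)
        if classes.get("background", 0) != 0:
            raise ValidationError("label 0 is reserved for 'background'")
        classes.setdefault("background", 0)
        for name in REQUIRED_CLASSES:
            if name not in classes:
                raise ValidationError(f"required tissue class missing: {name!r}")
        labels = list(classes.values())
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate pixel labels in label dictionary")
        for name, lab in classes.items():
            if name != "background" and lab <= 0:
                raise ValidationError(f"label for {name!r} must be positive")

    def __getitem__(self, name: str) -> int:
        return self.classes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.classes

    @property
    def labels(self) -> frozenset[int]:
        return frozenset(self.classes.values())

    @classmethod
    def default(cls) -> "LabelDictionary":
        return cls({name: i for i, name in enumerate(REQUIRED_CLASSES)})


@dataclass
class LabelMap:
    """One 2D integer-labelled slice.

    Parameters
    ----------
    pixels
        2D integer array; values index classes of the study's
        :class:`LabelDictionary`.
    plane
        ``"axial"`` or ``"sagittal"``.
    spacing_mm
        ``(row, col)`` pixel spacing in millimetres.
    segment_id
        Intervertebral segment this slice belongs to (required for axial
        slices).
    slice_index
        Position within its stack (superior to inferior).
    instance_labels
        Optional mapping pixel-label -> anatomical instance name (e.g. which
        vertebra a body label corresponds to).
    """

    pixels: np.ndarray
    plane: str
    spacing_mm: tuple[float, float]
    segment_id: Optional[str] = None
    slice_index: int = 0
    instance_labels: Optional[Mapping[int, str]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError("pixels must be a 2D integer array")
        if self.plane not in ("axial", "sagittal"):
            raise ValidationError(f"unknown plane {self.plane!r}")
        sr, sc = float(self.spacing_mm[0]), float(self.spacing_mm[1])
        if not (sr > 0 and sc > 0):
            raise ValidationError("spacing_mm must be positive")
        self.spacing_mm = (sr, sc)
        if self.plane == "axial" and self.segment_id is None:
            raise ValidationError("axial label maps must carry a segment_id")
        if self.segment_id is not None and self.segment_id not in SEGMENTS:
            raise ValidationError(f"unknown segment_id {self.segment_id!r}")

    def mask(self, label: int) -> np.ndarray:
        """Binary mask of one pixel label."""
        return self.pixels == label

    def class_mask(self, dictionary: LabelDictionary, name: str) -> np.ndarray:
        return self.mask(dictionary[name])

    def validate_against(self, dictionary: LabelDictionary) -> None:
        present = set(np.unique(self.pixels).tolist())
        unknown = present - set(dictionary.labels)
        if unknown:
            raise ValidationError(
                f"pixel labels {sorted(unknown)} absent from label dictionary"
            )


@dataclass
class Study:
    """A complete label-map study: one sagittal stack, per-segment axial stacks."""

    study_id: str
    sagittal_stack: Sequence[LabelMap]
    axial_stacks: Mapping[str, Sequence[LabelMap]]
    label_dictionary: LabelDictionary

    def __post_init__(self) -> None:
        if not self.sagittal_stack:
            raise ValidationError("sagittal stack must be non-empty")
        for seg in self.axial_stacks:
            if seg not in SEGMENTS:
                raise ValidationError(f"unknown segment_id {seg!r}")
        self.validate()

    def validate(self) -> None:
        for lm in self.sagittal_stack:
            if lm.plane != "sagittal":
                raise ValidationError("sagittal stack contains non-sagittal map")
            lm.validate_against(self.label_dictionary)
        for seg, stack in self.axial_stacks.items():
            for lm in stack:
                if lm.plane != "axial":
                    raise ValidationError("axial stack contains non-axial map")
                if lm.segment_id != seg:
                    raise ValidationError(
                        f"axial map segment_id {lm.segment_id!r} under stack {seg!r}"
                    )
                lm.validate_against(self.label_dictionary)


@dataclass
class ReferenceReading:
    """Per-segment binary findings for one study, plus Meyerding grades.

    Absent entries mean "finding absent".  This is the common currency
    between the reference (expert) reading, the pipeline's own predictions
    and the evaluation statistics.
    """

    study_id: str
    segments: tuple[str, ...] = SEGMENTS
    findings: dict = field(default_factory=dict)  # (segment, pathology) -> bool
    grades: dict = field(default_factory=dict)  # segment -> Meyerding grade

    def __post_init__(self) -> None:
        for (seg, path), val in self.findings.items():
            if seg not in self.segments:
                raise ValidationError(f"segment {seg!r} outside segment universe")
            if path not in PATHOLOGIES:
                raise ValidationError(f"unknown pathology {path!r}")
            self.findings[(seg, path)] = bool(val)

    def set(self, segment: str, pathology: str, present: bool, grade: int | None = None) -> None:
        if pathology not in PATHOLOGIES:
            raise ValidationError(f"unknown pathology {pathology!r}")
        if segment not in self.segments:
            raise ValidationError(f"segment {segment!r} outside segment universe")
        self.findings[(segment, pathology)] = bool(present)
        if grade is not None:
            self.grades[segment] = int(grade)

    def get(self, segment: str, pathology: str) -> bool:
        return self.findings.get((segment, pathology), False)

    def positives(self, pathology: str) -> int:
        return sum(self.get(seg, pathology) for seg in self.segments)
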