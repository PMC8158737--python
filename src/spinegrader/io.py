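"""Readers and writers for label-map studies and reference-reading tables.

On disk a study is a directory with one JSON sidecar (``study.json``) holding
all metadata, plus one 16-bit grayscale PNG per slice (or one NIfTI volume
per stack).  Image files carry pixels only; the sidecar is the single source
of label dictionary, plane, spacing and segment assignment.  Sidecars are
written with sorted keys so that two writes of the same study are
byte-identical.

Reference readings and prediction dumps are long-format CSV with columns
``study_id, segment_id, pathology, present, grade``; rows absent from the
table mean the finding is absent.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .datamodel import (
    PATHOLOGIES,
    SEGMENTS,
    FormatError,
    LabelDictionary,
    LabelMap,
    ReferenceReading,
    Study,
    ValidationError,
)

__all__ = [
    "SIDECAR_NAME",
    "read_study",
    "write_study",
    "read_reference",
    "write_reference",
    "readings_to_frame",
    "frame_to_readings",
]

SIDECAR_NAME = "study.json"
SCHEMA_VERSION = 1


def _slice_meta(lm: LabelMap, fname: str) -> dict:
    meta = {"file": fname, "slice_index": lm.slice_index}
    if lm.segment_id is not None:
        meta["segment_id"] = lm.segment_id
    if lm.instance_labels:
        meta["instance_labels"] = {str(k): v for k, v in lm.instance_labels.items()}
    return meta


def write_study(study: Study, path: str | Path, image_format: str = "png") -> Path:
    """Write a study directory (sidecar + per-slice images).

    ``image_format`` is ``"png"`` (one 16-bit PNG per slice, the default) or
    ``"nifti"`` (one ``.nii.gz`` volume per stack).  Returns the directory.
    """
    if image_format not in ("png", "nifti"):
        raise ValueError(f"unknown image format {image_format!r}")
    path = Path(path)
    (path / "slices").mkdir(parents=True, exist_ok=True)

    stacks_meta = []
    named_stacks: list[tuple[str, list[LabelMap]]] = [
        ("sagittal", list(study.sagittal_stack))
    ]
    for seg in SEGMENTS:
        if seg in study.axial_stacks:
            named_stacks.append((f"axial_{seg.replace('/', '-')}", list(study.axial_stacks[seg])))

    for name, stack in named_stacks:
        sr, sc = stack[0].spacing_mm
        meta = {
            "name": name,
            "plane": stack[0].plane,
            "spacing_mm": [sr, sc],
            "slices": [],
        }
        if image_format == "png":
            for lm in stack:
                fname = f"slices/{name}_{lm.slice_index:03d}.png"
                iio.imwrite(
                    path / fname, np.ascontiguousarray(lm.pixels.astype(np.uint16))
                )
                meta["slices"].append(_slice_meta(lm, fname))
        else:
            fname = f"slices/{name}.nii.gz"
            vol = np.stack([lm.pixels.astype(np.int16) for lm in stack], axis=-1)
            affine = np.diag([sr, sc, 1.0, 1.0])
            nib.save(nib.Nifti1Image(vol, affine), path / fname)
            for k, lm in enumerate(stack):
                smeta = _slice_meta(lm, fname)
                smeta["volume_index"] = k
                meta["slices"].append(smeta)
        stacks_meta.append(meta)

    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "study_id": study.study_id,
        "label_dictionary": dict(study.label_dictionary.classes),
        "stacks": stacks_meta,
    }
    (path / SIDECAR_NAME).write_text(
        json.dumps(sidecar, sort_keys=True, indent=2) + "\n"
    )
    return path


def _read_slice_pixels(study_dir: Path, smeta: Mapping) -> np.ndarray:
    fname = smeta["file"]
    fpath = study_dir / fname
    if not fpath.exists():
        raise FormatError(f"slice file missing: {fname}")
    if fname.endswith((".nii", ".nii.gz")):
        vol = np.asarray(nib.load(fpath).dataobj)
        return np.asarray(vol[..., int(smeta["volume_index"])]).astype(np.int64)
    return np.asarray(iio.imread(fpath)).astype(np.int64)


def read_study(path: str | Path) -> Study:
    """Read and validate a study directory written by :func:`write_study`."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {SIDECAR_NAME} in {path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar is not valid JSON: {exc}") from exc

    dictionary = LabelDictionary(
        {name: int(lab) for name, lab in sidecar["label_dictionary"].items()}
    )
    sagittal: list[LabelMap] = []
    axial: dict[str, list[LabelMap]] = {}
    for stack_meta in sidecar["stacks"]:
        spacing = tuple(float(v) for v in stack_meta["spacing_mm"])
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValidationError("non-positive spacing in sidecar")
        plane = stack_meta["plane"]
        for smeta in stack_meta["slices"]:
            inst = smeta.get("instance_labels")
            lm = LabelMap(
                pixels=_read_slice_pixels(path, smeta),
                plane=plane,
                spacing_mm=spacing,
                segment_id=smeta.get("segment_id"),
                slice_index=int(smeta["slice_index"]),
                instance_labels={int(k): v for k, v in inst.items()} if inst else None,
            )
            if plane == "sagittal":
                sagittal.append(lm)
            else:
                axial.setdefault(lm.segment_id, []).append(lm)
    sagittal.sort(key=lambda lm: lm.slice_index)
    for stack in axial.values():
        stack.sort(key=lambda lm: lm.slice_index)
    return Study(
        study_id=sidecar["study_id"],
        sagittal_stack=sagittal,
        axial_stacks=axial,
        label_dictionary=dictionary,
    )


def readings_to_frame(readings: Mapping[str, ReferenceReading]) -> pd.DataFrame:
    """Long-format table of the *positive* findings of several readings."""
    rows = []
    for sid in sorted(readings):
        r = readings[sid]
        for seg in r.segments:
            for path in PATHOLOGIES:
                if r.get(seg, path):
                    rows.append(
                        {
                            "study_id": sid,
                            "segment_id": seg,
                            "pathology": path,
                            "present": 1,
                            "grade": r.grades.get(seg, "")
                            if path == "spondylolisthesis"
                            else "",
                        }
                    )
    return pd.DataFrame(
        rows, columns=["study_id", "segment_id", "pathology", "present", "grade"]
    )


def frame_to_readings(df: pd.DataFrame) -> dict[str, ReferenceReading]:
    readings: dict[str, ReferenceReading] = {}
    seen: set[tuple] = set()
    for row in df.itertuples(index=False):
        path = str(row.pathology)
        if path not in PATHOLOGIES:
            raise ValidationError(f"unknown pathology name {path!r}")
        seg = str(row.segment_id)
        if seg not in SEGMENTS:
            raise ValidationError(f"unknown segment_id {seg!r}")
        sid = str(row.study_id)
        present = bool(int(row.present))
        key = (sid, seg, path)
        if key in seen:
            raise ValidationError(f"duplicate row for {key}")
        seen.add(key)
        reading = readings.setdefault(sid, ReferenceReading(study_id=sid))
        grade = getattr(row, "grade", "")
        grade_val = None
        if grade not in ("", None) and not (isinstance(grade, float) and np.isnan(grade)):
            grade_val = int(float(grade))
        reading.set(seg, path, present, grade=grade_val)
    return readings


def read_reference(path: str | Path) -> dict[str, ReferenceReading]:
    """Read a reference-reading (or prediction) CSV into per-study readings."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"reference table not found: {path}")
    df = pd.read_csv(path, dtype={"grade": "object"}, keep_default_na=False)
    required = {"study_id", "segment_id", "pathology", "present"}
    if not required.issubset(df.columns):
        raise FormatError(f"reference CSV must have columns {sorted(required)}")
    return frame_to_readings(df)


def write_reference(readings: Mapping[str, ReferenceReading], path: str | Path) -> Path:
    path = Path(path)
    readings_to_frame(readings).to_csv(path, index=False)
    return path
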