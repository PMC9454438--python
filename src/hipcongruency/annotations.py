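"""Read and write LabelMe-style polygon annotation JSON and measurement CSVs.

Only the ``shapes[].label / points / shape_type`` subset of the LabelMe
schema is consumed; embedded ``imageData`` is ignored (annotations, not
pixels, drive all computation). The label vocabulary is fixed:

    acetabulum_L / acetabulum_R    polygon, acetabular coverage area
    femoral_head_L / femoral_head_R polygon, proximal femur head
    fhc_L / fhc_R                  point, femoral head center
    rim_L / rim_R                  point, cranial effective acetabular rim

One file may carry one or both sides. Unknown labels are skipped with a
warning; a side that appears at all but lacks either polygon is an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from hipcongruency.errors import (
    IncompleteSideError,
    InvalidAnnotationError,
)
from hipcongruency.geometry import Point2D, Polygon2D
from hipcongruency.metrics import FCI_GRADES, HipAnnotation

_SIDE_SUFFIX = {"L": "left", "R": "right"}
_POLYGON_LABELS = {f"{base}_{s}" for base in ("acetabulum", "femoral_head") for s in "LR"}
_POINT_LABELS = {f"{base}_{s}" for base in ("fhc", "rim") for s in "LR"}
KNOWN_LABELS = _POLYGON_LABELS | _POINT_LABELS

#: measurement CSV column order
MEASUREMENT_COLUMNS = [
    "dog_id",
    "side",
    "examiner",
    "session",
    "aa_px2",
    "aaofh_px2",
    "hci",
    "norberg_deg",
    "fci_grade",
]
_REQUIRED_COLUMNS = ["dog_id", "side", "aa_px2", "aaofh_px2", "hci"]


class UnknownLabelWarning(UserWarning):
    """A shape carries a label outside the controlled vocabulary."""


@dataclass
class MeasurementRecord:
    """One measured hip as a flat table row."""

    dog_id: str
    side: str
    aa_px2: float
    aaofh_px2: float
    hci: float
    examiner: Optional[str] = None
    session: Optional[str] = None
    norberg_deg: Optional[float] = None
    fci_grade: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.hci <= 1.0:
            raise InvalidAnnotationError(f"hci {self.hci} outside [0, 1] for {self.dog_id}/{self.side}")
        if self.fci_grade is not None and self.fci_grade not in FCI_GRADES:
            raise InvalidAnnotationError(f"unknown fci_grade {self.fci_grade!r}")


def read_annotation(source: Union[str, Path, dict]) -> list[HipAnnotation]:
    """Parse one LabelMe-style JSON document into per-side hip annotations.

    ``source`` may be a path or an already-decoded JSON dict. Sides are
    paired from the label suffixes; point landmarks are attached when
    present. A side with a missing acetabulum or femoral head raises
    :class:`IncompleteSideError` naming what is absent.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        doc = json.loads(path.read_text())
        default_id = path.stem
    else:
        doc = source
        default_id = "unknown"
    if not isinstance(doc, dict) or "shapes" not in doc:
        raise InvalidAnnotationError("document has no 'shapes' array")
    dog_id = str(Path(str(doc.get("imagePath") or default_id)).stem) or default_id

    polygons: dict[str, Polygon2D] = {}
    points: dict[str, Point2D] = {}
    for shape in doc["shapes"]:
        label = shape.get("label")
        pts = shape.get("points", [])
        if label not in KNOWN_LABELS:
            warnings.warn(f"skipping unknown label {label!r} in {dog_id}", UnknownLabelWarning)
            continue
        if label in _POLYGON_LABELS:
            if len(pts) < 3:
                raise InvalidAnnotationError(
                    f"shape {label!r} in {dog_id} has {len(pts)} points; a polygon needs >= 3"
                )
            try:
                polygons[label] = Polygon2D([(p[0], p[1]) for p in pts])
            except Exception as exc:
                raise InvalidAnnotationError(f"shape {label!r} in {dog_id}: {exc}") from exc
        else:
            if len(pts) != 1:
                raise InvalidAnnotationError(
                    f"point shape {label!r} in {dog_id} must have exactly 1 point, got {len(pts)}"
                )
            points[label] = Point2D(pts[0][0], pts[0][1])

    annotations: list[HipAnnotation] = []
    for suffix, side in _SIDE_SUFFIX.items():
        present = [lbl for lbl in list(polygons) + list(points) if lbl.endswith(f"_{suffix}")]
        if not present:
            continue
        missing = [
            base for base in ("acetabulum", "femoral_head") if f"{base}_{suffix}" not in polygons
        ]
        if missing:
            raise IncompleteSideError(
                f"{dog_id} side {side}: missing {', '.join(missing)} "
                f"(found {', '.join(sorted(present))})"
            )
        annotations.append(
            HipAnnotation(
                dog_id=dog_id,
                side=side,
                acetabulum=polygons[f"acetabulum_{suffix}"],
                femoral_head=polygons[f"femoral_head_{suffix}"],
                femoral_head_center=points.get(f"fhc_{suffix}"),
                cranial_rim=points.get(f"rim_{suffix}"),
            )
        )
    return annotations


def write_annotation(
    annotations: list[HipAnnotation],
    image_height: int = 1024,
    image_width: int = 1024,
    image_identifier: Optional[str] = None,
) -> dict:
    """Serialize hip annotations back to a LabelMe-style JSON dict.

    Round-trips losslessly through :func:`read_annotation`.
    """
    if image_identifier is None:
        image_identifier = annotations[0].dog_id if annotations else "empty"
    shapes = []
    for ann in annotations:
        suffix = "L" if ann.side == "left" else "R"
        for base, poly in (("acetabulum", ann.acetabulum), ("femoral_head", ann.femoral_head)):
            shapes.append(
                {
                    "label": f"{base}_{suffix}",
                    "points": [[float(x), float(y)] for x, y in poly.coords],
                    "shape_type": "polygon",
                }
            )
        for base, pt in (("fhc", ann.femoral_head_center), ("rim", ann.cranial_rim)):
            if pt is not None:
                shapes.append(
                    {
                        "label": f"{base}_{suffix}",
                        "points": [[float(pt.x), float(pt.y)]],
                        "shape_type": "point",
                    }
                )
    return {
        "version": "4.5.13",
        "flags": {},
        "shapes": shapes,
        "imagePath": f"{image_identifier}.png",
        "imageData": None,
        "imageHeight": image_height,
        "imageWidth": image_width,
    }


def write_annotation_file(
    annotations: list[HipAnnotation], path: Union[str, Path], **meta
) -> None:
    Path(path).write_text(json.dumps(write_annotation(annotations, **meta), indent=1))


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "dog_id": r.dog_id,
                "side": r.side,
                "examiner": r.examiner,
                "session": r.session,
                "aa_px2": r.aa_px2,
                "aaofh_px2": r.aaofh_px2,
                "hci": r.hci,
                "norberg_deg": r.norberg_deg,
                "fci_grade": r.fci_grade,
            }
        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements(records: list[MeasurementRecord], path: Union[str, Path]) -> None:
    """Write measurement records to a header-first CSV, one row per hip.

    Floats are serialized with ``repr`` precision so the decimal
    representation round-trips exactly.
    """
    records_to_frame(records).to_csv(path, index=False)


def read_measurements(path: Union[str, Path]) -> list[MeasurementRecord]:
    """Read a measurements CSV, enforcing column names and value invariants."""
    df = pd.read_csv(path, dtype={"examiner": str, "session": str, "dog_id": str})
    unknown = [c for c in df.columns if c not in MEASUREMENT_COLUMNS]
    if unknown:
        raise InvalidAnnotationError(f"unknown column(s) in measurements CSV: {', '.join(unknown)}")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidAnnotationError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key, cast=str):
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and pd.isna(v)) or pd.isna(v) else cast(v)

        records.append(
            MeasurementRecord(
                dog_id=str(d["dog_id"]),
                side=str(d["side"]),
                aa_px2=float(d["aa_px2"]),
                aaofh_px2=float(d["aaofh_px2"]),
                hci=float(d["hci"]),
                examiner=opt("examiner"),
                session=opt("session"),
                norberg_deg=opt("norberg_deg", float),
                fci_grade=opt("fci_grade"),
            )
        )
    return records
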