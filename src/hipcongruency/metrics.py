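"""Per-hip measurement constructs: Hip Congruency Index and Norberg angle.

The Hip Congruency Index (HCI) is the fraction of the acetabular coverage
area (AA) occupied by the femoral head: HCI = AAOFH / AA, where AAOFH is
the overlap area between the acetabular and femoral-head polygons. Being a
ratio of areas measured on the same projection, it is invariant to
radiographic magnification and to rigid motion of the annotation frame.

The Norberg angle is measured at a femoral head center between the ray
toward the contralateral femoral head center and the ray toward the
cranial effective acetabular rim; it is reported as an unsigned magnitude
in [0, 180] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from hipcongruency.errors import DegenerateAnnotationError, DegenerateLandmarkError
from hipcongruency.geometry import Point2D, Polygon2D, intersection_area, polygon_area

SIDES = ("left", "right")
FCI_GRADES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class HciMeasurement:
    """Acetabular area, overlap area, and their ratio for one hip."""

    aa: float  # acetabular area, square pixels
    aaofh: float  # acetabular area occupied by the femoral head, square pixels
    hci: float  # aaofh / aa, dimensionless in [0, 1]

    def __post_init__(self) -> None:
        if not self.aa > 0:
            raise DegenerateAnnotationError(f"acetabular area must be positive, got {self.aa}")
        if not 0.0 <= self.aaofh <= self.aa * (1 + 1e-12):
            raise DegenerateAnnotationError(
                f"overlap area {self.aaofh} outside [0, acetabular area {self.aa}]"
            )


@dataclass(frozen=True)
class NorbergMeasurement:
    """Norberg angle in degrees, unsigned, within [0, 180]."""

    angle_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 180.0:
            raise DegenerateLandmarkError(f"angle {self.angle_deg} outside [0, 180]")


@dataclass
class HipAnnotation:
    """One hip's polygon annotations plus optional landmarks and metadata."""

    dog_id: str
    side: str
    acetabulum: Polygon2D
    femoral_head: Polygon2D
    femoral_head_center: Optional[Point2D] = None
    cranial_rim: Optional[Point2D] = None
    examiner: Optional[str] = None
    session: Optional[str] = None
    fci_grade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.fci_grade is not None and self.fci_grade not in FCI_GRADES:
            raise ValueError(f"fci_grade must be one of {FCI_GRADES}, got {self.fci_grade!r}")


def compute_hci(acetabulum: Polygon2D, femoral_head: Polygon2D) -> HciMeasurement:
    """Measure AA, AAOFH and their ratio HCI for one hip.

    Only the overlap between the two polygons counts toward AAOFH; the
    femoral head routinely extends beyond the acetabular coverage area.
    """
    aa = polygon_area(acetabulum)
    if aa <= 0.0:
        raise DegenerateAnnotationError("acetabulum polygon has zero area")
    aaofh = intersection_area(acetabulum, femoral_head)
    aaofh = min(max(aaofh, 0.0), aa)  # clamp float noise at containment
    return HciMeasurement(aa=aa, aaofh=aaofh, hci=aaofh / aa)


def norberg_angle(
    own_center: Point2D, contralateral_center: Point2D, cranial_rim: Point2D
) -> NorbergMeasurement:
    """Angle at ``own_center`` between the rays to the contralateral femoral
    head center and to the cranial effective acetabular rim, in degrees."""
    ux, uy = contralateral_center.x - own_center.x, contralateral_center.y - own_center.y
    vx, vy = cranial_rim.x - own_center.x, cranial_rim.y - own_center.y
    nu = math.hypot(ux, uy)
    nv = math.hypot(vx, vy)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateLandmarkError("coincident landmark points: angle undefined")
    cosang = (ux * vx + uy * vy) / (nu * nv)
    return NorbergMeasurement(angle_deg=math.degrees(math.acos(max(-1.0, min(1.0, cosang)))))


def measure_hip(
    annotation: HipAnnotation, contralateral_center: Optional[Point2D] = None
) -> tuple[HciMeasurement, Optional[NorbergMeasurement]]:
    """Measure one annotated hip.

    HCI is always computed. The Norberg angle is computed only when the
    annotation carries both landmarks and the caller supplies the
    contralateral femoral head center (pairing of left/right hips is the
    caller's responsibility).
    """
    hci = compute_hci(annotation.acetabulum, annotation.femoral_head)
    na = None
    if (
        contralateral_center is not None
        and annotation.femoral_head_center is not None
        and annotation.cranial_rim is not None
    ):
        na = norberg_angle(annotation.femoral_head_center, contralateral_center, annotation.cranial_rim)
    return hci, na
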