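"""Synthetic hip annotations with known ground-truth congruency.

The generative model is deliberately minimal: the acetabular coverage
region is a "cup" -- a disc of radius R intersected with the half-plane
that removes a lateral-facing opening of a given half-angle -- and the
femoral head is a disc of radius r (< R) whose center is displaced
laterally by d pixels from the acetabular center. Displacement is the
single subluxation axis: overlap with the cup, and hence the congruency
index, decreases monotonically as d grows, reaching zero at dislocation.

Ground-truth HCI is computed with the brute-force grid oracle for the
overlap (numerator) against the exact closed-form cup area (denominator),
so it never shares code with the polygon-clipping measurement path.

Examiner/session variability is modelled as independent isotropic Gaussian
jitter on every polygon vertex. Cohort generation is reproducible: every
hip and every replicate draws from its own RNG substream derived
deterministically from the cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from hipcongruency.annotations import write_annotation_file
from hipcongruency.errors import GenerationError, ParameterError
from hipcongruency.geometry import (
    CircleSpec,
    Point2D,
    Polygon2D,
    circle_polygon,
    grid_overlap_oracle,
)
from hipcongruency.metrics import HipAnnotation

DEFAULT_GRADE_DISPLACEMENT = {"A": 0.05, "B": 0.15, "C": 0.25, "D": 0.40, "E": 0.60}


@dataclass(frozen=True)
class HipShapeParams:
    """Parameters of one synthetic hip."""

    acetabular_radius: float = 100.0
    femoral_radius: float = 85.0
    lateral_displacement: float = 0.0
    opening_halfangle: float = 60.0  # degrees, in (0, 90]
    n_vertices: int = 128
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.femoral_radius < self.acetabular_radius:
            raise ParameterError(
                f"need 0 < femoral radius < acetabular radius, got "
                f"r={self.femoral_radius}, R={self.acetabular_radius}"
            )
        if self.lateral_displacement < 0:
            raise ParameterError(f"displacement must be >= 0, got {self.lateral_displacement}")
        if not 0 < self.opening_halfangle <= 90:
            raise ParameterError(f"opening_halfangle must be in (0, 90], got {self.opening_halfangle}")
        if self.n_vertices < 64:
            raise ParameterError(f"n_vertices must be >= 64, got {self.n_vertices}")
        if not self.pixel_scale > 0:
            raise ParameterError(f"pixel_scale must be > 0, got {self.pixel_scale}")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth for one synthetic hip."""

    true_hci: float
    true_displacement: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_hci <= 1.0:
            raise ParameterError(f"true_hci {self.true_hci} outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort: grade mix, subluxation levels, noise."""

    grade_counts: dict[str, int] = field(
        default_factory=lambda: {g: 20 for g in "ABCDE"}
    )
    grade_disp_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_DISPLACEMENT)
    )  # mean displacement as a fraction of the acetabular radius
    grade_disp_sd: float = 0.05
    jitter_sd: float = 1.0  # pixels, per vertex, per replicate
    n_examiners: int = 2
    n_sessions: int = 2
    seed: int = 0
    shape: HipShapeParams = field(default_factory=HipShapeParams)
    oracle_resolution: int = 2000

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.grade_counts.values()):
            raise ParameterError("grade counts must be >= 0")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")
        if self.n_examiners < 1 or self.n_sessions < 1:
            raise ParameterError("need at least one examiner and one session")


@dataclass
class CohortHip:
    """One synthetic hip: clean annotation, truth, grade, noisy replicates."""

    dog_id: str
    side: str
    grade: str
    annotation: HipAnnotation  # noise-free
    truth: GroundTruth
    replicates: dict[tuple[str, str], HipAnnotation]  # (examiner, session) -> jittered


def cup_area(acetabular_radius: float, opening_halfangle_deg: float) -> float:
    """Closed-form area of the cup region (disc minus the opening segment)."""
    theta = math.radians(opening_halfangle_deg)
    R = acetabular_radius
    return R * R * (math.pi - theta + math.sin(theta) * math.cos(theta))


def _lateral_sign(side: str) -> float:
    # On a ventrodorsal image the dog's right hip is on the image left, so
    # "away from the midline" is -x for the right side and +x for the left.
    return -1.0 if side == "right" else 1.0


def cup_polygon(
    center: Point2D, radius: float, opening_halfangle_deg: float, n_vertices: int, lateral_sign: float
) -> Polygon2D:
    """Discretized cup: arc spanning the closed part of the circle plus the
    straight chord across the opening."""
    theta = math.radians(opening_halfangle_deg)
    phi = np.linspace(theta, 2.0 * math.pi - theta, n_vertices)
    xy = np.column_stack(
        (center.x + radius * lateral_sign * np.cos(phi), center.y + radius * np.sin(phi))
    )
    return Polygon2D(xy)


def make_hip(
    params: HipShapeParams,
    center: Point2D = Point2D(256.0, 256.0),
    side: str = "right",
    dog_id: str = "synthetic",
    oracle_resolution: int = 2000,
) -> tuple[HipAnnotation, GroundTruth]:
    """Build one synthetic hip annotation and its ground truth.

    The femoral head center is displaced laterally (away from the image
    midline) by ``lateral_displacement``; landmarks are the head center and
    the cranial edge of the cup opening. ``true_hci`` comes from the grid
    oracle, independent of the polygon-clipping measurement path.
    """
    s = params.pixel_scale
    R = params.acetabular_radius * s
    r = params.femoral_radius * s
    d = params.lateral_displacement * s
    lat = _lateral_sign(side)
    theta = math.radians(params.opening_halfangle)
    head_center = Point2D(center.x + lat * d, center.y)

    acet = cup_polygon(center, R, params.opening_halfangle, params.n_vertices, lat)
    head = circle_polygon(CircleSpec(head_center, r), params.n_vertices)
    # cranial edge of the opening (cranial is -y in image coordinates)
    rim = Point2D(center.x + lat * R * math.cos(theta), center.y - R * math.sin(theta))

    chord = R * math.cos(theta)

    def cup_region(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        dx, dy = X - center.x, Y - center.y
        return (dx * dx + dy * dy <= R * R) & (lat * dx <= chord)

    def head_region(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        dx, dy = X - head_center.x, Y - head_center.y
        return dx * dx + dy * dy <= r * r

    pad = 2.0
    bbox = (
        min(center.x - R, head_center.x - r) - pad,
        center.y - max(R, r) - pad,
        max(center.x + R, head_center.x + r) + pad,
        center.y + max(R, r) + pad,
    )
    overlap = grid_overlap_oracle(cup_region, head_region, bbox, oracle_resolution).area
    true_hci = min(max(overlap / cup_area(R, params.opening_halfangle), 0.0), 1.0)

    annotation = HipAnnotation(
        dog_id=dog_id,
        side=side,
        acetabulum=acet,
        femoral_head=head,
        femoral_head_center=head_center,
        cranial_rim=rim,
    )
    return annotation, GroundTruth(true_hci=true_hci, true_displacement=d)


def jitter_polygon(p: Polygon2D, sd: float, rng: np.random.Generator) -> Polygon2D:
    """Perturb every vertex by independent isotropic Gaussian noise.

    The result is re-validated; when jitter makes the ring self-intersect
    the draw is repeated (at most 100 times) before giving up.
    """
    if sd < 0:
        raise ParameterError(f"jitter sd must be >= 0, got {sd}")
    if sd == 0:
        return p
    coords = p.coords
    for _ in range(100):
        try:
            return Polygon2D(coords + rng.normal(0.0, sd, size=coords.shape))
        except Exception:
            continue
    raise GenerationError(f"could not produce a simple polygon after 100 jitter retries (sd={sd})")


def make_cohort(spec: CohortSpec) -> list[CohortHip]:
    """Generate a graded cohort of synthetic hips with examiner/session noise.

    Per-grade lateral displacements are drawn (truncated at zero) from the
    grade's displacement distribution. Hips are paired two-per-dog
    (left/right) so Norberg landmarks can be used downstream. The same seed
    always yields a byte-identical cohort.
    """
    hips_plan: list[str] = []
    for grade in sorted(spec.grade_counts):
        hips_plan.extend([grade] * spec.grade_counts[grade])
    root = np.random.default_rng([spec.seed, len(hips_plan)])
    order = root.permutation(len(hips_plan))
    hips_plan = [hips_plan[i] for i in order]

    R = spec.shape.acetabular_radius
    hip_spacing = 2.0 * R * spec.shape.pixel_scale + 60.0
    cohort: list[CohortHip] = []
    for idx, grade in enumerate(hips_plan):
        dog_no = idx // 2
        side = "right" if idx % 2 == 0 else "left"
        dog_id = f"dog{dog_no:04d}"
        rng = np.random.default_rng([spec.seed, idx])
        frac = max(rng.normal(spec.grade_disp_mean[grade], spec.grade_disp_sd), 0.0)
        params = replace(spec.shape, lateral_displacement=frac * R)
        cx = 256.0 if side == "right" else 256.0 + hip_spacing
        ann, truth = make_hip(
            params,
            center=Point2D(cx, 256.0),
            side=side,
            dog_id=dog_id,
            oracle_resolution=spec.oracle_resolution,
        )
        ann.fci_grade = grade
        replicates: dict[tuple[str, str], HipAnnotation] = {}
        for e in range(1, spec.n_examiners + 1):
            for ses in range(1, spec.n_sessions + 1):
                jrng = np.random.default_rng([spec.seed, idx, e, ses])
                replicates[(f"E{e}", f"S{ses}")] = HipAnnotation(
                    dog_id=dog_id,
                    side=side,
                    acetabulum=jitter_polygon(ann.acetabulum, spec.jitter_sd, jrng),
                    femoral_head=jitter_polygon(ann.femoral_head, spec.jitter_sd, jrng),
                    femoral_head_center=ann.femoral_head_center,
                    cranial_rim=ann.cranial_rim,
                    examiner=f"E{e}",
                    session=f"S{ses}",
                    fci_grade=grade,
                )
        cohort.append(
            CohortHip(
                dog_id=dog_id,
                side=side,
                grade=grade,
                annotation=ann,
                truth=truth,
                replicates=replicates,
            )
        )
    return cohort


def write_cohort(cohort: list[CohortHip], outdir: str | Path) -> None:
    """Write a cohort to disk: one annotation JSON per dog per (examiner,
    session) replicate, plus ``ground_truth.csv``.

    File names follow ``<dog_id>__E<k>S<m>.json``; the measurement command
    recovers examiner and session from this suffix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_dog: dict[str, list[CohortHip]] = {}
    for hip in cohort:
        by_dog.setdefault(hip.dog_id, []).append(hip)
    for dog_id in sorted(by_dog):
        hips = by_dog[dog_id]
        keys = sorted(hips[0].replicates)
        for key in keys:
            e, ses = key
            anns = [h.replicates[key] for h in hips]
            write_annotation_file(
                anns, outdir / f"{dog_id}__{e}{ses}.json", image_identifier=f"{dog_id}__{e}{ses}"
            )
    lines = ["dog_id,side,true_hci,true_displacement,fci_grade"]
    for hip in cohort:
        lines.append(
            f"{hip.dog_id},{hip.side},{hip.truth.true_hci!r},{hip.truth.true_displacement!r},{hip.grade}"
        )
    (outdir / "ground_truth.csv").write_text("\n".join(lines) + "\n")
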