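"""Single-slice lesion geometry.

Each lesion is annotated once, as a closed freehand contour on the axial
slice where it appears largest.  From that 2D polygon we derive an
approximate 3D volume:

    volume = (2/3) * area * minor_axis

where ``area`` is the enclosed in-plane area and ``minor_axis`` is the
shorter principal axis of the region, defined as ``4 * sqrt(lambda_minor)``
with ``lambda_minor`` the smaller eigenvalue of the covariance of the
uniform distribution over the polygon interior.  For a disk of radius r
this yields exactly the sphere volume (4/3)*pi*r^3, which motivates the
2/3 prefactor.

All coordinates are in millimetres; areas in mm^2, volumes in mm^3.
Conversion to cm^3 happens only at patient-level aggregation
(:func:`mmrd_burden.biomarkers.total_volume`).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OrganLabel",
    "Timepoint",
    "Polygon2D",
    "ShapeFeatures",
    "LesionAnnotation",
    "MeasuredLesion",
    "polygon_area",
    "principal_axis_lengths",
    "shape_features",
    "lesion_volume",
    "equivalent_sphere_diameter",
    "measure_lesions",
    "filter_lesions",
]


class OrganLabel(str, enum.Enum):
    """The 16 anatomical labels available to the annotating radiologist."""

    HEART = "heart"
    LUNG = "lung"
    LIVER = "liver"
    LYMPH_NODE = "lymph_node"
    BONE = "bone"
    SPLEEN = "spleen"
    KIDNEY = "kidney"
    CARCINOSIS = "carcinosis"
    OVARY = "ovary"
    PANCREAS = "pancreas"
    SKIN_SOFT_TISSUE = "skin_soft_tissue"
    ADRENAL = "adrenal"
    BRAIN = "brain"
    MUSCLE = "muscle"
    BOWELS = "bowels"
    OTHER = "other"


class Timepoint(str, enum.Enum):
    """Imaging timepoint: pre-treatment baseline or first evaluation."""

    BASELINE = "baseline"
    EVAL1 = "eval1"


@dataclass(frozen=True)
class Polygon2D:
    """A closed 2D contour in mm on one axial slice.

    The last vertex implicitly connects back to the first.  Consecutive
    duplicate vertices (including a repeated closing vertex) are collapsed
    on construction.  Simplicity (no self-intersection) is assumed, not
    enforced; degenerate polygons are allowed and yield zero features.
    """

    vertices: np.ndarray = field(repr=False)

    def __init__(self, vertices: Sequence[Sequence[float]] | np.ndarray):
        arr = np.asarray(vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) mm points")
        # collapse consecutive duplicates, including last == first
        keep = np.ones(len(arr), dtype=bool)
        keep[1:] = np.any(arr[1:] != arr[:-1], axis=1)
        arr = arr[keep]
        if len(arr) > 1 and np.all(arr[0] == arr[-1]):
            arr = arr[:-1]
        if len(arr) < 3:
            raise ValueError("a polygon needs at least 3 distinct vertices")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "vertices", arr)

    def __len__(self) -> int:
        return len(self.vertices)

    def translated(self, dx: float, dy: float) -> "Polygon2D":
        return Polygon2D(self.vertices + np.array([dx, dy]))

    def scaled(self, s: float) -> "Polygon2D":
        return Polygon2D(self.vertices * s)

    def rotated(self, angle_rad: float) -> "Polygon2D":
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return Polygon2D(self.vertices @ rot.T)


@dataclass(frozen=True)
class ShapeFeatures:
    """In-plane area (mm^2), principal axes (mm) and approximate volume (mm^3)."""

    surface: float
    major_axis: float
    minor_axis: float
    volume: float


@dataclass(frozen=True)
class LesionAnnotation:
    """One annotated lesion: contour plus organ label and identity."""

    lesion_id: str
    patient_id: str
    timepoint: Timepoint
    organ: OrganLabel
    polygon: Polygon2D


@dataclass(frozen=True)
class MeasuredLesion:
    """A lesion annotation with its computed shape features."""

    annotation: LesionAnnotation
    features: ShapeFeatures


def _edge_cross(v: np.ndarray) -> np.ndarray:
    """Per-edge cross products x_i*y_{i+1} - x_{i+1}*y_i (wrapping)."""
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return x * yn - xn * y


def polygon_area(polygon: Polygon2D) -> float:
    """Enclosed area in mm^2.

    Computed as the absolute value of the signed sum of triangle-fan areas
    about the centroid, which telescopes to the shoelace formula and is
    exact for any simple polygon regardless of convexity or fan origin.
    """
    return abs(float(_edge_cross(polygon.vertices).sum())) / 2.0


def _interior_covariance(polygon: Polygon2D) -> tuple[float, np.ndarray]:
    """(area, 2x2 covariance of the uniform distribution over the interior).

    Uses the exact Green's-theorem moment integrals of the polygon, so the
    result is resolution-independent (no rasterization).
    """
    v = polygon.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a_signed = cross.sum() / 2.0
    if abs(a_signed) < 1e-12:
        return 0.0, np.zeros((2, 2))
    cx = ((x + xn) * cross).sum() / (6.0 * a_signed)
    cy = ((y + yn) * cross).sum() / (6.0 * a_signed)
    # raw second moments over the interior
    ixx = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    iyy = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    ixy = ((2 * x * y + x * yn + xn * y + 2 * xn * yn) * cross).sum() / 24.0
    cov = np.array(
        [
            [ixx / a_signed - cx * cx, ixy / a_signed - cx * cy],
            [ixy / a_signed - cx * cy, iyy / a_signed - cy * cy],
        ]
    )
    return abs(a_signed), cov


def principal_axis_lengths(polygon: Polygon2D) -> tuple[float, float]:
    """(major_axis, minor_axis) in mm.

    The axes are ``4 * sqrt(lambda)`` for the eigenvalues of the interior
    covariance; for an ellipse with semi-axes (a, b) this recovers the full
    axis lengths (2a, 2b).  Degenerate polygons return (0, 0).
    """
    area, cov = _interior_covariance(polygon)
    if area == 0.0:
        return 0.0, 0.0
    lam = np.linalg.eigvalsh(cov)
    lam = np.clip(lam, 0.0, None)
    minor, major = 4.0 * np.sqrt(lam)
    return float(major), float(minor)


def lesion_volume(surface: float, minor_axis: float) -> float:
    """Approximate 3D volume (mm^3) of a single-slice lesion: (2/3)*area*minor."""
    if surface < 0 or minor_axis < 0:
        raise ValueError("surface and minor_axis must be non-negative")
    return (2.0 / 3.0) * surface * minor_axis


def shape_features(polygon: Polygon2D) -> ShapeFeatures:
    """Compute area, principal axes and approximate volume for one contour."""
    area = polygon_area(polygon)
    major, minor = principal_axis_lengths(polygon)
    return ShapeFeatures(
        surface=area,
        major_axis=major,
        minor_axis=minor,
        volume=lesion_volume(area, minor),
    )


def equivalent_sphere_diameter(volume_cm3: float) -> float:
    """Diameter (cm) of the sphere with the given volume (cm^3)."""
    if volume_cm3 < 0:
        raise ValueError("volume must be non-negative")
    return 2.0 * (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def measure_lesions(lesions: Iterable[LesionAnnotation]) -> list[MeasuredLesion]:
    """Attach shape features to each annotation, in order."""
    return [MeasuredLesion(a, shape_features(a.polygon)) for a in lesions]


# Inclusion rules used at annotation time: a lymph node counts as a lesion
# only if its short axis exceeds 10 mm; pulmonary micronodules count only
# above 3 mm.  Thresholds are strict (> retained, <= dropped).
LYMPH_NODE_MIN_MINOR_MM = 10.0
LUNG_MIN_MAJOR_MM = 3.0


def filter_lesions(lesions: Sequence[MeasuredLesion]) -> list[MeasuredLesion]:
    """Apply lesion-inclusion rules, preserving order.

    Drops lymph-node lesions with minor axis <= 10 mm and lung lesions with
    major axis <= 3 mm.  Zero-area (degenerate) contours are also removed,
    with a logged warning, since every downstream feature would be zero.
    """
    kept: list[MeasuredLesion] = []
    for lesion in lesions:
        f = lesion.features
        a = lesion.annotation
        if f.surface == 0.0:
            logger.warning(
                "dropping degenerate zero-area lesion %s/%s/%s",
                a.patient_id,
                a.timepoint.value,
                a.lesion_id,
            )
            continue
        if a.organ is OrganLabel.LYMPH_NODE and f.minor_axis <= LYMPH_NODE_MIN_MINOR_MM:
            continue
        if a.organ is OrganLabel.LUNG and f.major_axis <= LUNG_MIN_MAJOR_MM:
            continue
        kept.append(lesion)
    return kept
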