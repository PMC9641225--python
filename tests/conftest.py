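"""Shared fixtures: canonical polygons, a tiny measured-lesion fixture,
and a generated cohort on disk."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mmrd_burden.geometry import (
    LesionAnnotation,
    OrganLabel,
    Polygon2D,
    Timepoint,
    measure_lesions,
)
from mmrd_burden.synthetic import CohortConfig, generate_cohort


def regular_polygon(n: int, r: float, center=(0.0, 0.0), phase: float = 0.0) -> Polygon2D:
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False) + phase
    return Polygon2D(
        np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])
    )


def ellipse_polygon(a: float, b: float, n: int = 256) -> Polygon2D:
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return Polygon2D(np.column_stack([a * np.cos(ang), b * np.sin(ang)]))


def make_lesion(
    lesion_id: str,
    organ: OrganLabel,
    polygon: Polygon2D,
    patient_id: str = "P001",
    timepoint: Timepoint = Timepoint.BASELINE,
) -> LesionAnnotation:
    return LesionAnnotation(lesion_id, patient_id, timepoint, organ, polygon)


@pytest.fixture
def filter_fixture():
    """Six measured lesions of which the inclusion rules drop exactly two:
    a lymph node with ~9 mm minor axis and a ~2.5 mm lung micronodule."""
    anns = [
        make_lesion("L1", OrganLabel.LIVER, regular_polygon(64, 12.0)),
        make_lesion("L2", OrganLabel.LYMPH_NODE, ellipse_polygon(10.0, 4.5)),  # minor 9 mm
        make_lesion("L3", OrganLabel.LUNG, regular_polygon(64, 1.25)),  # major 2.5 mm
        make_lesion("L4", OrganLabel.LYMPH_NODE, regular_polygon(64, 8.0)),  # minor 16 mm
        make_lesion("L5", OrganLabel.LUNG, regular_polygon(64, 4.0)),  # major 8 mm
        make_lesion("L6", OrganLabel.BONE, regular_polygon(64, 6.0)),
    ]
    return measure_lesions(anns)


@pytest.fixture(scope="session")
def small_cohort():
    """A default-sized synthetic cohort, generated once per session."""
    return generate_cohort(CohortConfig(seed=20260925))


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    small_cohort.write(out)
    return out
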