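"""Patient-level burden parameters, variations and concordance scores.

Five parameters summarise each patient at each timepoint:

* ``volume`` — total tumor volume (cm^3), the sum of per-lesion approximate
  3D volumes over every annotated lesion in the body;
* ``recist_sum`` — sum of RECIST 1.1 target-lesion diameters (mm), read
  from the radiologist's table, not recomputed from contours;
* ``nlr`` — neutrophil-to-lymphocyte ratio from the blood draw;
* ``n_lesions`` — number of retained lesions;
* ``n_organs`` — number of distinct organ labels among them.

Between baseline and first evaluation each parameter has a percent
variation (E1 - BL)/BL * 100, binarized to increase (>0) vs decrease (<0).
The concordance score of two parameters is the three-way category of their
joint directions: mutual increase, mutual decrease, or discordant.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import MeasuredLesion, OrganLabel

logger = logging.getLogger(__name__)

__all__ = [
    "PARAMETERS",
    "BloodCounts",
    "ParameterSet",
    "Direction",
    "ConcordanceCategory",
    "Cutoffs",
    "BiomarkerRow",
    "total_volume",
    "organ_count",
    "compute_nlr",
    "variation",
    "direction",
    "binarize_baseline",
    "median_integer_cutoff",
    "concordance_category",
    "build_biomarker_table",
]

#: canonical parameter order used everywhere (tables, reports, screens)
PARAMETERS = ("volume", "recist_sum", "nlr", "n_lesions", "n_organs")


@dataclass(frozen=True)
class BloodCounts:
    """Absolute neutrophil and lymphocyte counts, 10^9 cells/L."""

    neutrophils: float
    lymphocytes: float


@dataclass(frozen=True)
class ParameterSet:
    """The five burden parameters at one timepoint."""

    volume: float  # cm^3
    recist_sum: float  # mm
    nlr: float
    n_lesions: int
    n_organs: int

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMETERS}


class Direction(str, enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"


class ConcordanceCategory(str, enum.Enum):
    MUTUAL_INCREASE = "mutual_increase"
    MUTUAL_DECREASE = "mutual_decrease"
    DISCORDANT = "discordant"


@dataclass(frozen=True)
class Cutoffs:
    """Baseline binarization cutoffs.

    Defaults are the study-reported medians (volume 90 cm^3, 3 organs,
    10 lesions, 55 mm RECIST sum) and the literature NLR cutoff of 5.
    """

    volume: float = 90.0  # cm^3
    recist_sum: float = 55.0  # mm
    nlr: float = 5.0
    n_lesions: float = 10.0
    n_organs: float = 3.0

    def for_parameter(self, name: str) -> float:
        if name not in PARAMETERS:
            raise KeyError(f"unknown parameter {name!r}")
        return getattr(self, name)


@dataclass
class BiomarkerRow:
    """All derived quantities for one patient.

    ``variation``/``direction_of`` entries are ``None`` where the baseline
    parameter is zero (variation undefined; the patient is excluded from
    that parameter's variation analysis).
    """

    patient_id: str
    baseline: ParameterSet
    eval1: ParameterSet
    variation: dict[str, float | None] = field(default_factory=dict)
    baseline_class: dict[str, str] = field(default_factory=dict)
    direction_of: dict[str, Direction | None] = field(default_factory=dict)
    concordance_vol_nlr: ConcordanceCategory | None = None
    concordance_recist_nlr: ConcordanceCategory | None = None


def total_volume(lesions: Iterable[MeasuredLesion]) -> float:
    """Total tumor volume in cm^3: sum of per-lesion volumes (mm^3) / 1000."""
    return sum(l.features.volume for l in lesions) / 1000.0


def organ_count(lesions: Iterable[MeasuredLesion]) -> int:
    """Number of distinct organ labels among the lesions."""
    return len({l.annotation.organ for l in lesions})


def compute_nlr(blood: BloodCounts, patient_id: str = "?") -> float:
    """Neutrophil/lymphocyte ratio; undefined when lymphocytes <= 0."""
    if blood.lymphocytes <= 0:
        raise ValueError(
            f"NLR undefined for patient {patient_id}: "
            f"lymphocyte count {blood.lymphocytes} <= 0"
        )
    return blood.neutrophils / blood.lymphocytes


def variation(baseline_value: float, eval1_value: float) -> float | None:
    """Percent change (E1 - BL)/BL * 100; None when the baseline is zero."""
    if baseline_value == 0:
        return None
    return (eval1_value - baseline_value) / baseline_value * 100.0


def direction(variation_percent: float, warn: bool = True) -> Direction:
    """Increase iff variation > 0; exact zero is pooled with decrease.

    Only the sign of the variation is analysed.  A parameter that did not
    increase is grouped with the decreases — the conservative pooling for a
    risk marker — and the tie is warned about so it can be audited
    (callers that aggregate ties themselves pass ``warn=False``).
    """
    if not math.isfinite(variation_percent):
        raise ValueError("variation must be finite")
    if variation_percent > 0:
        return Direction.INCREASE
    if variation_percent == 0 and warn:
        logger.warning("variation exactly 0% grouped with 'decrease'")
    return Direction.DECREASE


def binarize_baseline(value: float, parameter_name: str, cutoffs: Cutoffs | None = None) -> str:
    """'high' iff value > cutoff, else 'low' (ties go low)."""
    cutoffs = cutoffs or Cutoffs()
    return "high" if value > cutoffs.for_parameter(parameter_name) else "low"


def median_integer_cutoff(values: Sequence[float]) -> int:
    """Sample median rounded half away from zero to the nearest integer."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("need at least one finite value")
    med = float(np.median(arr))
    return int(math.floor(med + 0.5)) if med >= 0 else int(math.ceil(med - 0.5))


def concordance_category(direction_a: Direction, direction_b: Direction) -> ConcordanceCategory:
    """Joint category of two variation directions; symmetric in its arguments."""
    if direction_a is direction_b:
        return (
            ConcordanceCategory.MUTUAL_INCREASE
            if direction_a is Direction.INCREASE
            else ConcordanceCategory.MUTUAL_DECREASE
        )
    return ConcordanceCategory.DISCORDANT


def _parameter_set(
    lesions: Sequence[MeasuredLesion],
    blood: BloodCounts,
    recist_sum_mm: float,
    patient_id: str,
) -> ParameterSet:
    return ParameterSet(
        volume=total_volume(lesions),
        recist_sum=float(recist_sum_mm),
        nlr=compute_nlr(blood, patient_id),
        n_lesions=len(lesions),
        n_organs=organ_count(lesions),
    )


def build_biomarker_table(
    lesions_by_pt: Mapping[tuple[str, str], Sequence[MeasuredLesion]],
    blood_by_pt: Mapping[tuple[str, str], BloodCounts],
    recist_by_pt: Mapping[tuple[str, str], float],
    cutoffs: Cutoffs | None = None,
) -> tuple[list[BiomarkerRow], list[str]]:
    """Assemble one row per patient with both timepoints.

    Keys are (patient_id, timepoint) with timepoint in {'baseline','eval1'}.
    Patients missing a timepoint in the blood/RECIST tables are rejected
    (returned in the second element) rather than silently dropped.  A
    patient may legitimately have zero lesions at a timepoint.
    """
    cutoffs = cutoffs or Cutoffs()
    patients = sorted({pid for pid, _ in blood_by_pt} | {pid for pid, _ in lesions_by_pt})
    rows: list[BiomarkerRow] = []
    rejects: list[str] = []
    zero_variation: Counter[str] = Counter()
    undefined_variation: Counter[str] = Counter()
    for pid in patients:
        missing = [
            tp
            for tp in ("baseline", "eval1")
            if (pid, tp) not in blood_by_pt or (pid, tp) not in recist_by_pt
        ]
        if missing:
            rejects.append(f"{pid}: missing timepoint(s) {', '.join(missing)}")
            continue
        sets = {}
        for tp in ("baseline", "eval1"):
            sets[tp] = _parameter_set(
                lesions_by_pt.get((pid, tp), ()),
                blood_by_pt[(pid, tp)],
                recist_by_pt[(pid, tp)],
                pid,
            )
        row = BiomarkerRow(patient_id=pid, baseline=sets["baseline"], eval1=sets["eval1"])
        for p in PARAMETERS:
            bl, e1 = getattr(row.baseline, p), getattr(row.eval1, p)
            row.baseline_class[p] = binarize_baseline(bl, p, cutoffs)
            var = variation(bl, e1)
            row.variation[p] = var
            if var is None:
                undefined_variation[p] += 1
                row.direction_of[p] = None
            else:
                if var == 0:
                    zero_variation[p] += 1
                row.direction_of[p] = direction(var, warn=False)
        dv, dn, dr = (row.direction_of[p] for p in ("volume", "nlr", "recist_sum"))
        if dv is not None and dn is not None:
            row.concordance_vol_nlr = concordance_category(dv, dn)
        if dr is not None and dn is not None:
            row.concordance_recist_nlr = concordance_category(dr, dn)
        rows.append(row)
    for p, c in sorted(zero_variation.items()):
        logger.warning("%d patient(s) with exactly 0%% %s variation grouped with 'decrease'", c, p)
    for p, c in sorted(undefined_variation.items()):
        logger.warning("%d patient(s) with zero baseline %s: variation undefined", c, p)
    return rows, rejects
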