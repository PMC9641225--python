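"""Readers and writers for the pipeline's plain-text exchange formats.

* Annotations: JSON-lines, one lesion per line with keys ``patient_id``,
  ``timepoint`` ("baseline"|"eval1"), ``lesion_id``, ``organ`` and
  ``vertices_mm`` ([[x, y], ...]).  A pixel dialect with
  ``pixel_spacing_mm`` and ``vertices_px`` is accepted and converted to mm
  on read (mm = px * spacing).  Coordinates are continuous mm throughout;
  no pixel indexing convention is exposed.
* Blood / RECIST table: CSV with columns patient_id, timepoint,
  neutrophils, lymphocytes, and either recist_sum_mm or per-target
  ``target_diameter_mm_*`` columns (summed on read).
* Outcomes: patient-level CSV with os_months, os_event, pfs_months,
  pfs_event and optional demographics.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .biomarkers import PARAMETERS, BiomarkerRow, BloodCounts
from .geometry import LesionAnnotation, OrganLabel, Polygon2D, Timepoint

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_timepoint_table",
    "read_outcomes",
    "biomarker_table_to_frame",
    "write_biomarker_table",
]


def read_annotations(path: str | Path) -> list[LesionAnnotation]:
    """Parse a JSON-lines annotation file; unknown organ labels raise."""
    out: list[LesionAnnotation] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                if "vertices_mm" in rec:
                    vertices = rec["vertices_mm"]
                else:
                    spacing = float(rec["pixel_spacing_mm"])
                    vertices = [
                        [x * spacing, y * spacing] for x, y in rec["vertices_px"]
                    ]
                ann = LesionAnnotation(
                    lesion_id=str(rec["lesion_id"]),
                    patient_id=str(rec["patient_id"]),
                    timepoint=Timepoint(rec["timepoint"]),
                    organ=OrganLabel(rec["organ"]),
                    polygon=Polygon2D(vertices),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad annotation record: {exc}") from exc
            key = (ann.patient_id, ann.timepoint.value, ann.lesion_id)
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate lesion key {key}")
            seen.add(key)
            out.append(ann)
    return out


def write_annotations(path: str | Path, annotations: Iterable[LesionAnnotation]) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            rec = {
                "patient_id": a.patient_id,
                "timepoint": a.timepoint.value,
                "lesion_id": a.lesion_id,
                "organ": a.organ.value,
                "vertices_mm": [[round(x, 4), round(y, 4)] for x, y in a.polygon.vertices],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_timepoint_table(
    path: str | Path,
) -> tuple[dict[tuple[str, str], BloodCounts], dict[tuple[str, str], float]]:
    """Read the per-(patient, timepoint) blood counts and RECIST sums."""
    df = pd.read_csv(path, dtype={"patient_id": str, "timepoint": str})
    required = {"patient_id", "timepoint", "neutrophils", "lymphocytes"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    target_cols = [c for c in df.columns if c.startswith("target_diameter_mm")]
    if "recist_sum_mm" not in df.columns and not target_cols:
        raise ValueError(f"{path}: need recist_sum_mm or target_diameter_mm_* columns")
    blood: dict[tuple[str, str], BloodCounts] = {}
    recist: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        key = (row["patient_id"], row["timepoint"])
        if key in blood:
            raise ValueError(f"{path}: duplicate (patient, timepoint) {key}")
        blood[key] = BloodCounts(float(row["neutrophils"]), float(row["lymphocytes"]))
        if "recist_sum_mm" in df.columns and pd.notna(row.get("recist_sum_mm")):
            recist[key] = float(row["recist_sum_mm"])
        else:
            diam = [float(row[c]) for c in target_cols if pd.notna(row[c])]
            if len(diam) > 5:
                raise ValueError(f"{path}: more than 5 target lesions for {key}")
            recist[key] = float(sum(diam))
    return blood, recist


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Patient-level survival outcomes (and optional demographics)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "os_months", "os_event", "pfs_months", "pfs_event"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient_id rows")
    return df.set_index("patient_id", drop=False)


_BIOMARKER_COLUMNS = (
    ["patient_id"]
    + [f"{p}_baseline" for p in PARAMETERS]
    + [f"{p}_eval1" for p in PARAMETERS]
    + [f"{p}_variation_pct" for p in PARAMETERS]
    + [f"{p}_baseline_class" for p in PARAMETERS]
    + [f"{p}_direction" for p in PARAMETERS]
    + ["concordance_vol_nlr", "concordance_recist_nlr"]
)


def biomarker_table_to_frame(rows: Sequence[BiomarkerRow]) -> pd.DataFrame:
    """Flatten biomarker rows to a DataFrame with a fixed column order."""
    records = []
    for r in rows:
        rec: dict[str, object] = {"patient_id": r.patient_id}
        for p in PARAMETERS:
            rec[f"{p}_baseline"] = getattr(r.baseline, p)
            rec[f"{p}_eval1"] = getattr(r.eval1, p)
            rec[f"{p}_variation_pct"] = r.variation[p]
            rec[f"{p}_baseline_class"] = r.baseline_class[p]
            d = r.direction_of[p]
            rec[f"{p}_direction"] = d.value if d is not None else None
        rec["concordance_vol_nlr"] = (
            r.concordance_vol_nlr.value if r.concordance_vol_nlr else None
        )
        rec["concordance_recist_nlr"] = (
            r.concordance_recist_nlr.value if r.concordance_recist_nlr else None
        )
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=_BIOMARKER_COLUMNS)


def write_biomarker_table(rows: Sequence[BiomarkerRow], path: str | Path) -> None:
    """CSV, one row per patient; missing values as empty fields."""
    df = biomarker_table_to_frame(rows)
    df.to_csv(path, index=False, float_format="%.6g", na_rep="", lineterminator="\n",
              quoting=csv.QUOTE_MINIMAL)
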