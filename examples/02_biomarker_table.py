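"""From lesions and blood counts to the five burden parameters.

Hand-builds two patients — a responder whose tumors shrink and NLR falls,
and a progressor with growth and rising NLR — and prints their variations,
baseline classes and concordance categories.
"""

import math

import numpy as np

from mmrd_burden.biomarkers import BloodCounts, build_biomarker_table
from mmrd_burden.geometry import (
    LesionAnnotation,
    OrganLabel,
    Polygon2D,
    Timepoint,
    measure_lesions,
)


def circle(r, n=96):
    a = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Polygon2D(np.column_stack([r * np.cos(a), r * np.sin(a)]))


def patient(pid, radii_bl, radii_e1):
    lesions = {}
    for tp, radii in (("baseline", radii_bl), ("eval1", radii_e1)):
        anns = [
            LesionAnnotation(f"L{i}", pid, Timepoint(tp), OrganLabel.LIVER, circle(r))
            for i, r in enumerate(radii)
        ]
        lesions[(pid, tp)] = measure_lesions(anns)
    return lesions


lesions = patient("responder", [20.0, 15.0], [14.0, 10.0])
lesions |= patient("progressor", [18.0, 12.0], [24.0, 16.0])
blood = {
    ("responder", "baseline"): BloodCounts(6.0, 1.0),   # NLR 6 -> 3
    ("responder", "eval1"): BloodCounts(4.5, 1.5),
    ("progressor", "baseline"): BloodCounts(4.0, 1.0),  # NLR 4 -> 8
    ("progressor", "eval1"): BloodCounts(8.0, 1.0),
}
recist = {
    ("responder", "baseline"): 70.0,
    ("responder", "eval1"): 48.0,
    ("progressor", "baseline"): 60.0,
    ("progressor", "eval1"): 80.0,
}

rows, rejects = build_biomarker_table(lesions, blood, recist)
assert not rejects
for r in rows:
    print(f"patient {r.patient_id}")
    print(f"  baseline volume {r.baseline.volume:7.1f} cm^3 ({r.baseline_class['volume']})")
    for p in ("volume", "recist_sum", "nlr"):
        print(
            f"  {p:<11} {getattr(r.baseline, p):8.2f} -> {getattr(r.eval1, p):8.2f}"
            f"  ({r.variation[p]:+6.1f}%, {r.direction_of[p].value})"
        )
    print(f"  concordance volume x NLR: {r.concordance_vol_nlr.value}")
    print(f"  concordance RECIST x NLR: {r.concordance_recist_nlr.value}\n")
# Mutual decrease of volume and NLR marks the favourable response pattern;
# mutual increase marks progression.
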