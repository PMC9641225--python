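"""End-to-end run: synthetic cohort -> biomarker table -> survival report.

Generates a default 61-patient cohort with planted hazards (baseline
volume above 90 cm^3, NLR increase, volume increase), runs the full
pipeline and prints the key stratification results.
"""

import tempfile
from pathlib import Path

from mmrd_burden.pipeline import AnalysisConfig, run_pipeline, write_report
from mmrd_burden.synthetic import CohortConfig, generate_cohort

with tempfile.TemporaryDirectory() as tmp:
    d = Path(tmp)
    cohort = generate_cohort(CohortConfig(seed=42))
    cohort.write(d)
    print(
        f"generated {cohort.config.n_patients} patients, "
        f"{len(cohort.annotations)} lesion annotations"
    )

    report = run_pipeline(
        d / "annotations.jsonl",
        d / "blood_recist.csv",
        d / "outcomes.csv",
        AnalysisConfig(),
    )
    write_report(report, d / "report")

    os_an = report["analyses"]["os"]
    print("\nbaseline univariate (OS):")
    for p, a in os_an["baseline"].items():
        lr = a["log_rank"]
        sizes = "/".join(str(s["n"]) for s in a["groups"].values())
        p_txt = f"p={lr['p_value']:.4g}" if lr["status"] == "ok" else lr["reason"]
        print(f"  {p:<11} (high/low n={sizes}, cutoff {a['cutoff']:g}): log-rank {p_txt}")

    print("\nconcordance volume x NLR (OS):")
    conc = os_an["concordance"]["volume_x_nlr"]
    for g, s in conc["groups"].items():
        print(f"  {g:<16} n={s['n']:>2}, KM median = {s['median_months']} months")
    for pair, p in conc["log_rank"].get("pairwise", {}).items():
        print(f"  pairwise {pair}: p={p:.4g}")
# Because hazards were planted on high baseline volume and on volume/NLR
# increases, the volume split and the concordance categories should
# separate: mutual decrease longest survival, mutual increase shortest.
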