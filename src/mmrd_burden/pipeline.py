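"""End-to-end orchestration: files in, stats report out.

Stage order: read and validate inputs -> shape features -> inclusion
filter -> biomarker table -> per-parameter baseline univariate analyses
(KM + log-rank on low/high groups) -> baseline Spearman screen and
multivariate Cox -> the same for variations (increase/decrease groups) ->
concordance-score analyses with pairwise log-rank.  Everything is repeated
for both endpoints (OS and PFS).

The report is deterministic for identical inputs and config: analyses are
ordered, dict keys sorted on write, and no timestamps are embedded.
Groups that cannot be analysed (an empty arm, no events) are reported with
an explicit reason instead of failing the run.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as io_mod
from .biomarkers import (
    PARAMETERS,
    BiomarkerRow,
    Cutoffs,
    build_biomarker_table,
    median_integer_cutoff,
)
from .geometry import filter_lesions, measure_lesions
from .survival import (
    SurvivalOutcome,
    cox_fit,
    km_estimate,
    logrank_test,
    pairwise_logrank,
    spearman_screen,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline", "write_report"]

ENDPOINTS = ("os", "pfs")
CONCORDANCE_ATTRS = {
    ("volume", "nlr"): "concordance_vol_nlr",
    ("recist_sum", "nlr"): "concordance_recist_nlr",
}


class AnalysisConfig(BaseModel):
    """Analysis settings; defaults mirror the study's published choices."""

    cutoffs: dict[str, float] = Field(
        default_factory=lambda: {
            "volume": 90.0,
            "recist_sum": 55.0,
            "nlr": 5.0,
            "n_lesions": 10.0,
            "n_organs": 3.0,
        }
    )
    cutoff_mode: str = Field("fixed", pattern="^(fixed|cohort_median)$")
    concordance_pairs: list[tuple[str, str]] = Field(
        default_factory=lambda: [("volume", "nlr"), ("recist_sum", "nlr")]
    )
    independence_threshold: float = Field(0.8, gt=0, le=1)
    ci_level: float = Field(0.95, gt=0, lt=1)
    bonferroni_pairwise: bool = False
    log_level: str = "INFO"

    def model_post_init(self, _ctx) -> None:
        for p, v in self.cutoffs.items():
            if p not in PARAMETERS:
                raise ValueError(f"unknown parameter in cutoffs: {p!r}")
            if v <= 0:
                raise ValueError(f"cutoff for {p} must be positive")
        for a, b in self.concordance_pairs:
            if tuple(sorted((a, b))) not in {tuple(sorted(k)) for k in CONCORDANCE_ATTRS}:
                raise ValueError(f"unsupported concordance pair ({a}, {b})")


def _km_summary(outcomes: Sequence[SurvivalOutcome], ci_level: float) -> dict:
    curve = km_estimate(outcomes, ci_level)
    return {
        "n": len(outcomes),
        "events": int(sum(o.event for o in outcomes)),
        "median_months": None if np.isnan(curve.median()) else round(curve.median(), 4),
    }


def _km_coordinates(label: str, outcomes: Sequence[SurvivalOutcome], ci_level: float) -> list[dict]:
    curve = km_estimate(outcomes, ci_level)
    rows = [
        {"group": label, "time_months": 0.0, "survival": 1.0, "ci_lower": 1.0, "ci_upper": 1.0}
    ]
    for t, s, lo, hi in zip(curve.event_times, curve.survival, curve.ci_lower, curve.ci_upper):
        rows.append(
            {
                "group": label,
                "time_months": round(float(t), 6),
                "survival": round(float(s), 6),
                "ci_lower": round(float(lo), 6),
                "ci_upper": round(float(hi), 6),
            }
        )
    return rows


def _grouped_analysis(
    groups: Mapping[str, list[SurvivalOutcome]], ci_level: float, bonferroni: bool
) -> dict:
    """KM per group + (pairwise) log-rank; degenerate layouts get a reason."""
    result: dict = {"groups": {}}
    for label in sorted(groups):
        result["groups"][label] = (
            _km_summary(groups[label], ci_level)
            if groups[label]
            else {"n": 0, "events": 0, "median_months": None}
        )
    usable = {k: v for k, v in groups.items() if v}
    if len(usable) < 2:
        result["log_rank"] = {"status": "not_estimable", "reason": "fewer than 2 non-empty groups"}
        return result
    try:
        if len(usable) == 2:
            r = logrank_test(list(usable.values()))
            result["log_rank"] = {
                "status": "ok",
                "chi_square": round(r.chi_square, 6),
                "dof": r.dof,
                "p_value": round(r.p_value, 6),
            }
        else:
            overall = logrank_test(list(usable.values()))
            pw = pairwise_logrank(usable, bonferroni=bonferroni)
            labels = sorted(usable)
            result["log_rank"] = {
                "status": "ok",
                "chi_square": round(overall.chi_square, 6),
                "dof": overall.dof,
                "p_value": round(overall.p_value, 6),
                "pairwise": {
                    f"{a} vs {b}": round(pw[(a, b)].p_value, 6)
                    for i, a in enumerate(labels)
                    for b in labels[i + 1 :]
                },
            }
    except ValueError as exc:
        result["log_rank"] = {"status": "not_estimable", "reason": str(exc)}
    return result


def _cox_analysis(
    covariates: dict[str, list[float]],
    outcomes: list[SurvivalOutcome],
    ci_level: float,
) -> dict:
    try:
        fit = cox_fit(covariates, outcomes, ci_level=ci_level)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return {"status": "not_estimable", "reason": str(exc)}
    return {
        "status": "ok" if fit.converged else "not_converged",
        "n_events": fit.n_events,
        "covariates": {
            k: {kk: round(vv, 6) for kk, vv in v.items()}
            for k, v in fit.summary_dict().items()
        },
    }


def _screen_analysis(values: dict[str, list[float]], threshold: float) -> dict:
    complete = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    try:
        screen = spearman_screen(complete, threshold)
    except ValueError as exc:
        return {"status": "not_estimable", "reason": str(exc)}
    return {
        "status": "ok",
        "threshold": threshold,
        "matrix": {
            a: {
                b: (
                    round(float(screen.matrix[i, j]), 4)
                    if np.isfinite(screen.matrix[i, j])
                    else None
                )
                for j, b in enumerate(screen.names)
            }
            for i, a in enumerate(screen.names)
        },
        "non_independent_pairs": [
            {"a": a, "b": b, "rho": round(r, 4)} for a, b, r in screen.flagged_pairs
        ],
    }


def run_pipeline(
    annotations_path: str | Path,
    tables_path: str | Path,
    outcomes_path: str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Execute the full analysis and return the report as a plain dict."""
    config = config or AnalysisConfig()

    annotations = io_mod.read_annotations(annotations_path)
    blood_by_pt, recist_by_pt = io_mod.read_timepoint_table(tables_path)
    outcomes_df = io_mod.read_outcomes(outcomes_path)

    measured = filter_lesions(measure_lesions(annotations))
    lesions_by_pt: dict[tuple[str, str], list] = defaultdict(list)
    for m in measured:
        lesions_by_pt[(m.annotation.patient_id, m.annotation.timepoint.value)].append(m)

    cutoffs = Cutoffs(**config.cutoffs)
    rows, rejects = build_biomarker_table(lesions_by_pt, blood_by_pt, recist_by_pt, cutoffs)

    # patients must also carry outcomes
    with_outcomes: list[BiomarkerRow] = []
    for r in rows:
        if r.patient_id in outcomes_df.index:
            with_outcomes.append(r)
        else:
            rejects.append(f"{r.patient_id}: no survival outcome record")
    for pid in outcomes_df.index:
        if pid not in {r.patient_id for r in rows}:
            rejects.append(f"{pid}: outcome present but no biomarker data")
    rows = with_outcomes
    if len(rows) < 2:
        raise ValueError(
            f"cohort too small after rejects: {len(rows)} analysable patient(s)"
        )

    if config.cutoff_mode == "cohort_median":
        recomputed = {
            p: float(median_integer_cutoff([getattr(r.baseline, p) for r in rows]))
            for p in PARAMETERS
            if p != "nlr"  # NLR keeps its literature cutoff
        }
        recomputed["nlr"] = cutoffs.nlr
        cutoffs = Cutoffs(**recomputed)
        rows, _ = build_biomarker_table(lesions_by_pt, blood_by_pt, recist_by_pt, cutoffs)
        rows = [r for r in rows if r.patient_id in outcomes_df.index]

    surv: dict[str, dict[str, SurvivalOutcome]] = {ep: {} for ep in ENDPOINTS}
    for r in rows:
        rec = outcomes_df.loc[r.patient_id]
        surv["os"][r.patient_id] = SurvivalOutcome(float(rec.os_months), int(rec.os_event))
        surv["pfs"][r.patient_id] = SurvivalOutcome(float(rec.pfs_months), int(rec.pfs_event))

    tumor_counts = (
        Counter(outcomes_df.loc[[r.patient_id for r in rows], "tumor_type"])
        if "tumor_type" in outcomes_df.columns
        else Counter()
    )
    report: dict = {
        "config": json.loads(config.model_dump_json()),
        "cutoffs_used": {p: getattr(cutoffs, p) for p in PARAMETERS},
        "cohort": {
            "n_analyzed": len(rows),
            "n_rejected": len(rejects),
            "n_lesions_after_filter": len(measured),
            "tumor_types": dict(sorted(tumor_counts.items())),
            "median_age": (
                float(outcomes_df.loc[[r.patient_id for r in rows], "age"].median())
                if "age" in outcomes_df.columns
                else None
            ),
        },
        "rejects": sorted(rejects),
        "warnings": [],
        "analyses": {},
        "km_coordinates": [],
    }

    for ep in ENDPOINTS:
        ep_out: dict = {"baseline": {}, "variation": {}, "concordance": {}}
        out_of = lambda ids: [surv[ep][i] for i in ids]  # noqa: E731

        # --- baseline univariate: low vs high per parameter
        for p in PARAMETERS:
            groups = {"low": [], "high": []}
            for r in rows:
                groups[r.baseline_class[p]].append(r.patient_id)
            analysis = _grouped_analysis(
                {k: out_of(v) for k, v in groups.items()},
                config.ci_level,
                config.bonferroni_pairwise,
            )
            analysis["cutoff"] = getattr(cutoffs, p)
            ep_out["baseline"][p] = analysis
            if ep == "os":
                for k, ids in groups.items():
                    if ids:
                        report["km_coordinates"].extend(
                            _km_coordinates(f"os baseline {p} {k}", out_of(ids), config.ci_level)
                        )

        # --- baseline multivariate: Spearman screen + Cox on low/high indicators
        ep_out["baseline_screen"] = _screen_analysis(
            {p: [getattr(r.baseline, p) for r in rows] for p in PARAMETERS},
            config.independence_threshold,
        )
        ep_out["baseline_cox"] = _cox_analysis(
            {
                f"{p}_baseline_high": [
                    1.0 if r.baseline_class[p] == "high" else 0.0 for r in rows
                ]
                for p in PARAMETERS
            },
            out_of([r.patient_id for r in rows]),
            config.ci_level,
        )

        # --- variation univariate: increase vs decrease (undefined excluded)
        for p in PARAMETERS:
            groups = {"increase": [], "decrease": []}
            excluded = 0
            for r in rows:
                d = r.direction_of[p]
                if d is None:
                    excluded += 1
                else:
                    groups[d.value].append(r.patient_id)
            analysis = _grouped_analysis(
                {k: out_of(v) for k, v in groups.items()},
                config.ci_level,
                config.bonferroni_pairwise,
            )
            analysis["n_undefined_variation"] = excluded
            ep_out["variation"][p] = analysis

        defined = [r for r in rows if all(r.direction_of[p] is not None for p in PARAMETERS)]
        ep_out["variation_screen"] = _screen_analysis(
            {p: [r.variation[p] for r in defined] for p in PARAMETERS},
            config.independence_threshold,
        )
        ep_out["variation_cox"] = _cox_analysis(
            {
                f"{p}_increase": [
                    1.0 if r.direction_of[p].value == "increase" else 0.0 for r in defined
                ]
                for p in PARAMETERS
            },
            out_of([r.patient_id for r in defined]),
            config.ci_level,
        )

        # --- concordance scores: 3-way stratification + pairwise log-rank
        for pair in config.concordance_pairs:
            pair = tuple(pair)
            attr = CONCORDANCE_ATTRS.get(pair) or CONCORDANCE_ATTRS[(pair[1], pair[0])]
            groups: dict[str, list[str]] = defaultdict(list)
            for r in rows:
                cat = getattr(r, attr)
                if cat is not None:
                    groups[cat.value].append(r.patient_id)
            analysis = _grouped_analysis(
                {k: out_of(v) for k, v in groups.items()},
                config.ci_level,
                config.bonferroni_pairwise,
            )
            key = f"{pair[0]}_x_{pair[1]}"
            ep_out["concordance"][key] = analysis
            if ep == "os":
                for k, ids in sorted(groups.items()):
                    if ids:
                        report["km_coordinates"].extend(
                            _km_coordinates(f"os concordance {key} {k}", out_of(ids), config.ci_level)
                        )

        report["analyses"][ep] = ep_out

    report["biomarker_rows"] = rows  # stripped before JSON serialization
    return report


def _report_text(report: dict) -> str:
    lines = ["Tumor-burden biomarker analysis report", "=" * 40, ""]
    c = report["cohort"]
    lines.append(
        f"Cohort: {c['n_analyzed']} analysed, {c['n_rejected']} rejected, "
        f"{c['n_lesions_after_filter']} lesions retained after filtering"
    )
    if c["tumor_types"]:
        lines.append("Tumor types: " + ", ".join(f"{k}={v}" for k, v in c["tumor_types"].items()))
    lines.append("Cutoffs: " + ", ".join(f"{k}={v:g}" for k, v in report["cutoffs_used"].items()))
    lines.append("")
    for ep, ep_out in report["analyses"].items():
        lines.append(f"[{ep.upper()}]")
        for section in ("baseline", "variation"):
            for p, a in ep_out[section].items():
                lr = a["log_rank"]
                p_txt = (
                    f"p={lr['p_value']:.4g}" if lr["status"] == "ok" else f"({lr['reason']})"
                )
                sizes = ", ".join(
                    f"{g}: n={s['n']}, median={s['median_months']}"
                    for g, s in a["groups"].items()
                )
                lines.append(f"  {section} {p}: {sizes}; log-rank {p_txt}")
        for key, a in ep_out["concordance"].items():
            lr = a["log_rank"]
            p_txt = f"p={lr['p_value']:.4g}" if lr["status"] == "ok" else f"({lr['reason']})"
            sizes = ", ".join(f"{g}: n={s['n']}" for g, s in a["groups"].items())
            lines.append(f"  concordance {key}: {sizes}; log-rank {p_txt}")
            if lr.get("pairwise"):
                for pk, pv in lr["pairwise"].items():
                    lines.append(f"    pairwise {pk}: p={pv:.4g}")
        for model in ("baseline_cox", "variation_cox"):
            cx = ep_out[model]
            if cx["status"] in ("ok", "not_converged"):
                lines.append(f"  {model} ({cx['n_events']} events):")
                for name, row in cx["covariates"].items():
                    lines.append(
                        f"    {name}: HR={row['hr']:.3g} "
                        f"[{row['ci_lower']:.3g}, {row['ci_upper']:.3g}], p={row['p']:.4g}"
                    )
            else:
                lines.append(f"  {model}: {cx['reason']}")
        lines.append("")
    if report["rejects"]:
        lines.append("Rejected records:")
        lines.extend(f"  - {r}" for r in report["rejects"])
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write report.json, report.txt, biomarker_table.csv, stats CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = report.pop("biomarker_rows")
    km_rows = report.pop("km_coordinates")
    paths = {
        "json": out / "report.json",
        "text": out / "report.txt",
        "biomarkers": out / "biomarker_table.csv",
        "km": out / "km_coordinates.csv",
        "stats": out / "stats_summary.csv",
    }
    with open(paths["json"], "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(paths["text"], "w") as fh:
        fh.write(_report_text(report))
    io_mod.write_biomarker_table(rows, paths["biomarkers"])
    pd.DataFrame(km_rows).to_csv(paths["km"], index=False, lineterminator="\n")
    stat_rows = []
    for ep, ep_out in report["analyses"].items():
        for section in ("baseline", "variation", "concordance"):
            for p, a in ep_out[section].items():
                lr = a["log_rank"]
                stat_rows.append(
                    {
                        "endpoint": ep,
                        "analysis": section,
                        "parameter": p,
                        "group_sizes": ";".join(
                            f"{g}={s['n']}" for g, s in a["groups"].items()
                        ),
                        "logrank_p": lr.get("p_value"),
                        "status": lr["status"],
                    }
                )
    pd.DataFrame(stat_rows).to_csv(paths["stats"], index=False, lineterminator="\n")
    report["biomarker_rows"] = rows
    report["km_coordinates"] = km_rows
    return paths
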