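"""Synthetic cohort generator.

Emulates the structure of a retrospective MMRD/MSI immunotherapy cohort:
~61 patients of mixed tumor type, freehand-style polygonal lesion contours
at two CT timepoints (baseline and first evaluation ~2 months later),
blood counts, RECIST target-diameter sums, and right-censored OS/PFS drawn
from an exponential proportional-hazards model whose covariates are the
binarized biomarkers the downstream analysis actually computes.  Each
generated cohort carries its ground truth (latent response class, growth
multiplier, linear predictor, uncensored event times) so that recovery of
planted effects can be tested end to end.

Design of the planted signal
----------------------------
Each patient is a latent responder or progressor.  Responders' lesions
shrink between timepoints (linear scale factor < 1) and their NLR tends to
drift down; progressors grow, may seed new lesions, and drift up.  The
hazard acts through three indicator covariates measured from the generated
data itself — baseline volume above the cutoff, NLR increase, volume
increase — with configurable log hazard ratios, so survival is tied to the
observable biomarkers, not to the latent class directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .geometry import (
    LesionAnnotation,
    MeasuredLesion,
    OrganLabel,
    Polygon2D,
    Timepoint,
    filter_lesions,
    measure_lesions,
)
from .io import write_annotations
from .survival import SurvivalOutcome

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_lesion_polygon",
    "generate_cohort",
    "simulate_survival",
]

#: tumor-type mix of the emulated cohort (counts out of 61)
DEFAULT_TUMOR_TYPE_WEIGHTS = {
    "colorectal": 26 / 61,
    "endometrial": 13 / 61,
    "gastric": 7 / 61,
    "small_intestine": 5 / 61,
    "prostate": 2 / 61,
    "ovarian": 2 / 61,
    "esophagus": 2 / 61,
    "pancreas": 2 / 61,
    "adrenal_gland": 1 / 61,
    "uterine_cervix": 1 / 61,
}

#: marginal propensity of each organ to host a metastasis
DEFAULT_ORGAN_WEIGHTS = {
    "liver": 0.19,
    "lymph_node": 0.20,
    "lung": 0.14,
    "carcinosis": 0.12,
    "bone": 0.08,
    "other": 0.05,
    "bowels": 0.04,
    "pancreas": 0.03,
    "adrenal": 0.03,
    "spleen": 0.02,
    "kidney": 0.02,
    "muscle": 0.02,
    "skin_soft_tissue": 0.02,
    "ovary": 0.02,
    "brain": 0.01,
    "heart": 0.01,
}


class CohortConfig(BaseModel):
    """All knobs of the generator; the defaults are the emulated study
    conditions (cohort size, tumor mix, responder fraction, lesion load).
    """

    n_patients: int = Field(61, ge=2)
    tumor_type_weights: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_TUMOR_TYPE_WEIGHTS)
    )
    organ_weights: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ORGAN_WEIGHTS)
    )
    # lesion load: negative binomial with mean 2120/61 across patients
    lesions_per_patient_mean: float = Field(2120 / 61, gt=0)
    lesions_per_patient_dispersion: float = Field(3.0, gt=0)  # NB size r
    organs_per_patient_poisson_mean: float = Field(2.2, ge=0)
    # lesion extent: log-normal radius in mm
    lesion_radius_log_mean: float = math.log(6.5)
    lesion_radius_log_sd: float = Field(0.5, ge=0)
    polygon_vertices: int = Field(32, ge=8)
    polygon_irregularity: float = Field(0.15, ge=0, lt=1)
    # latent response: responders shrink, progressors grow (linear scale)
    responder_fraction: float = Field(31 / 61, ge=0, le=1)
    responder_scale_log_mean: float = math.log(0.80)
    progressor_scale_log_mean: float = math.log(1.15)
    growth_scale_log_sd: float = Field(0.12, ge=0)
    new_lesions_poisson_mean: float = Field(1.5, ge=0)  # progressors only
    # blood counts: log-normal NLR around the clinical cutoff region
    nlr_log_mean: float = math.log(4.0)
    nlr_log_sd: float = Field(0.45, ge=0)
    lymphocytes_log_mean: float = math.log(1.2)
    lymphocytes_log_sd: float = Field(0.3, ge=0)
    nlr_drift_responder: float = -0.25  # additive on log NLR
    nlr_drift_progressor: float = 0.25
    nlr_drift_sd: float = Field(0.30, ge=0)
    # planted proportional-hazards effects on measured indicators
    log_hr_volume_baseline_high: float = math.log(3.2)
    log_hr_nlr_increase: float = math.log(2.9)
    log_hr_volume_increase: float = math.log(2.0)
    volume_baseline_cutoff_cm3: float = Field(90.0, gt=0)
    # exponential baseline hazards and censoring (per month)
    os_baseline_rate: float = Field(math.log(2) / 60.0, gt=0)
    pfs_baseline_rate: float = Field(math.log(2) / 12.0, gt=0)
    os_censor_rate: float = Field(0.045, ge=0)
    pfs_censor_rate: float = Field(0.10, ge=0)
    seed: int

    @model_validator(mode="after")
    def _check_weights(self) -> "CohortConfig":
        for name, w in (("tumor_type_weights", self.tumor_type_weights),
                        ("organ_weights", self.organ_weights)):
            total = sum(w.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} must sum to 1 (got {total:.6f})")
            if any(v < 0 for v in w.values()):
                raise ValueError(f"{name} must be non-negative")
        unknown = set(self.organ_weights) - {o.value for o in OrganLabel}
        if unknown:
            raise ValueError(f"unknown organ labels in organ_weights: {sorted(unknown)}")
        return self


def generate_lesion_polygon(
    center: tuple[float, float],
    mean_radius: float,
    irregularity: float,
    n_vertices: int,
    seed: int | np.random.Generator,
) -> Polygon2D:
    """Star-convex 'freehand' contour around ``center``.

    Radii are ``mean_radius * (1 + irregularity * noise)`` at equally
    spaced angles, with zero-mean uniform noise, so the expected radius is
    ``mean_radius`` by construction.  Deterministic given the seed.
    """
    if mean_radius <= 0:
        raise ValueError("mean_radius must be positive")
    if not 0 <= irregularity < 1:
        raise ValueError("irregularity must be in [0, 1)")
    if n_vertices < 8:
        raise ValueError("need at least 8 vertices")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    noise = rng.uniform(-1.0, 1.0, size=n_vertices)
    radii = mean_radius * (1.0 + irregularity * noise)
    cx, cy = center
    xy = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
    return Polygon2D(xy)


def simulate_survival(
    linear_predictor: float,
    baseline_rate: float,
    censor_rate: float,
    seed: int | np.random.Generator,
) -> SurvivalOutcome:
    """One subject from an exponential PH model with exponential censoring.

    Event time ~ Exp(baseline_rate * exp(linear_predictor)); censoring time
    ~ Exp(censor_rate) (infinite when censor_rate == 0); the observed time
    is the minimum, with the event indicator.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_event = rng.exponential(1.0 / (baseline_rate * math.exp(linear_predictor)))
    t_cens = rng.exponential(1.0 / censor_rate) if censor_rate > 0 else math.inf
    if t_event <= t_cens:
        return SurvivalOutcome(time=max(t_event, 1e-9), event=1)
    return SurvivalOutcome(time=max(t_cens, 1e-9), event=0)


@dataclass
class SyntheticCohort:
    """In-memory generated cohort plus its ground truth."""

    config: CohortConfig
    annotations: list[LesionAnnotation]
    timepoint_table: pd.DataFrame  # patient_id, timepoint, neutrophils, lymphocytes, recist_sum_mm
    outcomes: pd.DataFrame  # patient_id, os/pfs columns, demographics
    ground_truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write annotations.jsonl, blood_recist.csv, outcomes.csv and
        ground_truth.json; byte-identical for identical config + seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotations": out / "annotations.jsonl",
            "tables": out / "blood_recist.csv",
            "outcomes": out / "outcomes.csv",
            "ground_truth": out / "ground_truth.json",
        }
        write_annotations(paths["annotations"], self.annotations)
        self.timepoint_table.to_csv(
            paths["tables"], index=False, float_format="%.6g", lineterminator="\n"
        )
        self.outcomes.to_csv(
            paths["outcomes"], index=False, float_format="%.6g", lineterminator="\n"
        )
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _recist_target_sum(measured: Sequence[MeasuredLesion]) -> tuple[float, list[str]]:
    """Simplified target-lesion selection: measurable lesions (major axis
    > 10 mm; lymph nodes: minor axis > 15 mm), largest first, at most 2 per
    organ and 5 in total; returns (sum of major axes in mm, lesion ids)."""
    eligible = []
    for m in measured:
        if m.annotation.organ is OrganLabel.LYMPH_NODE:
            if m.features.minor_axis > 15.0:
                eligible.append(m)
        elif m.features.major_axis > 10.0:
            eligible.append(m)
    eligible.sort(key=lambda m: -m.features.major_axis)
    per_organ: dict[OrganLabel, int] = {}
    chosen: list[MeasuredLesion] = []
    for m in eligible:
        if len(chosen) == 5:
            break
        org = m.annotation.organ
        if per_organ.get(org, 0) >= 2:
            continue
        per_organ[org] = per_organ.get(org, 0) + 1
        chosen.append(m)
    return (
        float(sum(m.features.major_axis for m in chosen)),
        [m.annotation.lesion_id for m in chosen],
    )


def _sample_organs(cfg: CohortConfig, rng: np.random.Generator) -> list[str]:
    """Involved organs for one patient: 1 + Poisson draws, sampled without
    replacement by marginal propensity."""
    n = 1 + int(rng.poisson(cfg.organs_per_patient_poisson_mean))
    names = list(cfg.organ_weights)
    probs = np.array([cfg.organ_weights[o] for o in names])
    probs = probs / probs.sum()
    n = min(n, len(names))
    return list(rng.choice(names, size=n, replace=False, p=probs))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort; fully determined by ``config`` (incl. seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    tumor_types = list(cfg.tumor_type_weights)
    tumor_probs = np.array([cfg.tumor_type_weights[t] for t in tumor_types])
    tumor_probs = tumor_probs / tumor_probs.sum()

    annotations: list[LesionAnnotation] = []
    tp_rows: list[dict] = []
    outcome_rows: list[dict] = []
    truth: dict[str, dict] = {}

    nb_r = cfg.lesions_per_patient_dispersion
    nb_p = nb_r / (nb_r + cfg.lesions_per_patient_mean)

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        tumor_type = str(rng.choice(tumor_types, p=tumor_probs))
        is_responder = bool(rng.random() < cfg.responder_fraction)
        scale_mu = (
            cfg.responder_scale_log_mean if is_responder else cfg.progressor_scale_log_mean
        )
        growth = float(rng.lognormal(scale_mu, cfg.growth_scale_log_sd))

        n_lesions = max(1, int(rng.negative_binomial(nb_r, nb_p)))
        organs = _sample_organs(cfg, rng)
        organ_probs = rng.dirichlet(np.full(len(organs), 1.5))

        baseline_anns: list[LesionAnnotation] = []
        for j in range(n_lesions):
            organ = str(rng.choice(organs, p=organ_probs))
            radius = float(
                rng.lognormal(cfg.lesion_radius_log_mean, cfg.lesion_radius_log_sd)
            )
            center = tuple(rng.uniform(-150.0, 150.0, size=2))
            poly = generate_lesion_polygon(
                center, radius, cfg.polygon_irregularity, cfg.polygon_vertices, rng
            )
            baseline_anns.append(
                LesionAnnotation(
                    lesion_id=f"L{j + 1:03d}",
                    patient_id=pid,
                    timepoint=Timepoint.BASELINE,
                    organ=OrganLabel(organ),
                    polygon=poly,
                )
            )
        # first evaluation: same lesions rescaled about their centroid
        eval_anns: list[LesionAnnotation] = []
        for a in baseline_anns:
            c = a.polygon.vertices.mean(axis=0)
            scaled = Polygon2D((a.polygon.vertices - c) * growth + c)
            eval_anns.append(
                LesionAnnotation(
                    lesion_id=a.lesion_id,
                    patient_id=pid,
                    timepoint=Timepoint.EVAL1,
                    organ=a.organ,
                    polygon=scaled,
                )
            )
        n_new = 0
        if not is_responder and cfg.new_lesions_poisson_mean > 0:
            n_new = int(rng.poisson(cfg.new_lesions_poisson_mean))
            for j in range(n_new):
                organ = str(rng.choice(organs, p=organ_probs))
                radius = float(
                    rng.lognormal(cfg.lesion_radius_log_mean, cfg.lesion_radius_log_sd)
                )
                center = tuple(rng.uniform(-150.0, 150.0, size=2))
                poly = generate_lesion_polygon(
                    center, radius, cfg.polygon_irregularity, cfg.polygon_vertices, rng
                )
                eval_anns.append(
                    LesionAnnotation(
                        lesion_id=f"N{j + 1:03d}",
                        patient_id=pid,
                        timepoint=Timepoint.EVAL1,
                        organ=OrganLabel(organ),
                        polygon=poly,
                    )
                )

        measured_bl = filter_lesions(measure_lesions(baseline_anns))
        measured_e1 = filter_lesions(measure_lesions(eval_anns))
        vol_bl = sum(m.features.volume for m in measured_bl) / 1000.0
        vol_e1 = sum(m.features.volume for m in measured_e1) / 1000.0
        recist_bl, target_ids = _recist_target_sum(measured_bl)
        # the same reader re-measures the same targets at evaluation 1
        by_id_e1 = {m.annotation.lesion_id: m for m in measured_e1}
        recist_e1 = float(
            sum(
                by_id_e1[t].features.major_axis if t in by_id_e1
                # a target shrunk below the inclusion rules is measured anyway
                else next(
                    m.features.major_axis
                    for m in measure_lesions(eval_anns)
                    if m.annotation.lesion_id == t
                )
                for t in target_ids
            )
        )

        nlr_bl = float(rng.lognormal(cfg.nlr_log_mean, cfg.nlr_log_sd))
        drift_mu = cfg.nlr_drift_responder if is_responder else cfg.nlr_drift_progressor
        nlr_e1 = nlr_bl * float(np.exp(rng.normal(drift_mu, cfg.nlr_drift_sd)))
        lymph_bl = float(rng.lognormal(cfg.lymphocytes_log_mean, cfg.lymphocytes_log_sd))
        lymph_e1 = float(rng.lognormal(cfg.lymphocytes_log_mean, cfg.lymphocytes_log_sd))

        for tp, nlr, lymph, recist in (
            ("baseline", nlr_bl, lymph_bl, recist_bl),
            ("eval1", nlr_e1, lymph_e1, recist_e1),
        ):
            tp_rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "neutrophils": round(nlr * lymph, 4),
                    "lymphocytes": round(lymph, 4),
                    "recist_sum_mm": round(recist, 4),
                }
            )

        x_vol_high = 1.0 if vol_bl > cfg.volume_baseline_cutoff_cm3 else 0.0
        x_nlr_up = 1.0 if nlr_e1 > nlr_bl else 0.0
        x_vol_up = 1.0 if vol_e1 > vol_bl else 0.0
        lp = (
            cfg.log_hr_volume_baseline_high * x_vol_high
            + cfg.log_hr_nlr_increase * x_nlr_up
            + cfg.log_hr_volume_increase * x_vol_up
        )
        os_out = simulate_survival(lp, cfg.os_baseline_rate, cfg.os_censor_rate, rng)
        pfs_out = simulate_survival(lp, cfg.pfs_baseline_rate, cfg.pfs_censor_rate, rng)

        age = int(np.clip(rng.normal(62, 11), 25, 90))
        sex = "male" if rng.random() < 29 / 61 else "female"
        treatment = "anti-PD-1" if rng.random() < 26 / 61 else "anti-PD-L1"
        outcome_rows.append(
            {
                "patient_id": pid,
                "os_months": round(os_out.time, 4),
                "os_event": os_out.event,
                "pfs_months": round(pfs_out.time, 4),
                "pfs_event": pfs_out.event,
                "tumor_type": tumor_type,
                "age": age,
                "sex": sex,
                "treatment": treatment,
            }
        )
        annotations.extend(baseline_anns)
        annotations.extend(eval_anns)
        truth[pid] = {
            "response_class": "responder" if is_responder else "progressor",
            "growth_multiplier": round(growth, 6),
            "linear_predictor": round(lp, 6),
            "covariates": {
                "volume_baseline_high": x_vol_high,
                "nlr_increase": x_nlr_up,
                "volume_increase": x_vol_up,
            },
            "volume_baseline_cm3": round(vol_bl, 4),
            "volume_eval1_cm3": round(vol_e1, 4),
            "n_new_lesions": n_new,
        }

    return SyntheticCohort(
        config=cfg,
        annotations=annotations,
        timepoint_table=pd.DataFrame(tp_rows),
        outcomes=pd.DataFrame(outcome_rows),
        ground_truth={
            "config": json.loads(cfg.model_dump_json()),
            "patients": truth,
        },
    )
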