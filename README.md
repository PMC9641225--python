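# mmrd-burden

Tumor-burden biomarker analysis for patients with mismatch-repair-deficient
(MMRD/MSI) metastatic tumors treated with anti-PD-(L)1 immunotherapy.

Response to checkpoint blockade is highly heterogeneous across MMRD tumors,
and standard RECIST 1.1 evaluation tracks at most five target lesions. This
package implements an alternative: an expert annotates *every* lesion once,
as a freehand contour on the axial slice where it is largest, and the
package turns those single-slice contours into an approximate total tumor
volume, combines it with the neutrophil-to-lymphocyte ratio (NLR) and the
RECIST diameter sum, and stratifies patients by survival. It is written for
biostatisticians and imaging researchers who want to run or stress-test
this kind of burden analysis end to end, including on synthetic cohorts.

## The model

For a lesion contour with in-plane area *A* (mm²) and interior-covariance
eigenvalues λ₁ ≥ λ₂, the principal axes are `major = 4·√λ₁`,
`minor = 4·√λ₂`, and the approximate lesion volume is

    V = (2/3) · A · minor

which is exact for a sphere: (2/3)·(πr²)·(2r) = (4/3)πr³. The per-patient
**total tumor volume** is the sum over all retained lesions (lymph nodes
count only above 10 mm short axis; lung micronodules only above 3 mm).

Five parameters are computed at baseline and first evaluation — Volume,
RECIST sum of target diameters, NLR, lesion count, organ count — each with
its percent **variation** (E1 − BL)/BL × 100, binarized to increase (>0%)
vs decrease. Baseline values are split at fixed cutoffs (90 cm³, 55 mm,
NLR 5, 10 lesions, 3 organs; or cohort medians rounded to the nearest
integer). The **concordance score** of two variations (Volume×NLR,
RECIST×NLR) is mutual increase / mutual decrease / discordant. Groups are
compared with Kaplan–Meier estimates (Greenwood 95% bands), Mantel–Cox
log-rank tests (pairwise, unadjusted), Cox proportional-hazards fits
(Efron ties), and Spearman independence screening (|ρ| < 0.8).

## Worked example

`examples/04_full_pipeline.py` generates a synthetic 61-patient cohort
with hazards planted on three indicators (baseline volume > 90 cm³, NLR
increase, volume increase) and runs the full analysis:

```
generated 61 patients, 4600 lesion annotations

baseline univariate (OS):
  volume      (high/low n=35/26, cutoff 90): log-rank p=0.008528
  recist_sum  (high/low n=57/4, cutoff 55): log-rank p=0.1639
  nlr         (high/low n=15/46, cutoff 5): log-rank p=0.8208
  ...

concordance volume x NLR (OS):
  discordant       n=10, KM median = 19.3128 months
  mutual_decrease  n=25, KM median = 80.4098 months
  mutual_increase  n=26, KM median = 4.405 months
  pairwise mutual_decrease vs mutual_increase: p=0
```

High baseline volume separates survival (p≈0.009) while baseline NLR does
not, and the concordance categories order exactly as planted: mutual
decrease of volume and NLR has the longest median OS, mutual increase the
shortest. The other examples show the geometry (`01`), the biomarker table
(`02`) and the survival estimators (`03`) in isolation.

A CLI wraps the same functions:

```sh
synth-cohort --seed 7 --out cohort/
mmrd-burden run --annotations cohort/annotations.jsonl \
  --tables cohort/blood_recist.csv --outcomes cohort/outcomes.csv --out report/
mmrd-burden features --annotations cohort/annotations.jsonl --out lesions.csv
```

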