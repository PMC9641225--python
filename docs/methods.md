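# Methods

## Single-slice volumetry

Each lesion is represented by one closed polygon in physical millimetres
on the axial slice of largest extent. The enclosed area is the absolute
value of the *signed* triangle-fan sum about the centroid, which
telescopes to the shoelace formula and is exact for any simple polygon —
including the non-convex contours freehand annotation produces, where a
per-triangle absolute-value sum would overcount re-entrant regions.

The principal axes come from the covariance of the uniform distribution
over the polygon interior, computed from the exact Green's-theorem moment
integrals (not from a rasterized mask): with eigenvalues λ₁ ≥ λ₂ the axes
are 4√λ₁ and 4√λ₂. For an ellipse with semi-axes a ≥ b this gives exactly
(2a, 2b); for a square of side w, 4w/√12. Being continuous, the
computation is resolution-independent, and the test suite checks it
against a 0.1 mm pixel-counting oracle (agreement within 2%) so that a
mask-based pipeline at fine spacing would produce the same numbers.

The approximate 3D volume is V = (2/3)·A·minor. The factor is fixed by the
sphere: a circular ROI of radius r gives (2/3)(πr²)(2r) = (4/3)πr³. For an
elongated lesion (ellipse a, b) it yields (4/3)πab², the prolate spheroid
of revolution about the major axis — the implicit solid-shape assumption
of the method. Elongated *flat* lesions are therefore underestimated; this
is inherent to single-slice volumetry, not to the implementation.

Degenerate contours (collinear, zero area) yield zero features and are
removed with a logged warning rather than raising, since a single bad
annotation should not abort a cohort run. Inclusion rules are strict
inequalities: lymph nodes are lesions only when the minor axis exceeds
10 mm (the RECIST short-axis analogue), lung micronodules only when the
major axis exceeds 3 mm.

## Patient-level parameters

Volume (cm³, converted from mm³ only at aggregation), RECIST diameter sum
(mm, consumed from the reader's table — never recomputed from contours),
NLR (neutrophils/lymphocytes, undefined and an error when lymphocytes are
zero), lesion count and organ count (distinct labels among 16). Variation
is (E1 − BL)/BL × 100; a zero baseline makes the variation undefined and
excludes the patient from that parameter's variation analysis (counted and
warned, never silently dropped). Exact-zero variation is pooled with
"decrease": only the sign is analysed, and "did not increase" is the
conservative grouping for a risk marker; ties are counted and warned.

Baseline binarization uses strict `value > cutoff` for the high-risk
group. Default cutoffs are 90 cm³ (volume), 55 mm (RECIST sum — stored in
mm so the nearest-integer rule is self-consistent), 5 (NLR, a literature
cutoff that is never recomputed), 10 (lesions) and 3 (organs). A config
switch recomputes the four non-NLR cutoffs as cohort medians rounded half
away from zero; fixed cutoffs are the default so reports are comparable
across cohorts.

## Survival analysis

Product-limit estimator over distinct event times, with subjects censored
exactly at an event time kept in that risk set. Confidence bands use the
Greenwood variance on the log-survival scale, exp(log S ± z·σ̂), clipped to
[0, 1]. The k-group log-rank statistic is the quadratic form of the summed
observed-minus-expected vector against the summed hypergeometric
covariance (first k−1 groups, pseudo-inverse for safety); pairwise tests
are reported unadjusted, with an optional Bonferroni switch, because the
three-way concordance comparison is conventionally reported raw. The Cox
model maximises the Efron-approximated partial likelihood by Newton
iteration with step-halving, converging at 1e-7 relative log-likelihood
change (flagged, not raised, on non-convergence); Wald CIs and p-values
come from the observed information. Constant covariates and designs with
fewer events than covariates are rejected by name. All three estimators
are validated against hand-computed fixtures and cross-checked against
lifelines to ~1e-9; the Cox score test at β = 0 reproduces the log-rank
chi-square on tie-free data to 1e-6.

Spearman screening uses average ranks, pairwise-complete observations, and
flags |ρ| ≥ 0.8 as non-independent; a constant column yields an undefined
(NaN → null) coefficient rather than an error.

## Synthetic cohort generator

The generator emulates the structure of a ~61-patient retrospective MMRD
cohort: the tumor-type mix (26 colorectal, 13 endometrial, 7 gastric, 5
small intestine, 2×4, 1×2 of 61), ~35 lesions per patient on average
(negative binomial, dispersion 3, so a 61-patient cohort carries roughly
1 700–2 500 baseline lesions), a 51% responder fraction, and about half of
OS records right-censored. Per patient, 1 + Poisson(2.2) organs are
involved (weighted toward liver, nodes, lung, peritoneum) and lesions are
distributed among them by a Dirichlet draw; lesion radii are log-normal
(median 6.5 mm, σ = 0.5), which lands the median baseline total volume
near the 90 cm³ cutoff. Contours are star-convex polygons with
mean-preserving uniform radius noise (irregularity 0.15, 32 vertices).

Responders rescale their lesions by a log-normal linear factor with median
0.80, progressors by 1.15 (volume changes as the cube), and only
progressors seed Poisson(1.5) new lesions. NLR is log-normal (median 4)
with a response-linked log-drift (−0.25 responders, +0.25 progressors,
σ = 0.3), so variation directions correlate with, but are not determined
by, the latent class. RECIST sums use a simplified consistent reader:
largest measurable lesions (major axis > 10 mm; nodes > 15 mm short axis),
at most 2 per organ and 5 in total, re-measured at evaluation 1.

Survival is exponential proportional hazards on three indicators computed
from the generated data itself — baseline volume > 90 cm³ (HR 3.2), NLR
increase (HR 2.9), volume increase (HR 2.0) — with baseline OS/PFS medians
of 60 and 12 months at zero linear predictor and independent exponential
censoring (rates 0.045 and 0.10 per month). PFS events are generated
directly from the same linear predictor, not derived from RECIST
thresholds, because progression calls are reader-defined in practice;
synthetic PFS therefore exercises the statistics, not the RECIST
definition of progression.

What passing synthetic tests does *not* show: real contours are not
star-convex with uniform noise; real organ-count variation is more
dynamic (in synthetic cohorts organ count almost never changes between
timepoints, so its variation analysis is structurally uninformative);
real NLR has infection- and drug-driven excursions; and real RECIST
target selection varies across readers. The generator demonstrates
calibration and recovery of the machinery, not clinical effect sizes.

## Problem sizes and numerical choices

The calibration studies run at the cohort's own scale: log-rank type-I
error over 1 000 replicates of two exponential groups of 30 with ~30%
censoring; Cox recovery of a planted HR 3.2 over 500 replicates at n = 61
with ~45% censoring (the mean of exp(β̂) at this size carries a small
upward Jensen bias, ~3.6 vs 3.2, with CI coverage ≈ 95%); concordance
separation over 100 generated cohorts; planted-HR convergence checked at
n = 500. Determinism is enforced end to end: a single `numpy` Generator
per cohort seed, fixed float formatting in all writers, sorted JSON keys,
and no timestamps, so identical config + seed reproduce byte-identical
files.

## Known limitations

Single-slice volumes are approximations (prolate-spheroid assumption);
the pipeline has no pseudo-progression handling; Cox covariates default to
the binarized indicators (a continuous option exists at the API level via
`cox_fit` but the report uses indicators); and the multivariate Cox fits
all five parameters regardless of the Spearman screen, which is reported
alongside for the analyst to judge.
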