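"""Kaplan-Meier, log-rank and Cox PH on simulated two-arm survival data.

Draws a high-burden arm with twice the hazard of the low-burden arm,
estimates the KM medians, tests the separation, and recovers the hazard
ratio with a Cox fit.
"""

import math

import numpy as np

from mmrd_burden.survival import SurvivalOutcome, cox_fit, km_estimate, logrank_test
from mmrd_burden.synthetic import simulate_survival

rng = np.random.default_rng(12)
true_hr = 2.0
n_per_arm = 60

arms = {}
for label, lp in (("low burden", 0.0), ("high burden", math.log(true_hr))):
    arms[label] = [simulate_survival(lp, 0.05, 0.02, rng) for _ in range(n_per_arm)]
    km = km_estimate(arms[label])
    events = sum(o.event for o in arms[label])
    print(
        f"{label:<12} n={n_per_arm}, events={events}, "
        f"KM median = {km.median():.1f} months"
    )

lr = logrank_test([arms["low burden"], arms["high burden"]])
print(f"\nlog-rank: chi^2 = {lr.chi_square:.2f}, p = {lr.p_value:.4g}")

x = [0.0] * n_per_arm + [1.0] * n_per_arm
outcomes = arms["low burden"] + arms["high burden"]
fit = cox_fit({"high_burden": x}, outcomes)
hr = fit.hazard_ratio[0]
print(
    f"Cox: HR = {hr:.2f} [{fit.ci_lower[0]:.2f}, {fit.ci_upper[0]:.2f}], "
    f"p = {fit.p_value[0]:.4g} (true HR {true_hr})"
)
# The estimated HR should be near 2 with the CI covering the truth; the
# log-rank p-value quantifies the KM curve separation.
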