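"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, Spearman screening.

The estimators are implemented directly (product-limit, Mantel-Cox sums,
Efron partial likelihood) so that small fixtures can be checked against
hand computations; an external survival library serves only as a
cross-check in the test suite.

Conventions
-----------
* Times are in months, strictly positive; ``event`` is 1 for an observed
  event and 0 for right-censoring.
* Subjects censored exactly at an event time are still at risk for that
  time (the standard convention).
* Kaplan-Meier confidence bands use the Greenwood variance on the log
  survival scale, clipped to [0, 1].
* Tied event times in the Cox model use the Efron approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalOutcome",
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "CorrelationScreen",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "cox_fit",
    "spearman_screen",
]


@dataclass(frozen=True)
class SurvivalOutcome:
    """Follow-up time in months with event indicator (0 = right-censored)."""

    time: float
    event: int

    def __post_init__(self):
        if not (self.time > 0 and np.isfinite(self.time)):
            raise ValueError("time must be finite and positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _to_arrays(outcomes: Sequence[SurvivalOutcome]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([o.time for o in outcomes], dtype=float)
    e = np.array([o.event for o in outcomes], dtype=int)
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function with 95% Greenwood band."""

    event_times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) just after each event time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray  # at-risk count just before each event time

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step evaluation."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; NaN if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("nan")


def km_estimate(outcomes: Sequence[SurvivalOutcome], ci_level: float = 0.95) -> KMCurve:
    """Product-limit survival estimate over the distinct event times."""
    if len(outcomes) == 0:
        raise ValueError("km_estimate needs at least one outcome")
    t, e = _to_arrays(outcomes)
    times = np.unique(t[e == 1])
    surv = np.empty(len(times))
    var_log = np.empty(len(times))  # Greenwood sum for var(log S)
    lo = np.empty(len(times))
    hi = np.empty(len(times))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    s, g = 1.0, 0.0
    for i, ti in enumerate(times):
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            g += d_i / (n_i * (n_i - d_i))
        surv[i] = s
        var_log[i] = g
        if s > 0:
            half = z * np.sqrt(g)
            lo[i] = s * np.exp(-half)
            hi[i] = min(1.0, s * np.exp(half))
        else:
            lo[i] = hi[i] = 0.0
    n_at_risk = np.array([int(np.sum(t >= ti)) for ti in times])
    return KMCurve(times, surv, np.clip(lo, 0.0, 1.0), np.clip(hi, 0.0, 1.0), n_at_risk)


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    dof: int
    p_value: float


def logrank_test(groups: Sequence[Sequence[SurvivalOutcome]]) -> LogRankResult:
    """Mantel-Cox log-rank test across k >= 2 groups, (k-1) dof.

    At each distinct event time the observed event counts per group are
    compared with their hypergeometric expectation given the at-risk sets;
    the quadratic form of the summed O-E against the summed covariance
    gives the chi-square statistic.
    """
    k = len(groups)
    if k < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    ts, es, gs = [], [], []
    for gi, g in enumerate(groups):
        t, e = _to_arrays(g)
        ts.append(t)
        es.append(e)
        gs.append(np.full(len(t), gi))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)
    if e.sum() == 0:
        raise ValueError("log-rank statistic undefined with no events")
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = at_risk.sum()
        d = int(((t == ti) & (e == 1)).sum())
        n_g = np.array([(at_risk & (g == gi)).sum() for gi in range(k)], dtype=float)
        d_g = np.array(
            [((t == ti) & (e == 1) & (g == gi)).sum() for gi in range(k)], dtype=float
        )
        frac = n_g / n
        o_minus_e += d_g - d * frac
        if n > 1:
            scale = d * (n - d) / (n - 1)
            cov += scale * (np.diag(frac) - np.outer(frac, frac))
    dof = k - 1
    v = cov[:dof, :dof]
    u = o_minus_e[:dof]
    chi2 = float(u @ np.linalg.pinv(v) @ u)
    chi2 = max(chi2, 0.0)
    return LogRankResult(chi2, dof, float(stats.chi2.sf(chi2, dof)))


def pairwise_logrank(
    groups: Mapping[str, Sequence[SurvivalOutcome]],
    bonferroni: bool = False,
) -> dict[tuple[str, str], LogRankResult]:
    """One two-group log-rank test per unordered pair of categories.

    P-values are unadjusted by default; ``bonferroni=True`` multiplies each
    by the number of pairs (capped at 1).  Both key orders are present in
    the returned mapping.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 categories")
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    out: dict[tuple[str, str], LogRankResult] = {}
    for a, b in pairs:
        r = logrank_test([groups[a], groups[b]])
        if bonferroni:
            r = LogRankResult(r.chi_square, r.dof, min(1.0, r.p_value * len(pairs)))
        out[(a, b)] = out[(b, a)] = r
    return out


@dataclass(frozen=True)
class CoxResult:
    """Cox proportional-hazards fit: per-covariate Wald table."""

    names: list[str]
    coef: np.ndarray  # log hazard ratios
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_value: np.ndarray
    n_events: int
    converged: bool
    log_likelihood: float

    def summary_dict(self) -> dict:
        return {
            name: {
                "coef": float(self.coef[i]),
                "hr": float(self.hazard_ratio[i]),
                "ci_lower": float(self.ci_lower[i]),
                "ci_upper": float(self.ci_upper[i]),
                "p": float(self.p_value[i]),
            }
            for i, name in enumerate(self.names)
        }


def _efron_loglik_grad_hess(
    beta: np.ndarray, x: np.ndarray, t: np.ndarray, e: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron-approximated partial log-likelihood with gradient and Hessian."""
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for ti in np.unique(t[e == 1]):
        risk = t >= ti
        dead = (t == ti) & (e == 1)
        d = int(dead.sum())
        s0 = w[risk].sum()
        s1 = w[risk] @ x[risk]
        s2 = (w[risk, None] * x[risk]).T @ x[risk]
        wd = w[dead].sum()
        sd1 = w[dead] @ x[dead]
        sd2 = (w[dead, None] * x[dead]).T @ x[dead]
        ll += eta[dead].sum()
        grad += x[dead].sum(axis=0)
        for l in range(d):
            f = l / d
            denom = s0 - f * wd
            num1 = s1 - f * sd1
            num2 = s2 - f * sd2
            ll -= np.log(denom)
            grad -= num1 / denom
            hess -= num2 / denom - np.outer(num1, num1) / denom**2
    return ll, grad, hess


def cox_fit(
    covariates: Mapping[str, Sequence[float]] | np.ndarray,
    outcomes: Sequence[SurvivalOutcome],
    names: Sequence[str] | None = None,
    ci_level: float = 0.95,
    tol: float = 1e-7,
    max_iter: int = 50,
) -> CoxResult:
    """Fit a Cox PH model by Newton iteration on the Efron partial likelihood.

    ``covariates`` is either a name -> values mapping or an (n, p) array
    with ``names``.  Covariates should be binary or standardized continuous;
    a zero-variance column raises, since its coefficient is unidentified.
    Non-convergence within ``max_iter`` is flagged, not raised.
    """
    if isinstance(covariates, Mapping):
        names = list(covariates)
        x = np.column_stack([np.asarray(covariates[c], dtype=float) for c in names])
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = list(names) if names is not None else [f"x{i}" for i in range(x.shape[1])]
    t, e = _to_arrays(outcomes)
    if x.shape[0] != len(t):
        raise ValueError("covariate rows must match number of outcomes")
    for j, name in enumerate(names):
        if np.ptp(x[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant; coefficient unidentified")
    n_events = int(e.sum())
    if n_events < x.shape[1]:
        raise ValueError("fewer events than covariates")

    beta = np.zeros(x.shape[1])
    ll, grad, hess = _efron_loglik_grad_hess(beta, x, t, e)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving safeguards against overshoot (near-separation)
        alpha = 1.0
        for _ in range(30):
            new_beta = beta + alpha * step
            new_ll, new_grad, new_hess = _efron_loglik_grad_hess(new_beta, x, t, e)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            alpha /= 2.0
        rel = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if rel < tol:
            converged = True
            break
    info = -hess
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    zscores = beta / se
    with np.errstate(over="ignore"):
        ci_lo, ci_hi = np.exp(beta - z * se), np.exp(beta + z * se)
    return CoxResult(
        names=names,
        coef=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_value=2.0 * stats.norm.sf(np.abs(zscores)),
        n_events=n_events,
        converged=converged,
        log_likelihood=float(ll),
    )


@dataclass(frozen=True)
class CorrelationScreen:
    """Spearman correlation matrix with an independence flag per pair."""

    names: list[str]
    matrix: np.ndarray
    threshold: float
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def spearman_screen(
    data: Mapping[str, Sequence[float]], threshold: float = 0.8
) -> CorrelationScreen:
    """Rank correlation on every variable pair; |rho| >= threshold flags
    the pair as non-independent (ties get average ranks).

    Rows with a missing value in a pair are dropped pairwise; every pair
    needs >= 3 complete observations.
    """
    names = list(data)
    cols = [np.asarray(data[c], dtype=float) for c in names]
    k = len(names)
    mat = np.eye(k)
    flagged: list[tuple[str, str, float]] = []
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(cols[i]) & np.isfinite(cols[j])
            if ok.sum() < 3:
                raise ValueError(
                    f"need >= 3 complete observations for ({names[i]}, {names[j]})"
                )
            with warnings.catch_warnings():
                # a constant column has no rank correlation; report NaN
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                rho = float(stats.spearmanr(cols[i][ok], cols[j][ok]).statistic)
            mat[i, j] = mat[j, i] = rho
            if np.isfinite(rho) and abs(rho) >= threshold:
                flagged.append((names[i], names[j], rho))
    return CorrelationScreen(names, mat, threshold, flagged)
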