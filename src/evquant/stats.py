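"""Cohort statistics: rank tests, ROC analysis, power, and survival.

Standard tests are delegated to scipy/scikit-learn where they exist
(Mann-Whitney U, empirical ROC).  DeLong's correlated-AUC comparison, the
product-limit estimator, the two-group log-rank test (Breslow tie
handling), and maximally selected log-rank dichotomization are implemented
here; the survival routines are cross-checked against lifelines in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve


# ---------------------------------------------------------------------------
# rank tests and ROC
# ---------------------------------------------------------------------------

def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U of x vs y.

    The p-value is exact (full enumeration) for combined n <= 12 without
    ties, and a tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) + len(y) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC over all distinct thresholds.

    The trapezoidal AUC equals the Mann-Whitney identity U/(n1*n2); the
    standard error is Hanley-McNeil.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc ** 2)
        + (n0 - 1) * (q2 - auc ** 2)
    ) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        auc_se=se,
        ci95=(max(lo, 0.0), min(hi, 1.0)),
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    r_all = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # structural components over cases
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # over controls
    return auc, v10, v01


def compare_rocs(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> float:
    """DeLong two-sided test for two correlated (paired) AUCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("paired score vectors must align with labels")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def power_two_sample(n1: int, n2: int, effect_size_d: float, alpha: float = 0.05) -> float:
    """Normal-approximation power of a two-sided two-sample comparison.

    power = Phi(|d| * sqrt(n1 n2 / (n1+n2)) - z_{1-a/2})
          + Phi(-|d| * sqrt(n1 n2 / (n1+n2)) - z_{1-a/2})
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    delta = abs(effect_size_d) * np.sqrt(n1 * n2 / (n1 + n2))
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.sf(z - delta) + sps.norm.cdf(-z - delta))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    times: np.ndarray  # ascending observed event times
    survival: np.ndarray  # product-limit S(t) at those times
    greenwood_se: np.ndarray
    logrank_stat: float | None = None
    logrank_p: float | None = None


def km_fit(times: Sequence[float], events: Sequence[int]) -> SurvivalFit:
    """Kaplan-Meier product-limit estimator with Greenwood standard errors.

    Right-censoring is honored; the curve is reported at observed event
    times only (all-censored input yields an empty step list, S == 1).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv = []
    se = []
    s = 1.0
    gw = 0.0  # running sum d / (n (n - d))
    for ti in event_times:
        n_at_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            gw += d / (n_at_risk * (n_at_risk - d))
            se.append(s * np.sqrt(gw))
        else:
            se.append(0.0)
        surv.append(s)
    return SurvivalFit(
        times=event_times,
        survival=np.asarray(surv),
        greenwood_se=np.asarray(se),
    )


def _logrank_stat(
    times: np.ndarray, events: np.ndarray, in_a: np.ndarray
) -> tuple[float, float, float]:
    """(O - E, V, chi2) of the two-group log-rank with Breslow tie handling."""
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = times >= ti
        n = int(at_risk.sum())
        if n < 2:
            continue
        n_a = int((at_risk & in_a).sum())
        dead = (times == ti) & (events == 1)
        d = int(dead.sum())
        d_a = int((dead & in_a).sum())
        frac = n_a / n
        o_minus_e += d_a - d * frac
        var += d * frac * (1.0 - frac) * (n - d) / (n - 1)
    chi2 = (o_minus_e ** 2 / var) if var > 0 else 0.0
    return o_minus_e, var, chi2


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its two-sided p-value."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined", stacklevel=2)
        return 0.0, 1.0
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.zeros(len(times), dtype=bool)
    in_a[: len(ta)] = True
    _, _, chi2 = _logrank_stat(times, events, in_a)
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


@dataclass
class SurvivalCutoffResult:
    cutoff: float
    logrank_stat: float
    logrank_p: float  # unadjusted for the threshold scan
    n_candidates: int
    multiplicity_warning: bool = True

    @property
    def significant(self) -> bool:
        return self.logrank_p < 0.05


def survival_cutoff(
    marker_values: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    quantile_range: tuple[float, float] = (0.1, 0.9),
) -> SurvivalCutoffResult:
    """Maximally selected log-rank dichotomization of a marker.

    Scans candidate thresholds restricted to the inner quantile range of
    the marker, splitting at value > threshold, and returns the threshold
    maximizing the log-rank statistic (ties: lowest threshold).  The
    reported p-value is unadjusted for the scan (maxstat multiplicity);
    the result carries a warning flag.
    """
    x = np.asarray(marker_values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(x) < 10:
        raise ValueError("at least 10 subjects required")
    if e.sum() < 2:
        raise ValueError("at least 2 events required")
    if np.ptp(x) == 0:
        raise ValueError("marker values are all identical")
    lo, hi = np.quantile(x, quantile_range)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    best = None
    n_scanned = 0
    for c in candidates:
        in_high = x > c
        if not in_high.any() or in_high.all():
            continue
        n_scanned += 1
        _, _, chi2 = _logrank_stat(t, e, in_high)
        if best is None or chi2 > best[0] + 1e-12:
            best = (chi2, float(c))
    if best is None:
        raise ValueError("no admissible threshold in the quantile range")
    chi2, cutoff = best
    return SurvivalCutoffResult(
        cutoff=cutoff,
        logrank_stat=float(chi2),
        logrank_p=float(sps.chi2.sf(chi2, df=1)),
        n_candidates=n_scanned,
    )
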