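"""Survival stratification and the rank tests used around it.

The stratification follows the conventions of classical two-group
time-to-event analysis as implemented in common clinical-statistics
software: scores are dichotomized at the cohort median; curves are
Kaplan–Meier product-limit estimates; the two-sided comparison is the
Mantel–Cox log-rank test; and the hazard ratio is the O/E
(Mantel–Haenszel-style) estimator

    HR = (O1/E1) / (O2/E2),   CI95 = exp(log HR ± 1.96 * sqrt(1/E1 + 1/E2))

accumulated over the distinct event times with hypergeometric variance.
Cox regression is deliberately not used: the statistical arm is a
univariate stratification.  At tied times events precede censorings
(censored subjects remain at risk for events at their own time).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSplitError, UndefinedHazardRatioError

ALPHA = 0.05  # significance convention throughout


# ---------------------------------------------------------------------------
# median dichotomization
# ---------------------------------------------------------------------------

def dichotomize_median(values) -> tuple[np.ndarray, float, int]:
    """Split scores at the median: value > median -> "high", else "low".

    Missing values (NaN) are excluded from the median and labeled ``""``.
    Returns ``(labels, median, n_missing)``.

    Raises
    ------
    DegenerateSplitError
        When all non-missing values are identical (no split exists).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n_missing = int((~finite).sum())
    usable = values[finite]
    if usable.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.ptp(usable) == 0:
        raise DegenerateSplitError("all values identical; median split undefined")
    median = float(np.median(usable))
    labels = np.where(values > median, "high", "low")
    labels[~finite] = ""
    return labels, median, n_missing


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Product-limit estimate: survival just after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    n_subjects: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if out.size > 1 else out[0]

    def steps(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, survival) coordinates of the step plot, starting at (0, 1)."""
        t = np.concatenate([[0.0], np.repeat(self.event_times, 2)])
        s = np.concatenate([[1.0, 1.0],
                            np.repeat(self.survival, 2)[:-1]]) \
            if self.event_times.size else np.array([1.0])
        return t, s


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Kaplan–Meier product-limit estimator.

    ``events`` is 1 for an observed event, 0 for right-censoring.  Censored
    subjects reduce later risk sets but introduce no step; at tied times
    they stay at risk for the events at that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    event_times = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
    return KaplanMeierCurve(event_times=event_times,
                            survival=np.asarray(surv),
                            n_subjects=int(times.size))


# ---------------------------------------------------------------------------
# log-rank test and O/E hazard ratio
# ---------------------------------------------------------------------------

def _two_group_oe(groups, times, events, group_order=None):
    """Observed/expected events and hypergeometric variance per group."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if group_order is None:
        group_order = np.unique(groups)
    group_order = list(group_order)
    if len(group_order) != 2:
        raise ValueError(f"exactly 2 groups required, got {group_order}")
    g1 = groups == group_order[0]
    g2 = groups == group_order[1]
    if not g1.any() or not g2.any():
        raise ValueError("each group needs at least one subject")

    o = np.array([0.0, 0.0])
    e = np.array([0.0, 0.0])
    v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n1 = int((at_risk & g1).sum())
        n2 = int((at_risk & g2).sum())
        nj = n1 + n2
        d1 = int((g1 & (times == t) & (events == 1)).sum())
        d2 = int((g2 & (times == t) & (events == 1)).sum())
        dj = d1 + d2
        o += (d1, d2)
        e += (dj * n1 / nj, dj * n2 / nj)
        if nj > 1:
            v += dj * (n1 / nj) * (n2 / nj) * (nj - dj) / (nj - 1)
    return o, e, v, group_order


def logrank_test(groups, times, events, group_order=None
                 ) -> tuple[float, float]:
    """Two-group Mantel–Cox log-rank test.

    Returns ``(chi2, p)`` with chi2 = (O1 - E1)^2 / V and p from a
    chi-square distribution with 1 df.  Zero events in total yields
    ``(0.0, 1.0)``.
    """
    o, e, v, _ = _two_group_oe(groups, times, events, group_order)
    if o.sum() == 0 or v == 0:
        return 0.0, 1.0
    chi2 = (o[0] - e[0]) ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def hazard_ratio_logrank(groups, times, events, group_order=None
                         ) -> tuple[float, tuple[float, float]]:
    """O/E hazard ratio of group 1 vs group 2 with a 95% CI.

    Raises
    ------
    UndefinedHazardRatioError
        When either group's expected or observed event count is zero.
    """
    o, e, v, order = _two_group_oe(groups, times, events, group_order)
    if e[0] == 0 or e[1] == 0 or o[0] == 0 or o[1] == 0:
        raise UndefinedHazardRatioError(
            f"degenerate event pattern for groups {order}: O={o}, E={e}")
    hr = (o[0] / e[0]) / (o[1] / e[1])
    half = 1.96 * math.sqrt(1.0 / e[0] + 1.0 / e[1])
    ci = (hr * math.exp(-half), hr * math.exp(half))
    return float(hr), ci


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _u_statistic(x, y) -> float:
    """U for sample x (number of (x, y) pairs with x > y, ties count 1/2).

    Complete separation of x below y gives U = 0.
    """
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((x > y).sum() + 0.5 * (x == y).sum())


def mann_whitney(x, y, exact_max: int = 8) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses exact enumeration of all group assignments when the smaller
    sample has at most ``exact_max`` observations and the data are free of
    ties; otherwise the normal approximation with tie correction.  Returns
    ``(U, p)`` where U is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples need at least one observation")
    n, m = x.size, y.size
    u_x = _u_statistic(x, y)
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size

    if min(n, m) <= exact_max and not has_ties:
        # enumerate all C(n+m, n) assignments of the pooled values
        u_min_obs = min(u_x, n * m - u_x)
        count = 0
        total = 0
        idx_all = range(n + m)
        for comb in itertools.combinations(idx_all, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(combined[mask], combined[~mask])
            total += 1
            if min(u, n * m - u) <= u_min_obs:
                count += 1
        p = count / total
    else:
        mu = n * m / 2.0
        nn = n + m
        _, t_counts = np.unique(combined, return_counts=True)
        tie_term = ((t_counts ** 3 - t_counts).sum()) / (nn * (nn - 1))
        sigma2 = n * m / 12.0 * ((nn + 1) - tie_term)
        if sigma2 <= 0:
            return u_x, 1.0
        z = (u_x - mu) / math.sqrt(sigma2)
        p = 2.0 * stats.norm.sf(abs(z))
    return u_x, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Dunn's post test
# ---------------------------------------------------------------------------

def kruskal_dunn(samples: list) -> tuple[float, float, dict]:
    """Tie-corrected Kruskal–Wallis H with Dunn's pairwise post test.

    ``samples`` is a list of k >= 3 groups (each with >= 2 observations).
    Returns ``(H, p, pairwise)`` where ``pairwise[(i, j)]`` is Dunn's
    Bonferroni-adjusted two-sided p for groups i and j (indices into
    ``samples``).
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 groups")
    samples = [np.asarray(s, dtype=float) for s in samples]
    for s in samples:
        if s.size < 2:
            raise ValueError("each group needs at least 2 observations")
    sizes = np.array([s.size for s in samples])
    pooled = np.concatenate(samples)
    nn = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rank_sums = np.array([ranks[bounds[i]:bounds[i + 1]].sum()
                          for i in range(len(samples))])

    h = 12.0 / (nn * (nn + 1)) * (rank_sums ** 2 / sizes).sum() - 3 * (nn + 1)
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_sum = (t_counts ** 3 - t_counts).sum()
    correction = 1.0 - tie_sum / (nn ** 3 - nn)
    if correction == 0:
        # all observations identical: no evidence against the null
        return 0.0, 1.0, {pair: 1.0 for pair in
                          itertools.combinations(range(len(samples)), 2)}
    h /= correction
    p = float(stats.chi2.sf(h, df=len(samples) - 1))

    mean_ranks = rank_sums / sizes
    n_pairs = len(samples) * (len(samples) - 1) // 2
    base_var = nn * (nn + 1) / 12.0 - tie_sum / (12.0 * (nn - 1))
    pairwise = {}
    for i, j in itertools.combinations(range(len(samples)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairwise[(i, j)] = float(min(1.0, 2.0 * stats.norm.sf(z) * n_pairs))
    return float(h), p, pairwise
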