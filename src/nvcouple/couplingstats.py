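"""Neurovascular coupling estimation and group statistics.

Per-subject coupling is the ordinary-least-squares line mapping peak gamma
change (%) to a hemodynamic response measure over the 10 contrast × eye
points; the gradient is the coupling measure.  Group comparisons of medians
use the exact Mann–Whitney U test (null distribution enumerated over rank
assignments, midranks for ties), with Holm–Bonferroni control of the
family-wise error rate.  Contrast-response profiles are compared with a
two-way mixed ANOVA (between: group; within: contrast) with the
Greenhouse–Geisser sphericity correction and follow-up simple main effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats


@dataclass
class CouplingFit:
    subject: str
    measure: str          # e.g. "bold_pct", "cbf_pct", "cbf_quant"
    gradient: float       # hemodynamic units per % gamma change
    intercept: float
    n_points: int
    r_squared: float


@dataclass
class GroupTestResult:
    statistic: float      # U or F
    p: float
    method: str
    df: tuple | None = None
    epsilon: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def fit_coupling(gamma, hemo, measure: str = "", subject: str = ""
                 ) -> CouplingFit:
    """OLS line through (gamma %, hemodynamic) points for one subject.

    Ten points (5 contrasts × 2 eyes) are expected; fewer are accepted with
    a warning (e.g. a subject with one unusable eye contributes five).
    """
    gamma = np.asarray(gamma, float)
    hemo = np.asarray(hemo, float)
    if gamma.shape != hemo.shape or gamma.ndim != 1:
        raise ValueError("gamma and hemodynamic values must be 1-D and match")
    if len(gamma) < 3:
        raise ValueError("need at least 3 points for a coupling fit")
    if np.ptp(gamma) == 0:
        raise ValueError("degenerate fit: gamma values all equal")
    if len(gamma) < 10:
        warnings.warn(
            f"coupling fit for {subject or 'subject'} uses {len(gamma)} "
            "points (expected 10)", stacklevel=2)
    res = stats.linregress(gamma, hemo)
    return CouplingFit(subject=subject, measure=measure,
                       gradient=float(res.slope),
                       intercept=float(res.intercept),
                       n_points=len(gamma),
                       r_squared=float(res.rvalue ** 2))


# ---------------------------------------------------------------------------
# Exact Mann–Whitney U
# ---------------------------------------------------------------------------

def _rank_sum_distribution(scaled_ranks, n1: int):
    """Counts of group-1 rank sums over all equally likely assignments.

    ``scaled_ranks``: integer midranks × 2 of the pooled sample.  Dynamic
    programming over (#chosen, sum); returns an integer array ``counts``
    where ``counts[s]`` is the number of size-``n1`` subsets with scaled
    rank sum ``s``.
    """
    total = int(sum(scaled_ranks))
    counts = np.zeros((n1 + 1, total + 1), dtype=object)
    counts[0, 0] = 1
    for r in scaled_ranks:
        r = int(r)
        for k in range(n1, 0, -1):
            counts[k, r:] = counts[k, r:] + counts[k - 1, :total + 1 - r]
    return counts[n1]


def mannwhitney_exact(x, y, alternative: str = "two-sided",
                      max_exact: int = 25) -> GroupTestResult:
    """Mann–Whitney U test with an exact null distribution.

    U is computed from midranks (ties allowed).  For combined samples of at
    most ``max_exact`` observations the two-tailed p-value is exact: twice
    the smaller tail probability of the enumerated rank-assignment
    distribution, capped at 1.  Larger samples fall back to the normal
    approximation with tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if n1 + n2 <= max_exact:
        scaled = np.round(ranks * 2).astype(int)
        dist = _rank_sum_distribution(scaled, n1)
        total = Fraction(math.comb(n1 + n2, n1))
        s1 = int(round(r1 * 2))
        lo = Fraction(int(sum(dist[:s1 + 1])), 1) / total
        hi = Fraction(int(sum(dist[s1:])), 1) / total
        if alternative == "two-sided":
            p = min(Fraction(1), 2 * min(lo, hi))
        elif alternative == "greater":
            p = hi
        elif alternative == "less":
            p = lo
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return GroupTestResult(statistic=float(u1), p=float(p),
                               method="mann-whitney-exact")
    # normal approximation with tie correction
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (u1 - mu) / sigma if sigma > 0 else 0.0
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    else:
        p = stats.norm.cdf(z)
    return GroupTestResult(statistic=float(u1), p=float(min(p, 1.0)),
                           method="mann-whitney-normal")


# ---------------------------------------------------------------------------
# Holm–Bonferroni
# ---------------------------------------------------------------------------

def holm_bonferroni(pvals, alpha: float = 0.05):
    """Step-down Holm–Bonferroni decisions.

    Returns a dict with, in the input order: the per-comparison thresholds
    ``alpha/(m−i+1)`` (i the 1-based ascending rank of each p), and the
    step-down reject decisions (rejection stops at the first sorted
    non-rejection).
    """
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresholds = np.empty(m)
    reject = np.zeros(m, bool)
    alive = True
    for i, idx in enumerate(order):
        thresholds[idx] = alpha / (m - i)
        if alive and p[idx] < thresholds[idx]:
            reject[idx] = True
        else:
            alive = False
    return {"threshold": thresholds, "reject": reject,
            "rank": np.argsort(order) + 1}


# ---------------------------------------------------------------------------
# Mixed ANOVA with Greenhouse–Geisser correction
# ---------------------------------------------------------------------------

def gg_epsilon(data: np.ndarray, groups) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance.

    ``data`` is subjects × k repeated measures.  Epsilon is
    ``(Σλ)² / ((k−1) Σλ²)`` over the eigenvalues λ of the double-centered
    error covariance; bounded in [1/(k−1), 1].
    """
    data = np.asarray(data, float)
    groups = np.asarray(groups)
    k = data.shape[1]
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    if k == 2:
        return 1.0
    S = np.zeros((k, k))
    dof = 0
    for g in np.unique(groups):
        sub = data[groups == g]
        S += (len(sub) - 1) * np.cov(sub, rowvar=False)
        dof += len(sub) - 1
    S /= dof
    H = np.eye(k) - np.ones((k, k)) / k
    Sc = H @ S @ H
    lam = np.linalg.eigvalsh(Sc)
    num = lam.sum() ** 2
    den = (k - 1) * np.sum(lam ** 2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def mauchly_p(data: np.ndarray, groups) -> float:
    """Mauchly sphericity test p-value (chi-square approximation)."""
    data = np.asarray(data, float)
    groups = np.asarray(groups)
    k = data.shape[1]
    if k <= 2:
        return 1.0
    S = np.zeros((k, k))
    dof = 0
    for g in np.unique(groups):
        sub = data[groups == g]
        S += (len(sub) - 1) * np.cov(sub, rowvar=False)
        dof += len(sub) - 1
    S /= dof
    # orthonormal contrasts
    M = np.linalg.qr(np.eye(k) - np.ones((k, k)) / k)[0][:, :k - 1]
    T = M.T @ S @ M
    lam = np.linalg.eigvalsh(T)
    lam = np.clip(lam, 1e-300, None)
    d = k - 1
    W = np.exp(np.sum(np.log(lam)) - d * np.log(lam.mean()))
    df = d * (d + 1) // 2 - 1
    if df <= 0 or dof <= 0:
        return 1.0
    f = 1 - (2 * d ** 2 + d + 2) / (6.0 * d * dof)
    chi2 = -f * dof * np.log(max(W, 1e-300))
    return float(stats.chi2.sf(chi2, df))


def mixed_anova_gg(data: np.ndarray, groups, sphericity_alpha: float = 0.05
                   ) -> dict:
    """Two-way mixed ANOVA (between: group, within: k levels) with GG.

    Returns a dict of GroupTestResult for ``"group"``, ``"within"`` and
    ``"interaction"``.  The Greenhouse–Geisser correction is applied to the
    within and interaction tests when the Mauchly sphericity test rejects at
    ``sphericity_alpha``; epsilon and both uncorrected/corrected degrees of
    freedom are recorded either way.
    """
    data = np.asarray(data, float)
    groups = np.asarray(groups)
    if data.ndim != 2:
        raise ValueError("data must be subjects × within-levels")
    n, k = data.shape
    labels = np.unique(groups)
    g = len(labels)
    if g < 2 or np.min([np.sum(groups == l) for l in labels]) < 2:
        raise ValueError("need >= 2 subjects in each of >= 2 groups")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    group_means = np.array([data[groups == l].mean() for l in labels])
    cell_means = np.array([data[groups == l].mean(axis=0) for l in labels])
    n_per = np.array([np.sum(groups == l) for l in labels])

    ss_group = k * np.sum(n_per * (group_means - grand) ** 2)
    ss_subj_within = k * np.sum(
        (subj_means - group_means[np.searchsorted(labels, groups)]) ** 2)
    ss_within = n * np.sum((cond_means - grand) ** 2)
    # interaction SS: cell means minus both main effects
    ss_inter = np.sum(n_per[:, None]
                      * (cell_means
                         - group_means[:, None]
                         - cond_means[None, :] + grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_group - ss_subj_within - ss_within - ss_inter

    df_group, df_sw = g - 1, n - g
    df_within = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err = (k - 1) * (n - g)

    f_group = (ss_group / df_group) / (ss_subj_within / df_sw)
    f_within = (ss_within / df_within) / (ss_err / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err / df_err)

    eps = gg_epsilon(data, groups)
    correct = mauchly_p(data, groups) < sphericity_alpha and k > 2
    e = eps if correct else 1.0
    method = "mixed-anova-gg" if correct else "mixed-anova"

    return {
        "group": GroupTestResult(
            statistic=float(f_group),
            p=float(stats.f.sf(f_group, df_group, df_sw)),
            method="mixed-anova", df=(df_group, df_sw)),
        "within": GroupTestResult(
            statistic=float(f_within),
            p=float(stats.f.sf(f_within, e * df_within, e * df_err)),
            method=method, df=(e * df_within, e * df_err), epsilon=eps),
        "interaction": GroupTestResult(
            statistic=float(f_inter),
            p=float(stats.f.sf(f_inter, e * df_inter, e * df_err)),
            method=method, df=(e * df_inter, e * df_err), epsilon=eps),
    }


def simple_main_effects(data: np.ndarray, groups) -> list[GroupTestResult]:
    """One-way between-group F test at each within-subject level."""
    data = np.asarray(data, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    out = []
    for j in range(data.shape[1]):
        samples = [data[groups == l, j] for l in labels]
        f, p = stats.f_oneway(*samples)
        out.append(GroupTestResult(
            statistic=float(f), p=float(p), method="one-way-anova",
            df=(len(labels) - 1, data.shape[0] - len(labels))))
    return out


def logmar(acuity_decimal) -> np.ndarray | float:
    """Visual acuity loss in log(MAR) units: log10(1/acuity).

    0 is reference-standard (20/20) vision; +0.1 per chart line lost.
    """
    a = np.asarray(acuity_decimal, float)
    if np.any(a <= 0):
        raise ValueError("acuity must be positive")
    out = np.log10(1.0 / a)
    return float(out) if out.ndim == 0 else out
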