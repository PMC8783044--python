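"""Cohort statistics layer.

The per-animal measurements (R_A, Delta, I_DV, C_I, induced-VPC counts,
categorical breach / ring calls) are summarized the way the figures of
this kind of study report them: induction index, proportions with 95%
confidence intervals, Welch's t-test for continuous metrics, an F-test
for differences in variance, and the Mann–Whitney U test for discrete
scores, with significance star codes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

log = logging.getLogger(__name__)

__all__ = [
    "induction_index",
    "proportion_ci",
    "welch_t",
    "mann_whitney_u",
    "variance_f_test",
    "star_code",
    "summarize_groups",
]

#: Star-code thresholds: p < 0.05 (*), < 0.01 (**), < 0.001 (***), < 0.0001 (****).
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def induction_index(counts) -> float:
    """Vulval induction index VI: mean number of induced VPCs per animal.

    ``counts`` is a sequence (or DataFrame with an ``induced_vpcs``
    column) of per-animal induced-VPC counts, each in [0, 6] (at most six
    VPCs, P3.p–P8.p, can adopt a vulval fate).  Wild type has three
    induced VPCs per animal, hence VI = 3.0.  Reported to one decimal.
    """
    if isinstance(counts, pd.DataFrame):
        counts = counts["induced_vpcs"]
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("induction_index: empty scoring table")
    if np.any((counts < 0) | (counts > 6)):
        raise ValueError("induced-VPC counts must lie in [0, 6]")
    return round(float(counts.sum() / counts.size), 1)


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float, float]:
    """Proportion estimate with a confidence interval.

    Returns ``(p_hat, lo, hi)``.  The Wilson score interval is the
    default; ``method="clopper-pearson"`` gives the exact interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    return k / n, float(lo), float(hi)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's t-test for independent samples of unequal variance.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of
    freedom and a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per sample")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("welch_t requires finite observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        raise ValueError("degenerate samples: zero variance and equal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _mwu_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal approximation with tie correction and continuity correction."""
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u1 = ranks[:nx].sum() - nx * (nx + 1) / 2  # U for x
    mu = nx * ny / 2
    n = nx + ny
    tie_counts = np.array(list(Counter(combined).values()), dtype=float)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return u1, 1.0  # all observations tied: no evidence either way
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(var)
    p = min(1.0, 2 * sps.norm.sf(abs(z)))
    return u1, p


def mann_whitney_u(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Mann–Whitney U test (two-sided), ``U`` reported for the first sample.

    The exact p-value is used when both samples have at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if x.size <= exact_max_n and y.size <= exact_max_n and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    return _mwu_asymptotic(x, y)


def variance_f_test(x, y) -> tuple[float, float]:
    """Two-sided F-test for a difference in variance.

    ``F = s_x^2 / s_y^2`` with ``(n_x - 1, n_y - 1)`` degrees of freedom;
    the two-sided p doubles the smaller tail.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("variance_f_test requires at least 2 observations per sample")
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("zero variance in denominator sample; F undefined")
    f = x.var(ddof=1) / vy
    dist = sps.f(x.size - 1, y.size - 1)
    p = min(1.0, 2 * min(dist.cdf(f), dist.sf(f)))
    return float(f), float(p)


def star_code(p: float) -> str:
    """Significance stars at the conventional figure-legend thresholds."""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


_TESTS = {"welch": welch_t, "mwu": mann_whitney_u, "ftest": variance_f_test}


def summarize_groups(
    table: pd.DataFrame, metric: str, group_col: str = "genotype", test: str = "welch"
) -> dict:
    """Per-group summary of one metric plus pairwise test results.

    Returns ``{"groups": DataFrame, "tests": [dict, ...]}`` where the
    group table carries n, mean, s.d., median and quartiles (s.d. is NaN
    and flagged for single-observation groups) and each pairwise entry
    carries the chosen test's statistic, p-value and star code.
    """
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {sorted(_TESTS)}")
    groups = {name: sub[metric].dropna().to_numpy() for name, sub in table.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("summarize_groups requires at least 2 groups")
    rows = []
    for name, v in groups.items():
        if v.size < 2:
            log.warning("group %r has a single observation; s.d. undefined", name)
        rows.append(
            {
                group_col: name,
                "n": v.size,
                "mean": v.mean() if v.size else np.nan,
                "sd": v.std(ddof=1) if v.size > 1 else np.nan,
                "median": np.median(v) if v.size else np.nan,
                "q1": np.percentile(v, 25) if v.size else np.nan,
                "q3": np.percentile(v, 75) if v.size else np.nan,
            }
        )
    tests = []
    for a, b in combinations(groups, 2):
        out = _TESTS[test](groups[a], groups[b])
        stat, p = out[0], out[-1]
        entry = {"group_a": a, "group_b": b, "test": test, "statistic": stat, "p": p,
                 "stars": star_code(p)}
        if test == "welch":
            entry["df"] = out[1]
        tests.append(entry)
    return {"groups": pd.DataFrame(rows), "tests": tests}
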