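"""Nonparametric and parametric test wrappers shared across the pipeline.

The cohort analyses lean on small-sample rank tests (fewer than ~30 units or
syllables per group), so the rank tests use the exact null distribution when
sample sizes allow and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

EXACT_N_MAX = 25  # exact rank-test null up to this sample size (no ties)


@dataclass
class StatResult:
    """Outcome of a single hypothesis test."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    direction: str = "none"  # sign of the effect: a>b, a<b or none
    correction: str = "none"
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _direction(a: np.ndarray, b: np.ndarray) -> str:
    d = float(np.mean(a) - np.mean(b))
    if d > 0:
        return "a>b"
    if d < 0:
        return "a<b"
    return "none"


def wilcoxon_paired(a, b=None) -> StatResult:
    """Wilcoxon signed-rank test on paired samples (or on differences).

    All-zero differences are reported as p = 1 with a warning instead of an
    error: identical paired measurements carry no evidence against the null.
    """
    a = np.asarray(a, dtype=float)
    if b is not None:
        b = np.asarray(b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        diffs = a - b
    else:
        diffs = a
    if len(diffs) < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; returning p = 1")
        return StatResult("wilcoxon_paired", 0.0, 1.0, (len(diffs),), "none")
    nz = diffs[diffs != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= EXACT_N_MAX and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(diffs, zero_method="wilcox", method=method)
    direction = "a>b" if np.median(nz) > 0 else ("a<b" if np.median(nz) < 0 else "none")
    return StatResult(
        "wilcoxon_paired", float(res.statistic), float(res.pvalue), (len(diffs),), direction
    )


def wilcoxon_ranksum(a, b) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations tied; rank-sum test undefined")
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact"
        if (max(len(a), len(b)) <= EXACT_N_MAX and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        "wilcoxon_ranksum",
        float(res.statistic),
        float(res.pvalue),
        (len(a), len(b)),
        _direction(a, b),
    )


def kruskal_wallis(*groups) -> StatResult:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    res = stats.kruskal(*groups)
    return StatResult(
        "kruskal_wallis",
        float(res.statistic),
        float(res.pvalue),
        tuple(len(g) for g in groups),
    )


def t_two_sample(a, b) -> StatResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b)
    return StatResult(
        "t_two_sample",
        float(res.statistic),
        float(res.pvalue),
        (len(a), len(b)),
        _direction(a, b),
    )


def pearson_correlation(x, y) -> StatResult:
    """Pearson r with the classic no-correlation p-value (t distribution)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return StatResult(
        "pearson",
        r,
        float(res.pvalue),
        (len(x),),
        "a>b" if r > 0 else ("a<b" if r < 0 else "none"),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, each >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


_TEST_DISPATCH = {
    "wilcoxon_paired": wilcoxon_paired,
    "wilcoxon_ranksum": wilcoxon_ranksum,
    "kruskal_wallis": kruskal_wallis,
    "t_two_sample": t_two_sample,
}


def run_test(samples, kind: str, correction: str = "none") -> StatResult:
    """Run one named test on a tuple/list of sample arrays.

    ``samples`` is a sequence of arrays: two for the pairwise tests, two or
    more for Kruskal-Wallis.  ``correction`` is recorded on the result;
    family-wise adjustment across several results is done with
    :func:`adjust_family`.
    """
    if kind not in _TEST_DISPATCH:
        raise ValueError(f"unknown test kind {kind!r}")
    result = _TEST_DISPATCH[kind](*samples)
    result.correction = correction
    return result


def adjust_family(results: list[StatResult], method: str = "holm") -> list[StatResult]:
    """Apply a multiple-testing correction across a declared family of tests."""
    if method == "none":
        for r in results:
            r.p_adjusted = r.p_value
        return results
    if method != "holm":
        raise ValueError(f"unsupported correction {method!r}")
    adj = holm_adjust([r.p_value for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.correction = "holm"
    return results
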