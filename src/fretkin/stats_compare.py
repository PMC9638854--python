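"""Group comparisons of fitted kinetic parameters.

Supporting statistics for region comparisons: Kruskal-Wallis across
regions, Mann-Whitney / Welch / paired t for two-group contrasts, and a
Gardner-Altman style estimation difference (unpaired mean difference
with a Welch 95% CI).  All tests are two-sided and delegate to
scipy.stats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult", "EstimationResult", "kruskal_wallis", "mann_whitney",
    "paired_t", "welch_t", "estimation_difference", "compare_fit_parameter",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    group_medians: tuple[float, ...]


@dataclass(frozen=True)
class EstimationResult:
    """Unpaired mean difference (b - a) with a Welch 95% CI."""

    difference: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int


def _as_groups(groups, min_n, test):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < min_n:
            raise ValueError(f"{test}: group {i} has n={g.size} < {min_n}")
    return arrays


def kruskal_wallis(*groups) -> TestResult:
    """Rank-based H test across >= 2 groups (tie-corrected, chi-square p).

    Degenerate all-identical data returns H = 0, p = 1 with a warning.
    """
    arrays = _as_groups(groups, 3, "kruskal_wallis")
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        logger.warning("all values identical; Kruskal-Wallis degenerate")
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(p),
                      tuple(g.size for g in arrays),
                      tuple(float(np.median(g)) for g in arrays))


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney U (exact on small tie-free samples)."""
    a, b = _as_groups((group_a, group_b), 1, "mann_whitney")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), (float(np.median(a)), float(np.median(b))))


def welch_t(group_a, group_b) -> TestResult:
    """Two-sided unpaired t test with Welch's correction."""
    a, b = _as_groups((group_a, group_b), 2, "welch_t")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), (float(np.median(a)), float(np.median(b))))


def paired_t(group_a, group_b) -> TestResult:
    """Two-sided paired t test; groups aligned by disc.

    Raises
    ------
    ValueError
        Mismatched lengths or zero variance of the paired differences.
    """
    a, b = _as_groups((group_a, group_b), 2, "paired_t")
    if a.size != b.size:
        raise ValueError("paired_t: groups must have equal length")
    diffs = a - b
    if np.ptp(diffs) == 0:
        raise ValueError("paired_t: all paired differences are equal "
                         "(zero variance, statistic undefined)")
    res = stats.ttest_rel(a, b)
    return TestResult("paired_t", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), (float(np.median(a)), float(np.median(b))))


def estimation_difference(group_a, group_b, confidence: float = 0.95) -> EstimationResult:
    """Unpaired mean difference mean(b) - mean(a) with a Welch CI.

    With zero variance in both groups the CI has width zero.
    """
    a, b = _as_groups((group_a, group_b), 2, "estimation_difference")
    diff = float(b.mean() - a.mean())
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    se2 = var_a / a.size + var_b / b.size
    if se2 == 0:
        return EstimationResult(diff, diff, diff, a.size, b.size)
    df = se2**2 / (
        (var_a / a.size) ** 2 / (a.size - 1) + (var_b / b.size) ** 2 / (b.size - 1)
    )
    half = stats.t.ppf(0.5 + confidence / 2, df) * np.sqrt(se2)
    return EstimationResult(diff, diff - half, diff + half, a.size, b.size)


_TESTS = {
    "kruskal": kruskal_wallis,
    "mannwhitney": mann_whitney,
    "welch": welch_t,
    "paired": paired_t,
}


def compare_fit_parameter(fits: pd.DataFrame, regions: list[str],
                          param: str = "t_half_min",
                          test: str = "kruskal") -> TestResult:
    """Compare one fitted parameter across named regions of a fits table.

    Only converged per-disc fits enter; the mean-trace rows (disc_id
    "mean") are excluded.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    usable = fits[(fits["converged"]) & (fits["disc_id"] != "mean")]
    groups = []
    for region in regions:
        vals = usable.loc[usable["region"] == region, param].dropna().to_numpy()
        if vals.size == 0:
            raise ValueError(f"no converged fits for region {region!r}")
        groups.append(vals)
    if test == "kruskal":
        return kruskal_wallis(*groups)
    if len(groups) != 2:
        raise ValueError(f"test {test!r} needs exactly 2 regions")
    return _TESTS[test](*groups)
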