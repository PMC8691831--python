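"""Nonparametric statistics used to report the measurements.

Two-tailed paired Wilcoxon signed-rank tests (including the one-sample
comparison of a ratio against 0.5, "equal division") and two-tailed
unpaired Mann-Whitney tests, plus min/quartile/median/max/mean box-plot
summaries. Exact null distributions are used at small sample sizes
(signed-rank: n <= 25; Mann-Whitney: <= 10 per group, tie-free) and
continuity-corrected normal approximations above, with zero differences
dropped before ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class BoxSummary:
    """Box-plot summary: median, quartiles, range, mean."""

    median: float
    q1: float
    q3: float
    min: float
    max: float
    mean: float


def wilcoxon_paired(values_a, values_b_or_ref) -> TestResult:
    """Two-tailed paired Wilcoxon signed-rank test.

    ``values_b_or_ref`` may be a paired sample of equal length or a scalar
    reference (e.g. 0.5 for the equal-division null). Zero differences are
    dropped before ranking; if all differences are zero the test is
    degenerate and p = 1 is reported with a warning flag.
    """
    a = np.asarray(values_a, dtype=float)
    if a.size < 1:
        raise ParameterError("wilcoxon_paired needs at least one observation")
    if np.isscalar(values_b_or_ref) or np.ndim(values_b_or_ref) == 0:
        d = a - float(values_b_or_ref)
    else:
        b = np.asarray(values_b_or_ref, dtype=float)
        if b.shape != a.shape:
            raise ParameterError("paired samples must have equal length")
        d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; test is degenerate",
                      stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, n_effective=0,
                          method="wilcoxon_exact", degenerate=True)
    ties = np.unique(np.abs(d)).size < n
    if n <= WILCOXON_EXACT_MAX_N and not ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
        method = "wilcoxon_exact"
    else:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=True)
        method = "wilcoxon_normal"
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      n_effective=int(n), method=method)


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-tailed unpaired Mann-Whitney U test.

    Exact null enumeration for tie-free groups of at most 10 each,
    tie-corrected continuity-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= MANNWHITNEY_EXACT_MAX_N and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "mannwhitney_exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        method = "mannwhitney_normal"
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      n_effective=int(a.size + b.size), method=method)


def box_summary(values) -> BoxSummary:
    """Median, linear-interpolation quartiles, min, max and mean."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("box_summary needs at least one value")
    return BoxSummary(
        median=float(np.median(v)),
        q1=float(np.percentile(v, 25, method="linear")),
        q3=float(np.percentile(v, 75, method="linear")),
        min=float(v.min()),
        max=float(v.max()),
        mean=float(v.mean()),
    )
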