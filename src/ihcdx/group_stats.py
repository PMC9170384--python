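"""Descriptive summaries and significance tests between tissue groups.

Between-patient comparisons (HCC vs cirrhosis-only) use Welch's unequal-
variance t-test; within-patient comparisons (HCC region vs tumor-adjacent
tissue of the same sample) use the paired t-test on complete pairs; three-
group comparisons use one-way ANOVA.  Summaries use the sample SD (n-1
denominator) throughout.  ``t_test_from_summary`` allows the tests to be
recomputed from published (n, mean, SD) triples when raw data are not
available, and ``pooled_mixture_summary`` combines group summaries into the
exact mean/SD of the concatenated data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

_TINY_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample SD (H-score units) of one group."""

    n: int
    mean: float
    sd: float  # NaN when undefined (n == 1)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not math.isnan(self.sd) and self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def summarize(records: pd.DataFrame, by: Sequence[str] = ("marker", "region")) -> pd.DataFrame:
    """Per-group n, mean and sample SD of ``h_score``.

    Groups of size 1 report SD as NaN.  Records with missing scores are
    dropped before grouping.
    """
    present = records.dropna(subset=["h_score"])
    if not len(present):
        raise ValueError("no records with H-scores to summarize")
    grouped = present.groupby(list(by))["h_score"]
    out = grouped.agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    out["n"] = out["n"].astype(int)
    return out


def _as_summary(row) -> GroupSummary:
    return GroupSummary(int(row["n"]), float(row["mean"]), float(row["sd"]))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch (unequal-variance) t-test on raw scores."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult("welch_t", 0.0, float(len(x) + len(y) - 2), 1.0)
        raise ValueError("both groups have zero variance and unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.df), float(res.pvalue))


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test; pairs must be complete and aligned.

    When the paired differences have zero variance the t statistic is
    unbounded; the p-value is then reported as the smallest positive float
    (or 1 if the constant difference is 0).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired test needs equal-length, complete pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("incomplete pairs passed to paired test")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    dof = float(len(x) - 1)
    if np.var(diff, ddof=1) == 0:
        if diff[0] == 0:
            return TestResult("paired_t", 0.0, dof, 1.0)
        return TestResult("paired_t", math.copysign(math.inf, diff[0]), dof, _TINY_P)
    res = stats.ttest_rel(x, y)
    return TestResult("paired_t", float(res.statistic), dof, float(res.pvalue))


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA across 2+ groups; df reported as (between, within)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    res = stats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    df = (float(len(arrays) - 1), float(n_total - len(arrays)))
    return TestResult("one_way_anova", float(res.statistic), df, float(res.pvalue))


def t_test_from_summary(a: GroupSummary, b: GroupSummary, pooled: bool = False) -> TestResult:
    """Two-sided t-test from (n, mean, sd) triples only.

    Welch-Satterthwaite by default; ``pooled=True`` uses the equal-variance
    pooled test.  Lets published group summaries be re-tested without raw
    data.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise ValueError("t undefined: zero variance in both groups, equal means")
        raise ValueError("t undefined: zero variance in both groups")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled
    )
    if pooled:
        dof = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        dof = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    name = "pooled_t" if pooled else "welch_t"
    return TestResult(name, float(res.statistic), float(dof), float(res.pvalue))


def pooled_mixture_summary(parts: Sequence[GroupSummary]) -> GroupSummary:
    """Exact summary of the concatenation of several summarized groups.

    n is the total count, the mean is the count-weighted mean, and the
    variance combines within-group and between-group spread:

        s^2 = [sum (n_i - 1) s_i^2 + sum n_i (m_i - M)^2] / (n - 1)

    which equals the sample variance of the pooled raw data exactly.
    """
    if not parts:
        raise ValueError("need at least one group summary")
    n = sum(p.n for p in parts)
    mean = sum(p.n * p.mean for p in parts) / n
    if n == 1:
        return GroupSummary(n, mean, float("nan"))
    within = sum((p.n - 1) * p.sd**2 for p in parts if p.n > 1)
    between = sum(p.n * (p.mean - mean) ** 2 for p in parts)
    return GroupSummary(n, mean, math.sqrt((within + between) / (n - 1)))


def group_tests(records: pd.DataFrame, by: str = "marker") -> pd.DataFrame:
    """Welch HCC vs cirrhosis-only comparison per marker (or other key),
    as a tidy frame; used by the pipeline's summary report."""
    rows = []
    for key, sub in records.dropna(subset=["h_score"]).groupby(by):
        hcc = sub.loc[sub["region"] == "HCC", "h_score"].to_numpy()
        cir = sub.loc[sub["region"] == "CIRRHOSIS", "h_score"].to_numpy()
        if len(hcc) < 2 or len(cir) < 2:
            continue
        res = welch_t_test(cir, hcc)
        rows.append(
            {
                by: key,
                "test": res.name,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "n_cirrhosis": len(cir),
                "n_hcc": len(hcc),
            }
        )
    return pd.DataFrame(rows)
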