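"""Threshold classification and diagnostic-accuracy metrics.

Samples are classified HCC (the positive class) when the H-score — or the
modelled probability of cirrhosis-only — falls strictly below a threshold;
ties go to the negative class (cirrhosis-only).  From the confusion counts
the five standard metrics are computed, each with an untruncated 95% Wald
interval:

    sensitivity = tp / (tp + fn)        specificity = tn / (tn + fp)
    PPV = tp / (tp + fp)                NPV = tn / (tn + fn)
    accuracy = (tp + tn) / N

``threshold_sweep`` evaluates a grid of thresholds, and ``sweep_table``
formats the result as a report table (metric rows, threshold columns,
"est (lo-hi)" cells rounded half-up to 2 decimals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

HCC, CIRRHOSIS = "HCC", "CIRRHOSIS"

METRIC_LABELS = {
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "ppv": "Positive predictive value",
    "npv": "Negative predictive value",
    "accuracy": "Accuracy",
}


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with HCC as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with untruncated Wald bounds and its denominator."""

    estimate: float
    lower: float
    upper: float
    n: int


@dataclass(frozen=True)
class DiagnosticResult:
    """All five accuracy metrics at one threshold.

    A metric whose denominator is zero is ``None``, with the reason
    recorded in ``missing``.
    """

    threshold: float
    counts: ConfusionCounts
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    accuracy: MetricEstimate | None
    missing: dict[str, str]


def classify_by_hscore(score: float, threshold: float) -> str:
    """HCC iff the H-score is strictly below the threshold; a score exactly
    at the threshold classifies as cirrhosis-only."""
    return HCC if score < threshold else CIRRHOSIS


def classify_by_probability(prob_cirrhosis: float, threshold: float) -> str:
    """HCC iff the modelled Prob(cirrhosis-only) is strictly below the
    probability cut point."""
    if not 0 <= prob_cirrhosis <= 1:
        raise ValueError("probability must lie in [0, 1]")
    return HCC if prob_cirrhosis < threshold else CIRRHOSIS


def confusion(
    truth: Sequence[str],
    values: Sequence[float],
    threshold: float,
    mode: Literal["hscore", "probability"] = "hscore",
) -> ConfusionCounts:
    """Confusion counts of the threshold rule against true diagnoses.

    ``truth`` holds "HCC" / "CIRRHOSIS" labels; ``values`` the H-scores or
    probabilities.  Every record must be labelled and valued.
    """
    truth = np.asarray(truth, dtype=object)
    values = np.asarray(values, dtype=float)
    if truth.shape != values.shape:
        raise ValueError("truth and values must align")
    if np.isnan(values).any():
        raise ValueError("unvalued record passed to confusion")
    bad = set(truth) - {HCC, CIRRHOSIS}
    if bad:
        raise ValueError(f"unlabeled or unknown diagnoses: {sorted(bad)}")
    if mode == "probability" and (values.min() < 0 or values.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    predicted_hcc = values < threshold
    actual_hcc = truth == HCC
    return ConfusionCounts(
        tp=int(np.sum(predicted_hcc & actual_hcc)),
        fp=int(np.sum(predicted_hcc & ~actual_hcc)),
        tn=int(np.sum(~predicted_hcc & ~actual_hcc)),
        fn=int(np.sum(~predicted_hcc & actual_hcc)),
    )


def wald_ci(p_hat: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation interval p +/- z*sqrt(p(1-p)/n).

    Deliberately not clipped to [0, 1]: a proportion of 0.89 at n = 28 has
    upper bound 1.01, and degenerate proportions (0 or 1) give zero-width
    intervals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must lie in [0, 1]")
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return p_hat - half, p_hat + half


def _estimate(numerator: int, denominator: int, z: float) -> MetricEstimate | None:
    if denominator == 0:
        return None
    p = numerator / denominator
    lo, hi = wald_ci(p, denominator, z)
    return MetricEstimate(p, lo, hi, denominator)


def metrics(counts: ConfusionCounts, threshold: float = math.nan, z: float = 1.96) -> DiagnosticResult:
    """The five accuracy metrics with Wald intervals from confusion counts."""
    pieces = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
        "accuracy": (counts.tp + counts.tn, counts.total),
    }
    estimates: dict[str, MetricEstimate | None] = {}
    missing: dict[str, str] = {}
    for name, (num, den) in pieces.items():
        est = _estimate(num, den, z)
        estimates[name] = est
        if est is None:
            missing[name] = f"zero denominator ({name} n = 0)"
    return DiagnosticResult(threshold=threshold, counts=counts, missing=missing, **estimates)


def threshold_sweep(
    truth: Sequence[str],
    values: Sequence[float],
    thresholds: Sequence[float],
    mode: Literal["hscore", "probability"] = "hscore",
) -> list[DiagnosticResult]:
    """Evaluate :func:`metrics` at each threshold of an ascending grid."""
    thresholds = list(thresholds)
    if sorted(set(thresholds)) != thresholds:
        raise ValueError("thresholds must be ascending and unique")
    return [
        metrics(confusion(truth, values, t, mode=mode), threshold=t) for t in thresholds
    ]


def _round_half_up(x: float, digits: int = 2) -> float:
    scale = 10**digits
    return math.floor(x * scale + 0.5) / scale


def format_estimate(est: MetricEstimate | None, digits: int = 2) -> str:
    if est is None:
        return "NA"
    e, lo, hi = (_round_half_up(v, digits) for v in (est.estimate, est.lower, est.upper))
    fmt = f"{{:.{digits}f}}"
    return f"{fmt.format(e)} ({fmt.format(lo)}–{fmt.format(hi)})"


def sweep_table(results: Sequence[DiagnosticResult], digits: int = 2) -> pd.DataFrame:
    """Report table: metric rows x threshold columns of "est (lo-hi)" cells."""
    data = {
        f"{r.threshold:g}": [
            format_estimate(getattr(r, name), digits) for name in METRIC_LABELS
        ]
        for r in results
    }
    return pd.DataFrame(data, index=list(METRIC_LABELS.values()))
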