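"""Patient-matched comparison of tumor and tumor-adjacent staining.

For each patient with an H-score in both the HCC region and the tumor-
adjacent tissue (TAT) of the same slide, two flags are derived: whether the
HCC score is lower at all, and whether the TAT score exceeds it by more
than a relative margin (default 10%, read multiplicatively: tat > 1.1*hcc,
strict).  The tabulation reports the three percentages of the matched-pair
table: lower-in-HCC out of evaluable pairs, margin-exceeded out of
evaluable pairs, and margin-exceeded out of the lower-in-HCC subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PairedComparison:
    """Counts and report percentages of one marker's matched-pair table.

    Percentages are rounded half-up to whole numbers for report parity and
    are NaN when their denominator is zero.
    """

    total: int
    evaluable: int
    n_hcc_lower: int
    n_tat_exceeds: int
    pct_hcc_lower: float
    pct_tat_exceeds: float
    pct_tat_exceeds_of_lower: float


def pair_flags(hcc: float, tat: float, rel_threshold: float = 0.10) -> tuple[bool, bool]:
    """Flags for one complete pair: (hcc < tat, tat > hcc*(1+rel_threshold)).

    With hcc = 0, any positive tat exceeds the relative margin.
    """
    if math.isnan(hcc) or math.isnan(tat):
        raise ValueError("pair_flags requires both scores; filter incomplete pairs upstream")
    return hcc < tat, tat > hcc * (1.0 + rel_threshold)


def _pct(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return float("nan")
    return math.floor(100.0 * numerator / denominator + 0.5)


def tabulate_pairs(pairs: pd.DataFrame, rel_threshold: float = 0.10) -> PairedComparison:
    """Tabulate matched pairs (frame with ``hcc`` and ``tat`` columns; NaN
    marks a missing member).  Pairs lacking either score count toward
    ``total`` but not ``evaluable``."""
    hcc = pairs["hcc"].to_numpy(float)
    tat = pairs["tat"].to_numpy(float)
    complete = ~(np.isnan(hcc) | np.isnan(tat))
    lower = complete & (hcc < tat)
    exceeds = complete & (tat > hcc * (1.0 + rel_threshold))
    evaluable = int(complete.sum())
    n_lower = int(lower.sum())
    n_exceeds = int(exceeds.sum())
    n_exceeds_of_lower = int((exceeds & lower).sum())
    return PairedComparison(
        total=len(pairs),
        evaluable=evaluable,
        n_hcc_lower=n_lower,
        n_tat_exceeds=n_exceeds,
        pct_hcc_lower=_pct(n_lower, evaluable),
        pct_tat_exceeds=_pct(n_exceeds, evaluable),
        pct_tat_exceeds_of_lower=_pct(n_exceeds_of_lower, n_lower),
    )


def paired_table(comparisons: dict[str, PairedComparison]) -> pd.DataFrame:
    """Matched-pair report: one column per marker, rows mirroring the
    published table layout."""
    rows = [
        ("Total", lambda c: c.total),
        ("Samples with both HCC and TAT H-scores", lambda c: c.evaluable),
        ("Samples with HCC < TAT", lambda c: c.n_hcc_lower),
        ("Samples with TAT 10% > HCC", lambda c: c.n_tat_exceeds),
        ("Percentage of HCC < TAT out of evaluable", lambda c: c.pct_hcc_lower),
        ("Percentage of TAT 10% > HCC out of evaluable", lambda c: c.pct_tat_exceeds),
        ("Percentage of TAT 10% > HCC out of HCC < TAT", lambda c: c.pct_tat_exceeds_of_lower),
    ]
    data = {marker: [fn(comp) for _, fn in rows] for marker, comp in comparisons.items()}
    return pd.DataFrame(data, index=[label for label, _ in rows])
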