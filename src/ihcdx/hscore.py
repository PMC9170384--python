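"""H-score computation and sample-evaluability filtering.

The H-score is the standard semi-quantitative summary of immunohistochemical
(IHC) staining over a tissue region.  Each cell (or, in digital analysis, each
unit of area) is graded into one of four intensity classes — 0 none, 1 weak,
2 moderate, 3 strong — and the class percentages are combined as

    H = 3 * (% strong) + 2 * (% moderate) + 1 * (% weak)

so the score lives on a 0–300 scale: 0 when nothing stains, 300 when every
cell stains strongly.  This module provides the score from raw cell tallies
(:func:`hscore_from_tally`) or from area fractions produced by image analysis
(:func:`hscore_from_fractions`), the per-sample record type used throughout
the package, its CSV dialect, and the evaluability filter that removes
mixed-histology or physically damaged samples before quantification.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Intensity class codes, in increasing order of staining strength.
INTENSITY_CLASSES = (0, 1, 2, 3)

#: Canonical names of the intensity classes.  "mild" is an accepted alias
#: for "moderate" (class 2) in mapping-based constructors.
CLASS_NAMES = ("none", "weak", "moderate", "strong")

#: Tissue regions a sample record may carry.
REGIONS = ("HCC", "TAT", "CIRRHOSIS")

#: The two TGF-beta receptor markers scored by the workflow.
MARKERS = ("TGFBR1", "TGFBR2")

#: Reasons that render a sample non-evaluable for manual quantification.
EXCLUSION_REASONS = ("mixed_cholangiocarcinoma", "damaged")

#: Column order of the sample-record CSV dialect.
SAMPLE_COLUMNS = (
    "patient_id",
    "site",
    "region",
    "marker",
    "h_score",
    "excluded_flag",
    "exclusion_reason",
)

_ALIASES = {"mild": "moderate"}


@dataclass(frozen=True)
class CellTally:
    """Cell counts over the four staining-intensity classes.

    Parameters
    ----------
    counts
        Non-negative integer counts ``(none, weak, moderate, strong)``;
        the total must be positive.
    """

    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.counts) != 4:
            raise ValueError("a tally needs exactly four class counts")
        if any(c < 0 for c in self.counts):
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("a tally must contain at least one cell")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "CellTally":
        """Build a tally from a ``{class name: count}`` mapping.

        Accepts "mild" as an alias for "moderate"; absent classes count 0.
        """
        resolved: dict[str, int] = {}
        for key, value in counts.items():
            name = _ALIASES.get(key.lower(), key.lower())
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown intensity class {key!r}")
            resolved[name] = resolved.get(name, 0) + int(value)
        return cls(tuple(resolved.get(name, 0) for name in CLASS_NAMES))

    def fractions(self) -> "IntensityFractions":
        total = self.total
        return IntensityFractions(tuple(c / total for c in self.counts))


@dataclass(frozen=True)
class IntensityFractions:
    """Area (or cell) fractions over the four intensity classes.

    Fractions must each lie in [0, 1] and sum to 1 within 1e-9.
    """

    fractions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.fractions) != 4:
            raise ValueError("exactly four class fractions are required")
        if any(f < 0 or f > 1 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 (within 1e-9)")


@dataclass
class SampleRecord:
    """One scored tissue region of one patient — the pipeline's atom.

    ``h_score`` may be ``None`` for samples where the marker was not
    quantifiable; ``region`` is ``"CIRRHOSIS"`` only for patients without
    an HCC diagnosis.  The score is nominally on the [0, 300] scale, but
    the bound is not enforced here: unclipped synthetic cohorts preserve
    the reported group moments exactly and may spill slightly outside it.
    """

    patient_id: str
    site: str
    region: str
    marker: str
    h_score: float | None
    excluded_flag: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.h_score is not None and not np.isfinite(self.h_score):
            raise ValueError("h_score must be finite when present")


def hscore_from_tally(tally: CellTally) -> float:
    """H-score of a cell tally.

    The class percentages (0–100) are weighted by their intensity grade:
    ``3*p3 + 2*p2 + 1*p1``.  A tally of 100% strong cells scores 300; one
    of 100% unstained cells scores 0.
    """
    total = tally.total
    percentages = [100.0 * c / total for c in tally.counts]
    return 1.0 * percentages[1] + 2.0 * percentages[2] + 3.0 * percentages[3]


def hscore_from_fractions(fractions: IntensityFractions) -> float:
    """H-score of area fractions: the same weighted sum with fractions*100
    playing the role of the class percentages."""
    f = fractions.fractions
    return 100.0 * (1.0 * f[1] + 2.0 * f[2] + 3.0 * f[3])


def filter_evaluable(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records flagged as non-evaluable (mixed cholangiocarcinoma or
    damaged tissue) and log how many were removed per reason.

    Returns a copy; the input frame is untouched.  Removing every record
    emits a warning, since downstream group statistics would be empty.
    """
    flagged = records["excluded_flag"].fillna(False).astype(bool)
    removed = records.loc[flagged]
    if len(removed):
        reasons = Counter(removed["exclusion_reason"].replace("", "unspecified"))
        summary = ", ".join(f"{reason}: {n}" for reason, n in sorted(reasons.items()))
        logger.info("excluded %d of %d records (%s)", len(removed), len(records), summary)
    kept = records.loc[~flagged].copy()
    if len(records) and not len(kept):
        logger.warning("all %d records were excluded as non-evaluable", len(records))
    return kept


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Tidy DataFrame (one row per record) in the package's CSV dialect."""
    rows = [
        {
            "patient_id": r.patient_id,
            "site": r.site,
            "region": r.region,
            "marker": r.marker,
            "h_score": np.nan if r.h_score is None else float(r.h_score),
            "excluded_flag": bool(r.excluded_flag),
            "exclusion_reason": r.exclusion_reason,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


def write_samples(records: pd.DataFrame, path: str | Path) -> None:
    """Write sample records as CSV with the canonical column order."""
    records.loc[:, list(SAMPLE_COLUMNS)].to_csv(path, index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample-record CSV written by :func:`write_samples`."""
    frame = pd.read_csv(
        path,
        dtype={
            "patient_id": str,
            "site": str,
            "region": str,
            "marker": str,
            "exclusion_reason": str,
        },
        keep_default_na=True,
    )
    missing = set(SAMPLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"sample CSV is missing columns: {sorted(missing)}")
    frame["excluded_flag"] = frame["excluded_flag"].fillna(False).astype(bool)
    frame["exclusion_reason"] = frame["exclusion_reason"].fillna("")
    return frame
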