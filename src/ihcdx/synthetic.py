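"""Synthetic cohorts, matched pairs, cell tallies and label-map slides.

The published patient-level data behind the TGFBR1/TGFBR2 H-score analysis
are not deposited, so this module generates cohorts with the reported group
structure instead: per (marker, diagnosis) group, H-scores are drawn from a
normal distribution with the printed mean and SD, optionally truncated to
the score's [0, 300] support.  Defaults reproduce the combined analysis
cohort — 28 cirrhosis-only and 53 HCC patients per marker with
TGFBR1 196.1 ± 44.6 vs 174.6 ± 62.6 and TGFBR2 145.2 ± 78.9 vs 113.7 ± 67.9
— and the discovery-set tumor/tumor-adjacent groups for the paired analysis.

Also provided: an exact inverse of the H-score formula that builds a cell
tally hitting a target score (for round-trip tests of the scoring code) and
a label-map generator producing aligned parent/intensity/stain layers with
known ground truth for the image-quantification stage.

Everything is driven by a single integer seed; identical configuration and
seed give byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hscore import MARKERS, CellTally, SampleRecord, records_to_frame
from .image_quant import PARENT_CODES, LabelMapImage

#: Diagnosis labels used as the cohort grouping (region doubles as diagnosis).
DIAGNOSES = ("CIRRHOSIS", "HCC")


@dataclass(frozen=True)
class GroupParams:
    """Normal H-score distribution of one (marker, diagnosis) group.

    ``clip`` truncates draws to the H-score support [0, 300]; the default is
    off so that sample moments converge to ``mean``/``sd`` exactly.  The
    mean is nominally on the [0, 300] scale but is not range-checked, so
    clipping behaviour at the scale boundaries can be exercised.
    """

    label: str
    n: int
    mean: float
    sd: float
    clip: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    ``groups`` maps ``(marker, region)`` to :class:`GroupParams`;
    ``cross_marker_rho`` correlates a patient's two marker scores,
    ``paired_rho`` correlates HCC and tumor-adjacent scores within a
    patient, and ``artifact_rate`` is the prevalence of non-evaluable
    (mixed-cholangiocarcinoma or damaged) samples.
    """

    groups: Mapping[tuple[str, str], GroupParams]
    cross_marker_rho: float = 0.0
    paired_rho: float = 0.5
    seed: int = 0
    site_labels: Sequence[str] = ("synthetic",)
    artifact_rate: float = 0.0
    missingness: float = 0.0

    def __post_init__(self) -> None:
        for rho, name in ((self.cross_marker_rho, "cross_marker_rho"), (self.paired_rho, "paired_rho")):
            if abs(rho) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness rate must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["groups"] = {f"{m}|{r}": asdict(g) for (m, r), g in self.groups.items()}
        payload["site_labels"] = list(self.site_labels)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        payload = json.loads(Path(path).read_text())
        groups = {
            tuple(key.split("|")): GroupParams(**params)
            for key, params in payload.pop("groups").items()
        }
        return cls(groups=groups, **payload)


def default_cohort_config(seed: int = 0, clip: bool = False) -> CohortConfig:
    """Combined-analysis case/control cohort: 28 cirrhosis-only vs 53 HCC
    patients per marker, with the reported group means and SDs."""
    groups = {
        ("TGFBR1", "CIRRHOSIS"): GroupParams("TGFBR1-cirrhosis", 28, 196.1, 44.6, clip),
        ("TGFBR1", "HCC"): GroupParams("TGFBR1-HCC", 53, 174.6, 62.6, clip),
        ("TGFBR2", "CIRRHOSIS"): GroupParams("TGFBR2-cirrhosis", 28, 145.2, 78.9, clip),
        ("TGFBR2", "HCC"): GroupParams("TGFBR2-HCC", 53, 113.7, 67.9, clip),
    }
    return CohortConfig(groups=groups, seed=seed)


def default_paired_config(marker: str = "TGFBR2", seed: int = 0, clip: bool = False) -> CohortConfig:
    """Discovery-set tumor vs tumor-adjacent groups for the paired analysis
    (TGFBR1: 165.0 ± 56.6 vs 232.9 ± 36.6 over 69 pairs; TGFBR2:
    105.8 ± 56.9 vs 202.3 ± 55.5 over 67 pairs)."""
    params = {
        "TGFBR1": (69, (165.0, 56.6), (232.9, 36.6)),
        "TGFBR2": (67, (105.8, 56.9), (202.3, 55.5)),
    }
    if marker not in params:
        raise ValueError(f"unknown marker {marker!r}")
    n, (hcc_mean, hcc_sd), (tat_mean, tat_sd) = params[marker]
    groups = {
        (marker, "HCC"): GroupParams(f"{marker}-HCC", n, hcc_mean, hcc_sd, clip),
        (marker, "TAT"): GroupParams(f"{marker}-TAT", n, tat_mean, tat_sd, clip),
    }
    return CohortConfig(groups=groups, seed=seed)


def _correlated_standard_normals(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, rho * z1 + np.sqrt(1.0 - rho * rho) * z2


def _finalize(scores: np.ndarray, params: GroupParams) -> np.ndarray:
    return np.clip(scores, 0.0, 300.0) if params.clip else scores


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one cohort of :class:`~ihcdx.hscore.SampleRecord` rows.

    Patients within a diagnosis receive both markers; when both marker
    groups of a diagnosis have equal n, the two scores are drawn from a
    bivariate normal with correlation ``cross_marker_rho`` (otherwise the
    groups are drawn independently).  A fraction ``artifact_rate`` of
    records is flagged non-evaluable with a random exclusion reason.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SampleRecord] = []
    diagnoses = sorted({region for (_, region) in config.groups})
    for diagnosis in diagnoses:
        marker_groups = {m: g for (m, region), g in sorted(config.groups.items()) if region == diagnosis}
        markers = list(marker_groups)
        joint = len(markers) == 2 and len({g.n for g in marker_groups.values()}) == 1
        if joint:
            g1, g2 = (marker_groups[m] for m in markers)
            z1, z2 = _correlated_standard_normals(rng, g1.n, config.cross_marker_rho)
            draws = {
                markers[0]: _finalize(g1.mean + g1.sd * z1, g1),
                markers[1]: _finalize(g2.mean + g2.sd * z2, g2),
            }
        else:
            draws = {
                m: _finalize(g.mean + g.sd * rng.standard_normal(g.n), g)
                for m, g in marker_groups.items()
            }
        n_patients = max(g.n for g in marker_groups.values())
        sites = [config.site_labels[i % len(config.site_labels)] for i in range(n_patients)]
        for marker in markers:
            scores = draws[marker]
            for i, score in enumerate(scores):
                flagged = rng.random() < config.artifact_rate
                reason = ""
                if flagged:
                    reason = "mixed_cholangiocarcinoma" if rng.random() < 0.5 else "damaged"
                records.append(
                    SampleRecord(
                        patient_id=f"{diagnosis[:3]}-{i:04d}",
                        site=sites[i],
                        region=diagnosis,
                        marker=marker,
                        h_score=float(score),
                        excluded_flag=flagged,
                        exclusion_reason=reason,
                    )
                )
    return records_to_frame(records)


def generate_paired_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw patient-matched HCC / tumor-adjacent score pairs.

    For each marker with both an ``(marker, "HCC")`` and ``(marker, "TAT")``
    group, one pair per patient is drawn with within-patient correlation
    ``paired_rho``.  With probability ``missingness`` a pair loses one
    member (NaN), emulating samples scored in only one region.  Returns a
    wide frame with columns patient_id, marker, hcc, tat.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    markers = sorted({m for (m, region) in config.groups if region in ("HCC", "TAT")})
    for marker in markers:
        try:
            hcc = config.groups[(marker, "HCC")]
            tat = config.groups[(marker, "TAT")]
        except KeyError:
            continue
        n_pairs = min(hcc.n, tat.n)
        z_h, z_t = _correlated_standard_normals(rng, n_pairs, config.paired_rho)
        hcc_scores = _finalize(hcc.mean + hcc.sd * z_h, hcc)
        tat_scores = _finalize(tat.mean + tat.sd * z_t, tat)
        for i in range(n_pairs):
            h, t = float(hcc_scores[i]), float(tat_scores[i])
            if rng.random() < config.missingness:
                if rng.random() < 0.5:
                    h = np.nan
                else:
                    t = np.nan
            rows.append({"patient_id": f"PAIR-{marker}-{i:04d}", "marker": marker, "hcc": h, "tat": t})
    return pd.DataFrame(rows, columns=["patient_id", "marker", "hcc", "tat"])


def largest_remainder_counts(fractions: Sequence[float], total: int) -> np.ndarray:
    """Integer counts summing to ``total`` that best match ``fractions``
    (largest-remainder apportionment; ties broken by class order)."""
    ideal = np.asarray(fractions, dtype=float) * total
    counts = np.floor(ideal).astype(int)
    shortfall = total - counts.sum()
    if shortfall:
        remainders = ideal - counts
        # stable sort descending on remainder -> lowest class index wins ties
        order = np.argsort(-remainders, kind="stable")
        counts[order[:shortfall]] += 1
    return counts


def generate_cell_tally(target_hscore: float, n_cells: int) -> CellTally:
    """Exact deterministic inverse of the H-score formula.

    Allocates cells to the two adjacent intensity classes bracketing
    ``target_hscore / 100`` (the allocation minimising the largest class
    share among two-class solutions), then rounds to integer counts by
    largest remainder.  The recomputed H-score of the returned tally is
    within ``300 / n_cells`` of the target.
    """
    if not 0 <= target_hscore <= 300:
        raise ValueError("target H-score must lie in [0, 300]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    h = target_hscore / 100.0
    lower = min(int(np.floor(h)), 2)
    upper_share = h - lower
    fractions = [0.0, 0.0, 0.0, 0.0]
    fractions[lower] = 1.0 - upper_share
    fractions[lower + 1] = upper_share
    return CellTally(tuple(int(c) for c in largest_remainder_counts(fractions, n_cells)))


@dataclass(frozen=True)
class RegionSpec:
    """One tissue region of a synthetic slide: its parent class, target
    area fraction, and intensity-class mix (four fractions summing to 1)."""

    parent: str
    area_fraction: float
    intensity_mix: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.parent not in PARENT_CODES or self.parent == "background":
            raise ValueError(f"invalid region parent class {self.parent!r}")
        if not 0 < self.area_fraction <= 1:
            raise ValueError("area_fraction must lie in (0, 1]")
        if abs(sum(self.intensity_mix) - 1.0) > 1e-9 or any(f < 0 for f in self.intensity_mix):
            raise ValueError("intensity_mix must be non-negative and sum to 1")


@dataclass
class ImageSpec:
    """Specification of a synthetic label-map slide.

    Region area fractions may sum to less than 1; the remainder is
    background (stain 0, excluded from quantification).  ``stain_means``
    and ``stain_sds`` give the continuous stain signal per intensity class.
    """

    width: int
    height: int
    regions: Sequence[RegionSpec]
    stain_means: tuple[float, float, float, float] = (10.0, 80.0, 160.0, 240.0)
    stain_sds: tuple[float, float, float, float] = (6.0, 10.0, 12.0, 16.0)
    seed: int = 0
    pixel_size_um: float = 0.227

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        total = sum(r.area_fraction for r in self.regions)
        if total > 1 + 1e-9:
            raise ValueError("region area fractions exceed 1")
        if any(s < 0 for s in self.stain_sds):
            raise ValueError("stain sds must be non-negative")


def generate_label_map(spec: ImageSpec) -> LabelMapImage:
    """Build a slide with known ground truth.

    Regions are laid out as contiguous pixel blocks sized by largest-
    remainder apportionment (realised area fractions exact to one pixel);
    within a region, intensity classes are apportioned the same way and
    scattered uniformly at random.  The stain channel draws each tissue
    pixel from Normal(mean[class], sd[class]) truncated at 0; background
    pixels carry zero signal.
    """
    rng = np.random.default_rng(spec.seed)
    n_pixels = spec.width * spec.height
    area = [r.area_fraction for r in spec.regions]
    region_sizes = largest_remainder_counts(area + [1.0 - sum(area)], n_pixels)

    parent = np.full(n_pixels, PARENT_CODES["background"], dtype=np.uint8)
    intensity = np.zeros(n_pixels, dtype=np.uint8)
    stain = np.zeros(n_pixels, dtype=float)

    start = 0
    for region, size in zip(spec.regions, region_sizes[:-1]):
        idx = np.arange(start, start + size)
        start += size
        parent[idx] = PARENT_CODES[region.parent]
        class_counts = largest_remainder_counts(region.intensity_mix, size)
        classes = np.repeat(np.arange(4, dtype=np.uint8), class_counts)
        rng.shuffle(classes)
        intensity[idx] = classes
        means = np.asarray(spec.stain_means)[classes]
        sds = np.asarray(spec.stain_sds)[classes]
        stain[idx] = np.maximum(0.0, rng.normal(means, sds))

    shape = (spec.height, spec.width)
    return LabelMapImage(
        parent=parent.reshape(shape),
        intensity=intensity.reshape(shape),
        stain=stain.reshape(shape),
        pixel_size_um=spec.pixel_size_um,
    )
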