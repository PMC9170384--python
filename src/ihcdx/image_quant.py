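"""Region-level quantification of staining-intensity label maps.

Digital IHC analysis of a slide produces two layers: a *parent* layer
classifying each pixel into a tissue region (HCC, cirrhotic, tumor-adjacent,
or background) and an *intensity* layer grading each pixel's staining into
the four H-score classes.  Integrating the two gives, per tissue region, the
area fraction at each intensity and hence a region H-score.  This module is
a deterministic stand-in for that aggregation: pixels are classified by
fixed thresholds on a continuous stain channel, area fractions are taken
within parent-class masks, and predicted maps can be scored against ground
truth as a percentage of inaccurate annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .hscore import IntensityFractions, hscore_from_fractions

#: Parent-layer tissue classes; the integer code of a class is its index.
PARENT_CLASSES = ("background", "HCC", "cirrhotic", "adjacent")

PARENT_CODES = {name: code for code, name in enumerate(PARENT_CLASSES)}

#: Scale applied to the stain channel when stored as 16-bit PNG.
_STAIN_PNG_SCALE = 64.0


class MissingRegionError(ValueError):
    """Raised when a requested parent class has no pixels in the image —
    distinct from a region that exists but has, say, all-zero intensity."""


@dataclass
class LabelMapImage:
    """Synthetic slide stand-in: aligned per-pixel layers.

    Attributes
    ----------
    parent
        Integer map of tissue classes (codes into :data:`PARENT_CLASSES`).
    intensity
        Integer map of staining-intensity classes {0, 1, 2, 3}.
    stain
        Non-negative continuous stain signal (arbitrary units).
    pixel_size_um
        Physical edge length of a pixel in micrometres; metadata only.
    """

    parent: np.ndarray
    intensity: np.ndarray
    stain: np.ndarray
    pixel_size_um: float = 0.227

    def __post_init__(self) -> None:
        if not (self.parent.shape == self.intensity.shape == self.stain.shape):
            raise ValueError("parent, intensity and stain maps must share dimensions")
        if np.any(self.stain < 0):
            raise ValueError("stain signal must be non-negative")


def classify_pixels(stain: np.ndarray, thresholds: tuple[float, float, float]) -> np.ndarray:
    """Threshold a stain channel into the four intensity classes.

    A pixel with signal in ``[t_k, t_{k+1})`` gets class ``k``, with
    ``t_0 = 0`` and ``t_4 = inf``; a pixel exactly at a cut point joins the
    upper class (half-open convention).  Thresholds must be strictly
    ascending.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (3,) or np.any(np.diff(t) <= 0):
        raise ValueError("need three strictly ascending thresholds")
    return np.digitize(stain, t).astype(np.uint8)


def region_area_fractions(
    image: LabelMapImage,
    parent_class: str,
    intensity: np.ndarray | None = None,
) -> IntensityFractions:
    """Intensity-class area fractions among the pixels of one parent class.

    By default the image's own intensity layer is used; pass ``intensity``
    to evaluate a predicted map instead.  Raises :class:`MissingRegionError`
    when the parent class has no pixels.
    """
    if parent_class not in PARENT_CODES:
        raise ValueError(f"unknown parent class {parent_class!r}")
    mask = image.parent == PARENT_CODES[parent_class]
    if not mask.any():
        raise MissingRegionError(f"no pixels of parent class {parent_class!r}")
    layer = image.intensity if intensity is None else intensity
    values = layer[mask]
    counts = np.bincount(values.ravel(), minlength=4).astype(float)
    fractions = counts / counts.sum()
    return IntensityFractions(tuple(fractions))


def hscore_per_region(
    image: LabelMapImage, intensity: np.ndarray | None = None
) -> dict[str, float]:
    """Region H-scores for every non-background parent class present."""
    scores: dict[str, float] = {}
    for name in PARENT_CLASSES:
        if name == "background":
            continue
        if np.any(image.parent == PARENT_CODES[name]):
            scores[name] = hscore_from_fractions(
                region_area_fractions(image, name, intensity=intensity)
            )
    return scores


def annotation_error_rate(
    predicted: np.ndarray,
    truth: np.ndarray,
    parent: np.ndarray | None = None,
) -> float:
    """Percentage of evaluated pixels where the predicted map disagrees with
    ground truth.

    When a parent map is supplied, background pixels are excluded from the
    denominator (mirroring review of tissue annotations only).
    """
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth maps must share dimensions")
    if parent is not None:
        if parent.shape != truth.shape:
            raise ValueError("parent map must share dimensions with the label maps")
        evaluated = parent != PARENT_CODES["background"]
    else:
        evaluated = np.ones(truth.shape, dtype=bool)
    n = int(evaluated.sum())
    if n == 0:
        raise ValueError("no pixels to evaluate")
    mismatches = int(np.count_nonzero(predicted[evaluated] != truth[evaluated]))
    return 100.0 * mismatches / n


def write_label_map(image: LabelMapImage, directory: str | Path, prefix: str = "slide") -> dict:
    """Write one PNG per layer plus a JSON sidecar; returns the manifest.

    The parent and intensity maps are stored as 8-bit class codes, the stain
    channel as 16-bit grayscale with a fixed scale recorded in the sidecar.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "parent": directory / f"{prefix}_parent.png",
        "intensity": directory / f"{prefix}_intensity.png",
        "stain": directory / f"{prefix}_stain.png",
    }
    iio.imwrite(paths["parent"], image.parent.astype(np.uint8))
    iio.imwrite(paths["intensity"], image.intensity.astype(np.uint8))
    stain16 = np.clip(image.stain * _STAIN_PNG_SCALE, 0, 65535).astype(np.uint16)
    iio.imwrite(paths["stain"], stain16)
    sidecar = {
        "pixel_size_um": image.pixel_size_um,
        "stain_scale": _STAIN_PNG_SCALE,
        "parent_classes": list(PARENT_CLASSES),
        "files": {k: p.name for k, p in paths.items()},
    }
    sidecar_path = directory / f"{prefix}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {**{k: str(p) for k, p in paths.items()}, "sidecar": str(sidecar_path)}


def read_label_map(directory: str | Path, prefix: str = "slide") -> LabelMapImage:
    """Read a label map written by :func:`write_label_map`."""
    directory = Path(directory)
    sidecar = json.loads((directory / f"{prefix}.json").read_text())
    parent = iio.imread(directory / sidecar["files"]["parent"]).astype(np.uint8)
    intensity = iio.imread(directory / sidecar["files"]["intensity"]).astype(np.uint8)
    stain = iio.imread(directory / sidecar["files"]["stain"]).astype(float)
    stain /= sidecar["stain_scale"]
    return LabelMapImage(parent, intensity, stain, pixel_size_um=sidecar["pixel_size_um"])
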