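"""Mask post-processing and cardiothoracic-ratio geometry.

The cardiothoracic ratio (CTR) is the widest horizontal extent of the
cardiac silhouette (TCD, transverse cardiac diameter) divided by the widest
internal horizontal dimension of the chest (TTD, transverse thoracic
diameter).  Segmentation output is first cleaned deterministically
(connected-component filtering + hole filling) so stray artifacts such as
drains or cables cannot corrupt the widths, then both diameters are read
off the masks by column arithmetic.

Width convention: inclusive pixel count, ``max_col − min_col + 1`` for both
TCD and TTD, so the ratio treats numerator and denominator symmetrically.
Consequently the midline decomposition satisfies ``a + b + 1 == tcd``
whenever the heart spans the midline.

Classification is projection-specific: the cardiac silhouette is magnified
in the AP (supine) projection, so it carries a higher threshold
(CTR > 0.58) than the PA (standing) projection (CTR > 0.55).  Both
inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .core import Projection, SegmentationMask

__all__ = [
    "CardiomegalyLabel",
    "ClassifierConfig",
    "CTRMeasurement",
    "MeasurementError",
    "binarize",
    "clean_heart_mask",
    "clean_lung_mask",
    "estimate_midline",
    "measure_tcd",
    "measure_ttd",
    "compute_ctr",
    "classify_cardiomegaly",
]

# 4-connectivity: conservative separation of stray artifacts
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


class CardiomegalyLabel(str, Enum):
    NORMAL = "NORMAL"
    CARDIOMEGALY = "CARDIOMEGALY"
    INDETERMINATE = "INDETERMINATE"


class MeasurementError(ValueError):
    """A diameter could not be measured (e.g. empty mask channel)."""

    def __init__(self, message: str, channel: str | None = None):
        super().__init__(message)
        self.channel = channel


@dataclass(frozen=True)
class ClassifierConfig:
    pa_threshold: float = 0.55
    ap_threshold: float = 0.58

    def __post_init__(self):
        if not (0.0 < self.pa_threshold < self.ap_threshold < 1.0):
            raise ValueError("require 0 < pa_threshold < ap_threshold < 1")


@dataclass(frozen=True)
class CTRMeasurement:
    tcd: int
    ttd: int
    a: int
    b: int
    midline_col: int
    ctr: float
    projection: Projection
    label: CardiomegalyLabel


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strict thresholding: 1 where prob > threshold."""
    return (np.asarray(prob) > threshold).astype(np.uint8)


def _components(mask: np.ndarray):
    labels, n = ndimage.label(np.asarray(mask) > 0, structure=_STRUCT4)
    if n == 0:
        return labels, np.array([], dtype=int)
    areas = np.bincount(labels.ravel())[1:]
    return labels, areas


def clean_heart_mask(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 4-connected component and fill its holes."""
    labels, areas = _components(mask)
    if areas.size == 0:
        return np.zeros_like(np.asarray(mask), dtype=np.uint8)
    keep = labels == (int(np.argmax(areas)) + 1)
    return ndimage.binary_fill_holes(keep, structure=_STRUCT4).astype(np.uint8)


def clean_lung_mask(mask: np.ndarray, min_area_fraction: float = 0.25) -> np.ndarray:
    """Keep components with area ≥ ``min_area_fraction`` of the largest.

    Retains either two separate lung fields or one mediastinum-merged
    thoracic component while rejecting small artifacts; holes are filled in
    each kept component.
    """
    labels, areas = _components(mask)
    if areas.size == 0:
        return np.zeros_like(np.asarray(mask), dtype=np.uint8)
    cutoff = min_area_fraction * areas.max()
    out = np.zeros(labels.shape, dtype=np.uint8)
    for lab in np.nonzero(areas >= cutoff)[0] + 1:
        comp = ndimage.binary_fill_holes(labels == lab, structure=_STRUCT4)
        out |= comp.astype(np.uint8)
    return out


def estimate_midline(lungs: np.ndarray) -> int:
    """Median over occupied rows of the row-wise lung-extent midpoint.

    Serves as the mask-based surrogate for the vertical line along the
    spinous processes; TCD itself is independent of the midline whenever
    the heart spans it, the midline only fixes the a/b decomposition.
    Rounding is to nearest, ties to even.
    """
    lungs = np.asarray(lungs) > 0
    rows = np.nonzero(lungs.any(axis=1))[0]
    if rows.size == 0:
        raise MeasurementError("empty lung mask", channel="lungs")
    mids = np.empty(rows.size)
    for i, r in enumerate(rows):
        cols = np.nonzero(lungs[r])[0]
        mids[i] = 0.5 * (cols[0] + cols[-1])
    return int(np.round(np.median(mids)))


def measure_tcd(heart: np.ndarray, midline: int) -> tuple[int, int, int]:
    """(tcd, a, b): inclusive cardiac width plus its midline decomposition.

    ``a`` is the rightward extent from the midline, ``b`` the leftward,
    both clamped at zero.
    """
    heart = np.asarray(heart) > 0
    cols = np.nonzero(heart.any(axis=0))[0]
    if cols.size == 0:
        raise MeasurementError("empty heart mask", channel="heart")
    min_c, max_c = int(cols[0]), int(cols[-1])
    a = max(max_c - int(midline), 0)
    b = max(int(midline) - min_c, 0)
    return max_c - min_c + 1, a, b


def measure_ttd(lungs: np.ndarray) -> int:
    """Inclusive thoracic width over all lung pixels."""
    lungs = np.asarray(lungs) > 0
    cols = np.nonzero(lungs.any(axis=0))[0]
    if cols.size == 0:
        raise MeasurementError("empty lung mask", channel="lungs")
    return int(cols[-1] - cols[0] + 1)


def classify_cardiomegaly(ctr: float, projection: Projection,
                          cfg: ClassifierConfig | None = None) -> CardiomegalyLabel:
    """Projection-specific strict-threshold classification."""
    cfg = cfg or ClassifierConfig()
    if not ctr > 0:
        raise ValueError("ctr must be positive")
    projection = Projection.parse(projection)
    if projection is Projection.UNKNOWN:
        return CardiomegalyLabel.INDETERMINATE
    threshold = cfg.pa_threshold if projection is Projection.PA else cfg.ap_threshold
    return (CardiomegalyLabel.CARDIOMEGALY if ctr > threshold
            else CardiomegalyLabel.NORMAL)


def compute_ctr(mask: SegmentationMask, projection: Projection = Projection.UNKNOWN,
                cfg: ClassifierConfig | None = None) -> CTRMeasurement:
    """Full deterministic pipeline: clean → midline → TCD, TTD → CTR → label."""
    cfg = cfg or ClassifierConfig()
    heart = clean_heart_mask(mask.heart)
    lungs = clean_lung_mask(mask.lungs)
    if not heart.any():
        raise MeasurementError("heart channel empty after cleaning", channel="heart")
    if not lungs.any():
        raise MeasurementError("lung channel empty after cleaning", channel="lungs")
    midline = estimate_midline(lungs)
    tcd, a, b = measure_tcd(heart, midline)
    ttd = measure_ttd(lungs)
    ctr = tcd / ttd
    return CTRMeasurement(
        tcd=tcd, ttd=ttd, a=a, b=b, midline_col=midline, ctr=ctr,
        projection=Projection.parse(projection),
        label=classify_cardiomegaly(ctr, projection, cfg),
    )
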