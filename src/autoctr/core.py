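"""Shared domain types: radiographic projection and overlapping masks."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["Projection", "SegmentationMask"]


class Projection(str, Enum):
    """Beam direction of the radiograph.

    PA (posteroanterior, standing) is the reference projection for the
    cardiothoracic ratio; AP (anteroposterior, supine/bedside) magnifies the
    cardiac silhouette, which is why it carries a higher cardiomegaly
    threshold.
    """

    PA = "PA"
    AP = "AP"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, value) -> "Projection":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            return cls.UNKNOWN


@dataclass
class SegmentationMask:
    """Two aligned binary channels, heart and lungs, that may overlap.

    The cardiac silhouette genuinely overlies the lung fields on a
    radiograph, so the two channels are stored independently rather than as
    a single label plane: a pixel may belong to both structures.
    """

    heart: np.ndarray
    lungs: np.ndarray

    def __post_init__(self):
        self.heart = np.ascontiguousarray(self.heart, dtype=np.uint8)
        self.lungs = np.ascontiguousarray(self.lungs, dtype=np.uint8)
        if self.heart.ndim != 2 or self.lungs.ndim != 2:
            raise ValueError("mask channels must be 2-D")
        if self.heart.shape != self.lungs.shape:
            raise ValueError(
                f"channel shapes differ: heart {self.heart.shape} vs "
                f"lungs {self.lungs.shape}"
            )
        for name, ch in (("heart", self.heart), ("lungs", self.lungs)):
            vals = np.unique(ch)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} channel is not binary")

    @property
    def shape(self) -> tuple:
        return self.heart.shape

    def overlap_area(self) -> int:
        """Number of pixels belonging to both heart and lungs."""
        return int(np.count_nonzero(self.heart & self.lungs))

    def stacked(self) -> np.ndarray:
        """(2, rows, cols) array in channel order (heart, lungs)."""
        return np.stack([self.heart, self.lungs])

    @classmethod
    def from_stacked(cls, arr: np.ndarray) -> "SegmentationMask":
        return cls(heart=arr[0], lungs=arr[1])
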