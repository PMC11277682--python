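"""Synthetic chest-radiograph phantoms with analytically known geometry.

Clinical radiographs and their annotations cannot be redistributed, so all
testing runs on phantoms: two elliptical lung fields (dark), an optionally
rotated elliptical cardiac silhouette (bright) overlapping the lung region,
a soft-tissue thorax background, Gaussian noise, and optional bright line
artifacts emulating drains and cables.  Ground-truth masks are exact
rasterizations of the ellipses, and the cardiothoracic ratio is known in
closed form:

* heart width = 2·sqrt(a²cos²θ + b²sin²θ) for column/row semi-axes (a, b)
  rotated by θ,
* thoracic width = outer horizontal span of the two lung ellipses,

so measured CTR can be compared against an analytic value, with the only
discrepancy being rasterization error (O(1 px) on each width).

Following the annotation convention of the training data, the lungs channel
includes the mediastinal band between the two lung fields, making TTD the
full inner thoracic width, and the heart mask overlaps the lungs channel.
Intensity ordering is radiographic (Monochrome2): lungs dark, soft tissue
intermediate, heart bright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Projection, SegmentationMask
from .ctr_geometry import (
    CardiomegalyLabel,
    ClassifierConfig,
    CTRMeasurement,
    classify_cardiomegaly,
)

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "PhantomTruth",
    "analytic_widths",
    "generate_phantom",
    "generate_dataset",
    "DEFAULT_RANGES",
]


@dataclass(frozen=True)
class Ellipse:
    center_row: float
    center_col: float
    semi_row: float
    semi_col: float


@dataclass(frozen=True)
class PhantomSpec:
    canvas: tuple = (256, 256)
    lung_left: Ellipse = Ellipse(128.0, 72.0, 80.0, 44.0)
    lung_right: Ellipse = Ellipse(128.0, 184.0, 80.0, 44.0)
    heart: Ellipse = Ellipse(150.0, 128.0, 36.0, 50.0)
    heart_angle: float = 0.0
    intensities: tuple = (0.05, 0.55, 0.25, 0.85)  # background, soft, lung, heart
    noise_sigma: float = 0.02
    n_artifact_lines: int = 0
    projection: Projection = Projection.PA
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.canvas
        for name, e in (("lung_left", self.lung_left),
                        ("lung_right", self.lung_right),
                        ("heart", self.heart)):
            if (e.center_row - e.semi_row < 0 or e.center_row + e.semi_row > rows - 1
                    or e.center_col - e.semi_col < 0
                    or e.center_col + e.semi_col > cols - 1):
                raise ValueError(f"{name} ellipse exceeds the canvas")
        bg, soft, lung, heart = self.intensities
        if not (lung < soft < heart):
            raise ValueError("require lung < soft_tissue < heart intensity")
        hw = 0.5 * _heart_width(self.heart, self.heart_angle)
        left_inner = self.lung_left.center_col + self.lung_left.semi_col
        right_inner = self.lung_right.center_col - self.lung_right.semi_col
        if (self.heart.center_col + hw <= right_inner
                and self.heart.center_col - hw >= left_inner):
            raise ValueError("heart does not overlap the lung region horizontally")


@dataclass(frozen=True)
class PhantomTruth:
    image: np.ndarray
    mask: SegmentationMask
    analytic: CTRMeasurement
    spec: PhantomSpec


def _heart_width(e: Ellipse, theta: float) -> float:
    a, b = e.semi_col, e.semi_row
    return 2.0 * math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)


def analytic_widths(spec: PhantomSpec) -> tuple[float, float]:
    """Closed-form (TCD, TTD) of the continuous phantom geometry."""
    tcd = _heart_width(spec.heart, spec.heart_angle)
    ttd = ((spec.lung_right.center_col + spec.lung_right.semi_col)
           - (spec.lung_left.center_col - spec.lung_left.semi_col))
    return tcd, ttd


def _analytic_measurement(spec: PhantomSpec,
                          cfg: ClassifierConfig | None = None) -> CTRMeasurement:
    tcd, ttd = analytic_widths(spec)
    left_edge = spec.lung_left.center_col - spec.lung_left.semi_col
    midline = left_edge + ttd / 2.0
    a = (spec.heart.center_col + tcd / 2.0) - midline
    b = midline - (spec.heart.center_col - tcd / 2.0)
    ctr = tcd / ttd
    return CTRMeasurement(
        tcd=tcd, ttd=ttd, a=a, b=b, midline_col=midline, ctr=ctr,
        projection=spec.projection,
        label=classify_cardiomegaly(ctr, spec.projection, cfg),
    )


def _inside(rr: np.ndarray, cc: np.ndarray, e: Ellipse,
            theta: float = 0.0) -> np.ndarray:
    dr = rr - e.center_row
    dc = cc - e.center_col
    if theta:
        u = dc * math.cos(theta) + dr * math.sin(theta)
        v = -dc * math.sin(theta) + dr * math.cos(theta)
    else:
        u, v = dc, dr
    return (u / e.semi_col) ** 2 + (v / e.semi_row) ** 2 <= 1.0


def _rasterize_lungs(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.canvas
    rr, cc = np.ogrid[:rows, :cols]
    left = _inside(rr, cc, spec.lung_left)
    right = _inside(rr, cc, spec.lung_right)
    lungs = left | right
    # mediastinal band: on rows where both lungs are present, annotate the
    # gap between them too (TTD then equals the full inner thoracic width)
    both = left.any(axis=1) & right.any(axis=1)
    for r in np.nonzero(both)[0]:
        lcols = np.nonzero(left[r])[0]
        rcols = np.nonzero(right[r])[0]
        if lcols[-1] < rcols[0]:
            lungs[r, lcols[-1] : rcols[0] + 1] = True
    return lungs


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize masks, compose the intensity image, add noise + artifacts."""
    rows, cols = spec.canvas
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.ogrid[:rows, :cols]

    lungs = _rasterize_lungs(spec)
    heart = _inside(rr, cc, spec.heart, spec.heart_angle)

    bg, soft, lung_i, heart_i = spec.intensities
    thorax = Ellipse(
        center_row=0.5 * (spec.lung_left.center_row + spec.lung_right.center_row),
        center_col=0.5 * (spec.lung_left.center_col + spec.lung_right.center_col),
        semi_row=min(rows / 2 - 1,
                     max(spec.lung_left.semi_row, spec.lung_right.semi_row) * 1.25),
        semi_col=min(cols / 2 - 1,
                     (spec.lung_right.center_col + spec.lung_right.semi_col
                      - spec.lung_left.center_col + spec.lung_left.semi_col) * 0.62),
    )
    image = np.full((rows, cols), bg, dtype=np.float64)
    image[_inside(rr, cc, thorax)] = soft
    image[lungs] = lung_i
    image[heart] = heart_i  # heart painted last: silhouette is brightest

    if spec.n_artifact_lines:
        from skimage.draw import line as _line

        for _ in range(spec.n_artifact_lines):
            r0, r1 = rng.integers(0, rows, size=2)
            c0, c1 = rng.integers(0, cols, size=2)
            lr, lc = _line(int(r0), int(c0), int(r1), int(c1))
            width = int(rng.integers(1, 4))
            for off in range(-(width // 2), width - width // 2):
                rs = np.clip(lr + off, 0, rows - 1)
                image[rs, lc] = min(1.0, heart_i + 0.1)

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    mask = SegmentationMask(heart=heart.astype(np.uint8),
                            lungs=lungs.astype(np.uint8))
    return PhantomTruth(image=image, mask=mask,
                        analytic=_analytic_measurement(spec), spec=spec)


# Parameter ranges emulating the spread of adult chest radiographs: CTR is
# drawn uniformly across 0.40-0.70 so both sides of the 0.55 PA threshold
# (and the 0.58 AP threshold) are exercised.
DEFAULT_RANGES: dict = {
    "ctr": (0.40, 0.70),
    "ttd_fraction": (0.70, 0.90),      # thoracic width / canvas width
    "lung_height_fraction": (0.50, 0.70),
    "heart_aspect": (0.55, 0.80),      # row semi-axis / col semi-axis
    "heart_angle": (-0.10, 0.10),      # radians
    "heart_drop_fraction": (0.05, 0.15),  # heart center below mid-canvas
    "noise_sigma": (0.01, 0.03),
    "n_artifact_lines": (0, 3),        # inclusive integer range
}


def _uniform(rng, lo, hi):
    return float(rng.uniform(lo, hi))


def random_spec(rng: np.random.Generator, canvas: tuple = (256, 256),
                ranges: dict | None = None,
                projection: Projection | None = None) -> PhantomSpec:
    """Draw one phantom geometry from parameter ranges."""
    rg = dict(DEFAULT_RANGES)
    if ranges:
        rg.update(ranges)
    rows, cols = canvas
    ttd = _uniform(rng, *rg["ttd_fraction"]) * cols
    center_col = cols / 2.0
    lung_semi_col = 0.22 * ttd
    lung_semi_row = _uniform(rng, *rg["lung_height_fraction"]) * rows / 2.0
    left_center = center_col - ttd / 2.0 + lung_semi_col
    right_center = center_col + ttd / 2.0 - lung_semi_col
    lung_row = rows / 2.0

    ctr = _uniform(rng, *rg["ctr"])
    theta = _uniform(rng, *rg["heart_angle"])
    aspect = _uniform(rng, *rg["heart_aspect"])
    # solve the column semi-axis so the rotated width matches ctr exactly
    half_w = ctr * ttd / 2.0
    a = half_w / math.sqrt(math.cos(theta) ** 2 + aspect ** 2 * math.sin(theta) ** 2)
    b = aspect * a
    heart_row = rows / 2.0 + _uniform(rng, *rg["heart_drop_fraction"]) * rows
    heart_row = min(heart_row, rows - 1 - b)

    lo, hi = rg["n_artifact_lines"]
    proj = projection if projection is not None else (
        Projection.PA if rng.random() < 0.5 else Projection.AP)
    return PhantomSpec(
        canvas=canvas,
        lung_left=Ellipse(lung_row, left_center, lung_semi_row, lung_semi_col),
        lung_right=Ellipse(lung_row, right_center, lung_semi_row, lung_semi_col),
        heart=Ellipse(heart_row, center_col, b, a),
        heart_angle=theta,
        noise_sigma=_uniform(rng, *rg["noise_sigma"]),
        n_artifact_lines=int(rng.integers(lo, hi + 1)),
        projection=proj,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(n: int, ranges: dict | None = None, seed: int = 0,
                     canvas: tuple = (256, 256)) -> list[PhantomTruth]:
    """``n`` independent phantoms with parameters drawn from ``ranges``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [generate_phantom(random_spec(rng, canvas=canvas, ranges=ranges))
            for _ in range(n)]
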