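"""Segmentation metrics and observer-agreement statistics.

Two families of checks mirror how a segmentation-based CTR tool is
validated:

* overlap metrics of the predicted masks against reference masks — IoU
  (Jaccard) and F1 (Dice), pooled over all pixels of a subset
  (micro-average) and averaged equally over the heart and lung channels;
  the two are algebraically linked by F1 = 2·IoU/(1 + IoU);
* nonparametric comparisons of per-image measurements (TCD, TTD, CTR)
  between the model and human observers — Mann-Whitney U for the
  model-vs-human shift, Kruskal-Wallis for inter-observer differences,
  Spearman rank correlation for monotone agreement, with normality
  screened by Lilliefors and Kolmogorov-Smirnov tests and Tukey-fence
  outlier removal before the group comparisons.

Measurement tables are pandas DataFrames with columns
``source_id, observer, tcd, ttd, ctr, time_s, projection``; human
observers are any rows whose observer is not "AI", and ``average_observers``
adds a synthetic "HUMAN_MEAN" observer per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EvalReport",
    "StatsReport",
    "iou",
    "f1",
    "evaluate_model",
    "remove_outliers",
    "average_observers",
    "compare_ai_vs_humans",
    "compare_observers",
    "VARIABLES",
]

VARIABLES = ("tcd", "ttd", "ctr")
AI = "AI"
HUMAN_MEAN = "HUMAN_MEAN"


@dataclass
class EvalReport:
    iou_heart: float
    iou_lungs: float
    f1_heart: float
    f1_lungs: float
    n_images: int

    @property
    def iou_mean(self) -> float:
        return 0.5 * (self.iou_heart + self.iou_lungs)

    @property
    def f1_mean(self) -> float:
        return 0.5 * (self.f1_heart + self.f1_lungs)

    def to_dict(self) -> dict:
        return {
            "iou_heart": self.iou_heart, "iou_lungs": self.iou_lungs,
            "iou_mean": self.iou_mean, "f1_heart": self.f1_heart,
            "f1_lungs": self.f1_lungs, "f1_mean": self.f1_mean,
            "n_images": self.n_images,
        }


@dataclass
class StatsReport:
    normality: dict = field(default_factory=dict)      # var -> (lilliefors_p, ks_p)
    mann_whitney: dict = field(default_factory=dict)   # var -> (U, p)
    kruskal_wallis: dict = field(default_factory=dict) # var -> (H, p)
    spearman: dict = field(default_factory=dict)       # var -> (rho, rho2, p)
    outliers_removed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "normality": self.normality,
            "mann_whitney": self.mann_whitney,
            "kruskal_wallis": self.kruskal_wallis,
            "spearman": self.spearman,
            "outliers_removed": self.outliers_removed,
        }


def _confusion(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred > 0
    t = truth > 0
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, fp, fn


def iou(pred, truth) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    tp, fp, fn = _confusion(pred, truth)
    denom = tp + fp + fn
    return tp / denom if denom else 1.0


def f1(pred, truth) -> float:
    """Dice / F1 overlap, 2TP/(2TP+FP+FN); 1.0 when both masks are empty."""
    tp, fp, fn = _confusion(pred, truth)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def evaluate_model(model, dataset, threshold: float = 0.5) -> EvalReport:
    """Micro-averaged per-channel IoU/F1 of thresholded predictions.

    ``model`` is either a callable mapping a 2-D standardized image to a
    (2, rows, cols) probability map, or a trained U-Net; ``dataset`` is
    (images (N, H, W), masks (N, 2, H, W)).
    """
    images, masks = dataset
    images = np.asarray(images)
    masks = np.asarray(masks)
    if len(images) == 0:
        raise ValueError("empty dataset")
    if callable(model):
        predict_fn = model
    else:
        from . import unet as _unet

        predict_fn = lambda im: _unet.predict(model, im)  # noqa: E731
    counts = np.zeros((2, 3), dtype=np.int64)  # channel x (tp, fp, fn)
    for im, truth in zip(images, masks):
        prob = np.asarray(predict_fn(im))
        pred = prob > threshold
        for ch in range(2):
            counts[ch] += _confusion(pred[ch], truth[ch])
    out = {}
    for ch, name in enumerate(("heart", "lungs")):
        tp, fp, fn = counts[ch]
        out[f"iou_{name}"] = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
        out[f"f1_{name}"] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return EvalReport(n_images=len(images), **out)


def remove_outliers(values, k: float = 1.5):
    """Drop points outside the closed Tukey fences Q1 − k·IQR .. Q3 + k·IQR.

    At the default k = 1.5 this discards both "outliers" and the more
    distant "extremes" (3·IQR); order is preserved and ties at the fences
    are kept.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 4:
        raise ValueError("need at least 4 values for fence estimation")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return values[(values >= lo) & (values <= hi)]


def _require_columns(table: pd.DataFrame):
    missing = {"source_id", "observer", *VARIABLES} - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")


def average_observers(table: pd.DataFrame) -> pd.DataFrame:
    """Append a synthetic HUMAN_MEAN observer per image (mean of human rows)."""
    _require_columns(table)
    humans = table[~table["observer"].isin([AI, HUMAN_MEAN])]
    if humans.empty:
        raise ValueError("no human observer rows in table")
    agg = humans.groupby("source_id", as_index=False)[list(VARIABLES)].mean()
    agg["observer"] = HUMAN_MEAN
    if "projection" in table.columns:
        proj = humans.groupby("source_id")["projection"].first()
        agg["projection"] = agg["source_id"].map(proj)
    out = pd.concat([table[table["observer"] != HUMAN_MEAN], agg],
                    ignore_index=True)
    return out


def _normality(values) -> tuple:
    from statsmodels.stats.diagnostic import lilliefors

    values = np.asarray(values, dtype=np.float64)
    if values.std(ddof=1) == 0:  # constant sample: normality undefined
        return float("nan"), float("nan")
    _, lp = lilliefors(values, dist="norm")
    z = (values - values.mean()) / values.std(ddof=1)
    _, kp = sps.kstest(z, "norm")
    return float(lp), float(kp)


def compare_ai_vs_humans(table: pd.DataFrame, min_pairs: int = 10) -> StatsReport:
    """Model-vs-human comparison per variable (TCD, TTD, CTR).

    Outliers are removed from each group before the two-sided Mann-Whitney
    U test; Spearman rank correlation runs on the paired per-image values.
    """
    _require_columns(table)
    if HUMAN_MEAN not in set(table["observer"]):
        table = average_observers(table)
    ai = table[table["observer"] == AI].set_index("source_id")
    hm = table[table["observer"] == HUMAN_MEAN].set_index("source_id")
    shared = ai.index.intersection(hm.index)
    if len(shared) < min_pairs:
        raise ValueError(f"need >= {min_pairs} shared images, have {len(shared)}")
    report = StatsReport()
    for var in VARIABLES:
        x = ai.loc[shared, var].to_numpy(dtype=float)
        y = hm.loc[shared, var].to_numpy(dtype=float)
        xc = remove_outliers(x)
        yc = remove_outliers(y)
        report.outliers_removed[var] = int((x.size - xc.size) + (y.size - yc.size))
        u, p = sps.mannwhitneyu(xc, yc, alternative="two-sided")
        report.mann_whitney[var] = (float(u), float(p))
        if np.ptp(x) == 0 or np.ptp(y) == 0:  # rank correlation undefined
            rho, sp = float("nan"), float("nan")
        else:
            rho, sp = sps.spearmanr(x, y)
        report.spearman[var] = (float(rho), float(rho) ** 2, float(sp))
        report.normality[var] = _normality(np.concatenate([x, y]))
    return report


def compare_observers(table: pd.DataFrame) -> StatsReport:
    """Kruskal-Wallis H across human observer groups, per variable."""
    _require_columns(table)
    humans = table[~table["observer"].isin([AI, HUMAN_MEAN])]
    groups = [g for _, g in humans.groupby("observer")]
    if len(groups) < 2:
        raise ValueError("need at least 2 human observers")
    report = StatsReport()
    for var in VARIABLES:
        samples = [g[var].to_numpy(dtype=float) for g in groups]
        h, p = sps.kruskal(*samples)
        report.kruskal_wallis[var] = (float(h), float(p))
    return report
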