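"""Two-channel overlapping-output U-Net, its losses and its training loop.

The segmentation problem is multi-LABEL, not multi-class: the cardiac
silhouette overlies the lung fields, so a pixel may belong to both
structures.  The output head is therefore a per-channel sigmoid (one
independent probability per structure), and the loss is a weighted sum of
focal loss (pixel-wise, down-weighting easy pixels) and dice loss
(overlap-based, per channel).

The reference configuration — five resolution levels, base width 16
doubling per level, two 3×3 convolutions per block, 2×2 transposed-conv
upsampling with skip concatenation, no batch normalization, 2-channel 1×1
sigmoid head — has exactly 1,940,834 trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, Concat, Conv2D, ConvTranspose2, MaxPool2, ReLU

__all__ = [
    "UNetConfig",
    "LossConfig",
    "TrainingConfig",
    "TrainingHistory",
    "UNet",
    "build_unet",
    "count_parameters",
    "dice_loss",
    "focal_loss",
    "combined_loss",
    "train",
    "predict",
    "save_model",
    "load_model",
    "TrainingDivergedError",
]

_EPS = 1e-7


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class UNetConfig:
    input_shape: tuple = (256, 256, 1)
    n_levels: int = 5
    base_filters: int = 16
    convs_per_block: int = 2
    out_channels: int = 2

    def __post_init__(self):
        if self.n_levels < 1 or self.base_filters < 1:
            raise ValueError("n_levels and base_filters must be positive")
        h, w = self.input_shape[0], self.input_shape[1]
        stride = 2 ** (self.n_levels - 1)
        if h % stride or w % stride:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^(n_levels-1) = {stride}"
            )


@dataclass(frozen=True)
class LossConfig:
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    dice_smooth: float = 1.0
    focal_weight: float = 1.0
    dice_weight: float = 1.0

    def __post_init__(self):
        vals = asdict(self)
        if any(v < 0 for v in vals.values()):
            raise ValueError("loss parameters must be nonnegative")
        if self.focal_weight == 0 and self.dice_weight == 0:
            raise ValueError("focal_weight and dice_weight cannot both be zero")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    epochs: int = 56
    batch_size: int = 64
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_lr: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainingHistory:
    """Per-epoch training records; ``lr`` is non-increasing by construction."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_iou: list = field(default_factory=list)
    val_iou: list = field(default_factory=list)
    train_f1: list = field(default_factory=list)
    val_f1: list = field(default_factory=list)
    lr: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_dataframe(self):
        import pandas as pd

        d = asdict(self)
        d["epoch"] = list(range(1, len(self) + 1))
        return pd.DataFrame(d)[
            ["epoch", "train_loss", "val_loss", "train_iou", "val_iou",
             "train_f1", "val_f1", "lr"]
        ]


class UNet:
    """Encoder/decoder network with skip concatenations.

    Encoder: ``n_levels`` blocks of ``convs_per_block`` 3×3 convolutions +
    ReLU, with 2×2 max pooling between blocks and filter width doubling per
    level.  Decoder: symmetric, with 2×2 transposed convolutions and skip
    concatenation.  Output: 1×1 convolution, per-channel sigmoid.
    """

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        cin = cfg.input_shape[2] if len(cfg.input_shape) > 2 else 1
        self.enc_blocks = []
        self.pools = []
        for lvl in range(cfg.n_levels):
            f = cfg.base_filters * 2 ** lvl
            block = []
            c = cin if lvl == 0 else cfg.base_filters * 2 ** (lvl - 1)
            for _ in range(cfg.convs_per_block):
                block.append((Conv2D(c, f, 3, rng), ReLU()))
                c = f
            self.enc_blocks.append(block)
            if lvl < cfg.n_levels - 1:
                self.pools.append(MaxPool2())
        self.dec_blocks = []
        for lvl in reversed(range(cfg.n_levels - 1)):
            f = cfg.base_filters * 2 ** lvl
            up = ConvTranspose2(f * 2, f, rng)
            cat = Concat()
            block = []
            c = f * 2  # skip (f) + upsampled (f)
            for _ in range(cfg.convs_per_block):
                block.append((Conv2D(c, f, 3, rng), ReLU()))
                c = f
            self.dec_blocks.append((up, cat, block))
        self.out_conv = Conv2D(cfg.base_filters, cfg.out_channels, 1, rng)
        self._prob = None

    # -- graph traversal ----------------------------------------------------

    def layers(self):
        for block in self.enc_blocks:
            for conv, _ in block:
                yield conv
        for up, _, block in self.dec_blocks:
            yield up
            for conv, _ in block:
                yield conv
        yield self.out_conv

    def n_parameters(self) -> int:
        return sum(l.n_params() for l in self.layers())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, C, H, W) -> per-channel probabilities (B, out, H, W)."""
        h = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for lvl, block in enumerate(self.enc_blocks):
            for conv, relu in block:
                h = relu.forward(conv.forward(h))
            if lvl < self.cfg.n_levels - 1:
                skips.append(h)
                h = self.pools[lvl].forward(h)
        for up, cat, block in self.dec_blocks:
            h = up.forward(h)
            h = cat.forward(skips.pop(), h)
            for conv, relu in block:
                h = relu.forward(conv.forward(h))
        logits = self.out_conv.forward(h)
        # float64 with clipped logits keeps probabilities strictly in (0, 1)
        z = np.clip(logits.astype(np.float64), -30.0, 30.0)
        self._prob = 1.0 / (1.0 + np.exp(-z))
        return self._prob

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/d(probabilities)."""
        p = self._prob
        dz = (dprob * p * (1.0 - p)).astype(np.float32)
        dh = self.out_conv.backward(dz)
        dskips = []
        for up, cat, block in reversed(self.dec_blocks):
            for conv, relu in reversed(block):
                dh = conv.backward(relu.backward(dh))
            dskip, dh = cat.backward(dh)
            dskips.append(dskip)
            dh = up.backward(dh)
        for lvl in reversed(range(self.cfg.n_levels)):
            if lvl < self.cfg.n_levels - 1:
                dh = self.pools[lvl].backward(dh)
                dh = dh + dskips.pop()
            for conv, relu in reversed(self.enc_blocks[lvl]):
                dh = conv.backward(relu.backward(dh))


def build_unet(cfg: UNetConfig | None = None,
               rng: np.random.Generator | None = None) -> UNet:
    """Instantiate the network; raises if the input size is indivisible."""
    return UNet(cfg or UNetConfig(), rng)


def count_parameters(cfg: UNetConfig | None = None) -> int:
    """Total trainable scalar parameters of ``build_unet(cfg)``."""
    return build_unet(cfg).n_parameters()


# -- losses -----------------------------------------------------------------


def _check_shapes(pred, truth):
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def dice_loss(pred: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> float:
    """1 − (2·Σpt + s)/(Σp + Σt + s), averaged over leading (channel) axes.

    2-D inputs are treated as a single channel; for (C, H, W) or
    (B, C, H, W) inputs the loss is computed per channel and averaged.
    """
    pred, truth = _check_shapes(pred, truth)
    k = int(np.prod(pred.shape[:-2], dtype=int)) if pred.ndim > 2 else 1
    p = pred.reshape(k, -1)
    t = truth.reshape(k, -1)
    num = 2.0 * (p * t).sum(axis=1) + smooth
    den = p.sum(axis=1) + t.sum(axis=1) + smooth
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, 1.0)
    return float(np.mean(1.0 - d))


def focal_loss(pred: np.ndarray, truth: np.ndarray,
               alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Mean over pixels of −α_t (1−p_t)^γ log(p_t).

    ``p_t`` is the predicted probability of the true class; α weights
    positives by ``alpha`` and negatives by ``1 − alpha``; γ = 0 with
    α = 0.5 reduces to half the binary cross-entropy.
    """
    pred, truth = _check_shapes(pred, truth)
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    pt = np.where(truth > 0.5, p, 1.0 - p)
    at = np.where(truth > 0.5, alpha, 1.0 - alpha)
    return float(np.mean(-at * (1.0 - pt) ** gamma * np.log(pt)))


def combined_loss(pred: np.ndarray, truth: np.ndarray,
                  cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    return (cfg.focal_weight * focal_loss(pred, truth, cfg.focal_alpha, cfg.focal_gamma)
            + cfg.dice_weight * dice_loss(pred, truth, cfg.dice_smooth))


def _combined_loss_grad(pred: np.ndarray, truth: np.ndarray,
                        cfg: LossConfig) -> tuple:
    """Loss value and dL/d(pred) for a (B, C, H, W) batch.

    Dice is computed per (sample, channel) and averaged, matching the
    scalar loss functions; the analytic gradients here are verified against
    finite differences in the test suite.
    """
    p = np.clip(pred.astype(np.float64), _EPS, 1.0 - _EPS)
    t = truth.astype(np.float64)
    n_px = p.size

    # focal term
    pos = t > 0.5
    pt = np.where(pos, p, 1.0 - p)
    at = np.where(pos, cfg.focal_alpha, 1.0 - cfg.focal_alpha)
    g = cfg.focal_gamma
    one_m = 1.0 - pt
    focal = float(np.mean(-at * one_m ** g * np.log(pt)))
    # d/dpt of -a (1-pt)^g log pt
    dfocal_dpt = -at * (one_m ** g / pt - g * one_m ** np.maximum(g - 1.0, 0.0) * np.log(pt))
    dfocal = np.where(pos, dfocal_dpt, -dfocal_dpt) / n_px

    # dice term, per (sample, channel)
    b, c = p.shape[0], p.shape[1]
    k = b * c
    pf = p.reshape(k, -1)
    tf = t.reshape(k, -1)
    s = cfg.dice_smooth
    num = 2.0 * (pf * tf).sum(axis=1) + s
    den = pf.sum(axis=1) + tf.sum(axis=1) + s
    dice = float(np.mean(1.0 - num / den))
    ddice_flat = -(2.0 * tf * den[:, None] - num[:, None]) / den[:, None] ** 2 / k
    ddice = ddice_flat.reshape(p.shape)

    loss = cfg.focal_weight * focal + cfg.dice_weight * dice
    dpred = cfg.focal_weight * dfocal + cfg.dice_weight * ddice
    return loss, dpred


# -- training / inference ---------------------------------------------------


def _batch_metrics(prob: np.ndarray, truth: np.ndarray):
    """Pooled-pixel TP/FP/FN of thresholded predictions (both channels)."""
    pred = prob > 0.5
    t = truth > 0.5
    tp = int(np.count_nonzero(pred & t))
    fp = int(np.count_nonzero(pred & ~t))
    fn = int(np.count_nonzero(~pred & t))
    return tp, fp, fn


def _iou_f1_from_counts(tp, fp, fn):
    denom = tp + fp + fn
    iou = tp / denom if denom else 1.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return iou, f1


def _as_arrays(dataset):
    """Accept (images, masks) arrays or a sequence of (image, mask) pairs."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        images, masks = dataset
        images = np.asarray(images, dtype=np.float32)
        masks = np.asarray(masks, dtype=np.float32)
    else:
        from .core import SegmentationMask

        images = np.stack([np.asarray(im, dtype=np.float32) for im, _ in dataset])
        masks = np.stack([
            m.stacked().astype(np.float32) if isinstance(m, SegmentationMask)
            else np.asarray(m, dtype=np.float32)
            for _, m in dataset
        ])
    if images.ndim != 3 or masks.ndim != 4:
        raise ValueError("expected images (N, H, W) and masks (N, 2, H, W)")
    if len(images) == 0:
        raise ValueError("empty dataset")
    return images, masks


def train(model: UNet, train_set, val_set,
          tcfg: TrainingConfig | None = None,
          lcfg: LossConfig | None = None,
          acfg=None) -> TrainingHistory:
    """Adam training with reduce-on-plateau learning-rate scheduling.

    ``train_set``/``val_set`` are (images, masks) arrays with images
    (N, H, W) already standardized and masks (N, 2, H, W) binary, or
    sequences of (image, SegmentationMask) pairs.  If ``acfg`` (an
    :class:`autoctr.preprocess.AugmentConfig`) is given, each training
    sample is geometrically augmented afresh every epoch.
    """
    tcfg = tcfg or TrainingConfig()
    lcfg = lcfg or LossConfig()
    x_tr, y_tr = _as_arrays(train_set)
    x_va, y_va = _as_arrays(val_set)

    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.layers(), lr=tcfg.learning_rate)
    history = TrainingHistory()

    best_val = np.inf
    stale = 0
    lr = tcfg.learning_rate
    n = len(x_tr)

    aug = None
    if acfg is not None:
        from . import preprocess as _pp
        from .core import SegmentationMask as _SM

        def aug(img, mask2):  # noqa: E731 - local closure
            im2, m2 = _pp.augment(img, _SM(mask2[0], mask2[1]), acfg, rng)
            return im2, m2.stacked().astype(np.float32)

    for _epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        tp = fp = fn = 0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb = x_tr[idx]
            yb = y_tr[idx]
            if aug is not None:
                pairs = [aug(xb[i], yb[i]) for i in range(len(idx))]
                xb = np.stack([p[0] for p in pairs]).astype(np.float32)
                yb = np.stack([p[1] for p in pairs])
            prob = model.forward(xb[:, None])
            loss, dprob = _combined_loss_grad(prob, yb, lcfg)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {_epoch + 1}")
            model.backward(dprob)
            opt.lr = lr
            opt.step()
            ep_loss += loss * len(idx)
            btp, bfp, bfn = _batch_metrics(prob, yb)
            tp, fp, fn = tp + btp, fp + bfp, fn + bfn
        train_loss = ep_loss / n
        train_iou, train_f1 = _iou_f1_from_counts(tp, fp, fn)

        val_prob = model.forward(x_va[:, None])
        val_loss, _ = _combined_loss_grad(val_prob, y_va, lcfg)
        val_iou, val_f1 = _iou_f1_from_counts(*_batch_metrics(val_prob, y_va))

        history.train_loss.append(train_loss)
        history.val_loss.append(float(val_loss))
        history.train_iou.append(train_iou)
        history.val_iou.append(val_iou)
        history.train_f1.append(train_f1)
        history.val_f1.append(val_f1)
        history.lr.append(lr)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= tcfg.plateau_patience:
                lr = max(lr * tcfg.plateau_factor, tcfg.min_lr)
                stale = 0
    return history


def predict(model: UNet, img: np.ndarray) -> np.ndarray:
    """Probability maps for one standardized image.

    Returns a (2, rows, cols) array in channel order (heart, lungs), each
    value in [0, 1].  Inference is deterministic.
    """
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D image")
    h, w = img.shape
    eh, ew = model.cfg.input_shape[0], model.cfg.input_shape[1]
    if (h, w) != (eh, ew):
        raise ValueError(f"image {h}x{w} does not match model input {eh}x{ew}")
    return model.forward(img[None, None])[0]


# -- checkpointing ----------------------------------------------------------


def save_model(model: UNet, path) -> None:
    arrays = {}
    for i, layer in enumerate(model.layers()):
        arrays[f"W{i}"] = layer.W
        arrays[f"b{i}"] = layer.b
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> UNet:
    with np.load(path) as data:
        cfg_d = json.loads(bytes(data["config_json"]).decode())
        cfg_d["input_shape"] = tuple(cfg_d["input_shape"])
        model = build_unet(UNetConfig(**cfg_d))
        for i, layer in enumerate(model.layers()):
            layer.W = data[f"W{i}"].copy()
            layer.b = data[f"b{i}"].copy()
    return model
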