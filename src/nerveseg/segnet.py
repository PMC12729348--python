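"""4-level encoder–decoder segmentation network and its training loop.

The architecture is the canonical U-Net for biomedical segmentation: an
encoder of ``depth`` levels (two 3x3 convolutions + ReLU per level, 2x2
max-pooling between levels), a mirrored decoder with learned transposed-conv
upsampling and skip concatenations, and a 1x1 projection to two classes
(nerve vs background) with a per-pixel softmax. Training uses categorical
cross-entropy on one-hot masks with Adam; by default the recipe is
lr 1e-4, batch 4, 100 epochs and no early stopping. A scaled-down profile
(128x128 inputs, 8 base filters, 30 epochs, lr 1e-3) is provided for
CPU-budget runs.

The public surface follows the model/results idiom: configure a
:class:`UNetSegmenter`, call :meth:`~UNetSegmenter.fit` on image–mask pairs,
and use the returned :class:`SegmentationFit` for prediction, evaluation and
learning-curve access.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .metrics import confusion, dice

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "SCALED_TRAIN",
    "LearningCurves",
    "UNet",
    "build_model",
    "UNetSegmenter",
    "SegmentationFit",
    "train",
    "predict_mask",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``input_size`` (H, W) must be divisible by ``2**depth`` so every
    pooling stage halves cleanly.
    """

    depth: int = 4
    base_filters: int = 16
    input_size: tuple[int, int] = (1024, 1024)
    in_channels: int = 1
    out_classes: int = 2

    def __post_init__(self):
        h, w = self.input_size
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.depth}"
            )
        if self.out_classes != 2:
            raise ValueError("binary segmentation requires out_classes=2")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe. Defaults mirror the reference recipe
    (categorical cross-entropy, Adam at 1e-4, 100 epochs, batch 4, no
    early stopping); every field may be overridden for scaled-down runs."""

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 4
    validation_fraction: float = 0.1
    seed: int = 0


#: CPU-budget training profile used by the desk-scale experiments.
SCALED_TRAIN = TrainConfig(learning_rate=1e-3, epochs=30, batch_size=4)


@dataclass
class LearningCurves:
    """Per-epoch training/validation loss and pixel accuracy."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


class UNet:
    """The raw network: parameter container plus forward/backward passes."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        d, f = config.depth, config.base_filters
        self.enc: list[list] = []
        ch = config.in_channels
        for lvl in range(d):
            out = f << lvl
            self.enc.append(
                [nn.Conv3x3(ch, out, rng), nn.ReLU(), nn.Conv3x3(out, out, rng), nn.ReLU()]
            )
            ch = out
        self.pools = [nn.MaxPool2() for _ in range(d)]
        bott = f << d
        self.bottleneck = [
            nn.Conv3x3(ch, bott, rng), nn.ReLU(), nn.Conv3x3(bott, bott, rng), nn.ReLU()
        ]
        self.ups: list[nn.UpConv2] = []
        self.dec: list[list] = []
        ch = bott
        for lvl in reversed(range(d)):
            out = f << lvl
            self.ups.append(nn.UpConv2(ch, out, rng))
            self.dec.append(
                [nn.Conv3x3(2 * out, out, rng), nn.ReLU(), nn.Conv3x3(out, out, rng), nn.ReLU()]
            )
            ch = out
        self.head = nn.Conv1x1(ch, config.out_classes, rng)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.bottleneck
        for up, blk in zip(self.ups, self.dec):
            yield up
            yield from blk
        yield self.head

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for lay in self._layers():
            out.extend(lay.params)
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out = []
        for lay in self._layers():
            out.extend(lay.grads)
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """NCHW float32 batch -> per-pixel class logits (N, 2, H, W)."""
        h, w = self.config.input_size
        if x.shape[2:] != (h, w):
            raise ValueError(f"expected {h}x{w} input, got {x.shape[2:]}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            for lay in blk:
                x = lay.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for lay in self.bottleneck:
            x = lay.forward(x, train)
        self._skip_ch = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_ch.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for lay in blk:
                x = lay.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, blk, sc in zip(reversed(self.ups), reversed(self.dec), reversed(self._skip_ch)):
            for lay in reversed(blk):
                dx = lay.backward(dx)
            dskips.append(dx[:, :sc])
            dx = up.backward(np.ascontiguousarray(dx[:, sc:]))
        for lay in reversed(self.bottleneck):
            dx = lay.backward(dx)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dx = pool.backward(dx)
            dx = dx + dskip
            for lay in reversed(blk):
                dx = lay.backward(dx)

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, images: np.ndarray, batch: int = 8) -> np.ndarray:
        """Class probabilities for a stack of (N, H, W) images in [0, 1]."""
        images = np.asarray(images, dtype=np.float32)
        out = []
        for i in range(0, len(images), batch):
            x = images[i : i + batch][:, None]
            out.append(nn.softmax2(self.forward(x, train=False)))
        return np.concatenate(out, axis=0)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez_compressed(
            path,
            depth=self.config.depth,
            base_filters=self.config.base_filters,
            input_size=np.array(self.config.input_size),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as z:
            cfg = UNetConfig(
                depth=int(z["depth"]),
                base_filters=int(z["base_filters"]),
                input_size=tuple(int(v) for v in z["input_size"]),
            )
            model = cls(cfg, np.random.default_rng(0))
            for i, p in enumerate(model.params):
                p[...] = z[f"p{i}"]
        return model


def build_model(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct an initialized network from an architecture config."""
    return UNet(config, np.random.default_rng(seed))


def _onehot(masks: np.ndarray) -> np.ndarray:
    """(N, H, W) boolean masks -> (N, 2, H, W) one-hot float32."""
    fg = masks.astype(np.float32)[:, None]
    return np.concatenate([1.0 - fg, fg], axis=1)


def train(model: UNet, images: np.ndarray, masks: np.ndarray,
          cfg: TrainConfig) -> tuple[UNet, LearningCurves]:
    """Mini-batch training for exactly ``cfg.epochs`` epochs.

    ``images`` is (N, H, W) float32 in [0, 1]; ``masks`` is (N, H, W)
    boolean. A ``validation_fraction`` carve-out of the training set is
    monitored per epoch (never optimized on); set it to 0 to disable.
    Deterministic for a fixed seed. Raises on an empty dataset or a
    non-finite loss.
    """
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks).astype(bool)
    n = len(images)
    if n == 0:
        raise ValueError("empty training dataset")
    if images.shape[:1] != masks.shape[:1] or images.shape[1:] != masks.shape[1:]:
        raise ValueError("images and masks must align")

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(n * cfg.validation_fraction)) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation carve-out leaves no training data")

    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    curves = LearningCurves()
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        losses, accs = [], []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            x = images[idx][:, None]
            y = _onehot(masks[idx])
            logits = model.forward(x, train=True)
            loss, dlogits = nn.softmax_xent_grad(logits, y)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
            model.backward(dlogits)
            opt.step(model.grads)
            pred = logits[:, 1] > logits[:, 0]
            losses.append(loss)
            accs.append(float(np.mean(pred == masks[idx])))
        curves.train_loss.append(float(np.mean(losses)))
        curves.train_acc.append(float(np.mean(accs)))
        vl, va = _evaluate_loss(model, images, masks, val_idx, cfg.batch_size)
        curves.val_loss.append(vl)
        curves.val_acc.append(va)
    return model, curves


def _evaluate_loss(model, images, masks, idx, batch):
    if len(idx) == 0:
        return float("nan"), float("nan")
    losses, accs = [], []
    for i in range(0, len(idx), batch):
        sub = idx[i : i + batch]
        x = images[sub][:, None]
        logits = model.forward(x, train=False)
        loss, _ = nn.softmax_xent_grad(logits, _onehot(masks[sub]))
        pred = logits[:, 1] > logits[:, 0]
        losses.append(loss * len(sub))
        accs.append(float(np.sum(pred == masks[sub])) / masks[sub][0].size)
    return float(np.sum(losses) / len(idx)), float(np.sum(accs) / len(idx))


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Segment one (H, W) image: argmax over the 2-class softmax.

    Exact probability ties go to background, so a maximally uncertain
    network predicts no nerve rather than a full-frame one.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.shape != tuple(model.config.input_size):
        raise ValueError(
            f"image shape {image.shape} != configured {model.config.input_size}"
        )
    p = model.predict_proba(image[None])[0]
    return p[1] > p[0]


class UNetSegmenter:
    """Model object: architecture + training recipe, fitted with :meth:`fit`.

    Parameters
    ----------
    config : UNetConfig
        Network architecture (depth, filters, input size).
    train_config : TrainConfig, optional
        Optimization recipe; defaults to the full 100-epoch recipe.
    """

    def __init__(self, config: UNetConfig, train_config: TrainConfig | None = None):
        self.config = config
        self.train_config = train_config or TrainConfig()

    def fit(self, images: np.ndarray, masks: np.ndarray,
            seed: int | None = None) -> "SegmentationFit":
        cfg = self.train_config if seed is None else replace(self.train_config, seed=seed)
        model = build_model(self.config, seed=cfg.seed)
        model, curves = train(model, images, masks, cfg)
        return SegmentationFit(model, curves, cfg)


class SegmentationFit:
    """Results object: fitted weights, learning curves, prediction/evaluation."""

    def __init__(self, model: UNet, curves: LearningCurves, train_config: TrainConfig):
        self.model = model
        self.curves = curves
        self.train_config = train_config

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Boolean predicted masks for a stack of (N, H, W) images."""
        p = self.model.predict_proba(images)
        return p[:, 1] > p[:, 0]

    def evaluate_dice(self, images: np.ndarray, masks: np.ndarray) -> np.ndarray:
        """Per-image Dice of predictions against ground truth."""
        preds = self.predict(images)
        return np.array([dice(confusion(p, t)) for p, t in zip(preds, masks)])

    def summary(self) -> str:
        c = self.curves
        buf = io.StringIO()
        cfg = self.model.config
        buf.write("U-Net segmentation fit\n")
        buf.write("======================\n")
        buf.write(f"depth {cfg.depth}, base filters {cfg.base_filters}, "
                  f"input {cfg.input_size[0]}x{cfg.input_size[1]}, "
                  f"parameters {self.model.n_params}\n")
        buf.write(f"epochs {len(c.train_loss)}, lr {self.train_config.learning_rate}, "
                  f"batch {self.train_config.batch_size}\n")
        if c.train_loss:
            buf.write(f"final train loss {c.train_loss[-1]:.4f}, "
                      f"train acc {c.train_acc[-1]:.4f}\n")
            if np.isfinite(c.val_loss[-1]):
                buf.write(f"final val loss   {c.val_loss[-1]:.4f}, "
                          f"val acc   {c.val_acc[-1]:.4f}\n")
        return buf.getvalue()
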