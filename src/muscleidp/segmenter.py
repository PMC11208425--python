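"""Residual U-Net family for 2D multiclass muscle segmentation.

The architecture family has 4 encoding blocks and 3 decoding blocks. An
encoding block opens with a (possibly strided) convolution -> batch norm ->
PReLU; with ``residual_units = n >= 1`` it then stacks n residual units
(conv -> norm -> activation -> conv -> norm, plus an identity connection from
the unit input to the final addition, then activation); with ``n = 0`` (the
simple U-Net) the unit is the same stack without the identity connection.
Decoding blocks upsample, concatenate the encoder skip, then apply
norm -> activation -> convolution -> addition (a 1x1-projected shortcut).
The head is a 1x1 convolution to 13 channels (12 muscle classes +
background) followed by a channel softmax.

Training uses Adam with a staged learning-rate schedule, a compound loss of
mean soft-Dice over the 13 channels plus cross-entropy (either alone is
available by config; the cross-entropy term prevents channels from dying
under pure Dice), and random
zoom/rotation augmentation applied identically to image (linear) and labels
(nearest). Splits are study-level: slices from one study never straddle
train/validation, and five-repeat five-fold cross-validation partitions
studies, not slices.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from ._nn import Adam, BatchNorm2d, Conv2d, PReLU, Upsample2x, softmax_channels
from .classes import N_CHANNELS

__all__ = [
    "SegmenterConfig",
    "AugmentationSpec",
    "TrainConfig",
    "Study",
    "ResUNet",
    "build_segmenter",
    "augment_pair",
    "train",
    "crossvalidate",
    "mean_foreground_dice",
    "FINALIZE_SCHEDULE",
]

#: Staged fine-tuning schedule applied to the selected model after the
#: 100-epoch selection stage: 100 epochs at 1e-5 then 100 at 1e-6.
FINALIZE_SCHEDULE = ((100, 1e-5), (100, 1e-6))


@dataclass
class SegmenterConfig:
    """Architecture description. ``residual_units = 0`` is the simple U-Net."""

    residual_units: int = 2
    n_encode_blocks: int = 4
    n_decode_blocks: int = 3
    in_channels: int = 1
    out_channels: int = N_CHANNELS
    base_channel_width: int = 8
    activation: str = "prelu"
    norm: str = "batch"

    def __post_init__(self) -> None:
        if self.residual_units not in (0, 1, 2, 3, 4):
            raise ValueError("residual_units must be in {0, 1, 2, 3, 4}")
        if (self.n_encode_blocks, self.n_decode_blocks) != (4, 3):
            raise ValueError("the architecture family is fixed at 4 encode / 3 decode blocks")
        if self.out_channels != N_CHANNELS:
            raise ValueError(f"out_channels must be {N_CHANNELS} (12 muscle classes + background)")

    @property
    def downsampling_factor(self) -> int:
        return 2 ** (self.n_encode_blocks - 1)


@dataclass
class AugmentationSpec:
    """Random zoom/rotation augmentation parameters."""

    zoom_range: tuple[float, float] = (-0.2, 0.2)
    rotation_range_deg: tuple[float, float] = (-20.0, 20.0)
    apply_probability: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.apply_probability <= 1.0):
            raise ValueError("apply_probability must be in [0, 1]")


@dataclass
class TrainConfig:
    """Optimization protocol: Adam with a staged learning-rate schedule."""

    lr_schedule: tuple = ((100, 1e-4),)
    validation_steps_per_epoch: int = 128
    batch_size: int = 8
    augmentation: AugmentationSpec | None = field(default_factory=AugmentationSpec)
    loss: str = "dice_ce"  # "dice_ce" | "dice" | "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        for epochs, rate in self.lr_schedule:
            if epochs <= 0 or rate <= 0:
                raise ValueError("lr_schedule entries must have epochs > 0 and rate > 0")


@dataclass
class Study:
    """All axial slices of one study; the unit of train/val/test splitting."""

    study_id: str
    images: np.ndarray  # (n_slices, H, W), windowed intensities in [0, 1]
    labels: np.ndarray  # (n_slices, H, W), integer classes 0..12


class _EncodeBlock:
    def __init__(self, cin, cout, stride, n_res, rng):
        self.entry = [Conv2d(cin, cout, 3, stride, rng), BatchNorm2d(cout), PReLU(cout)]
        self.n_res = n_res
        self.units = []
        for _ in range(max(n_res, 1)):
            self.units.append(
                [
                    Conv2d(cout, cout, 3, 1, rng),
                    BatchNorm2d(cout),
                    PReLU(cout),
                    Conv2d(cout, cout, 3, 1, rng),
                    BatchNorm2d(cout),
                    PReLU(cout),
                ]
            )

    def params(self):
        ps = [p for l in self.entry for p in l.params()]
        for u in self.units:
            ps += [p for l in u for p in l.params()]
        return ps

    def forward(self, x, training):
        for l in self.entry:
            x = l.forward(x, training)
        for u in self.units:
            conv_a, bn_a, act_a, conv_b, bn_b, act_out = u
            h = act_a.forward(bn_a.forward(conv_a.forward(x, training), training), training)
            h = bn_b.forward(conv_b.forward(h, training), training)
            x = act_out.forward(h + x if self.n_res >= 1 else h, training)
        return x

    def backward(self, g):
        for u in reversed(self.units):
            conv_a, bn_a, act_a, conv_b, bn_b, act_out = u
            g = act_out.backward(g)
            gh = bn_b.backward(g)
            gh = conv_b.backward(gh)
            gh = act_a.backward(gh)
            gh = bn_a.backward(gh)
            gh = conv_a.backward(gh)
            g = gh + g if self.n_res >= 1 else gh
        for l in reversed(self.entry):
            g = l.backward(g)
        return g


class _DecodeBlock:
    """Upsample, concatenate the skip, norm -> activation -> conv -> addition."""

    def __init__(self, c_up, c_skip, cout, rng):
        cat = c_up + c_skip
        self.up = Upsample2x()
        self.bn = BatchNorm2d(cat)
        self.act = PReLU(cat)
        self.conv = Conv2d(cat, cout, 3, 1, rng)
        self.short = Conv2d(cat, cout, 1, 1, rng)
        self.c_skip = c_skip

    def params(self):
        return (
            self.bn.params() + self.act.params() + self.conv.params() + self.short.params()
        )

    def forward(self, x_up, skip, training):
        u = self.up.forward(x_up, training)
        cat = np.concatenate([skip, u], axis=3)
        y = self.conv.forward(self.act.forward(self.bn.forward(cat, training), training), training)
        return y + self.short.forward(cat, training)

    def backward(self, g):
        gcat = self.short.backward(g)
        gcat = gcat + self.bn.backward(self.act.backward(self.conv.backward(g)))
        gskip = gcat[..., : self.c_skip]
        gup = self.up.backward(gcat[..., self.c_skip :])
        return gup, gskip


class ResUNet:
    """The segmenter: windowed 2D slices in, 13-channel probability maps out."""

    def __init__(self, cfg: SegmenterConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        w = cfg.base_channel_width
        n = cfg.residual_units
        self.enc = [
            _EncodeBlock(cfg.in_channels, w, 1, n, rng),
            _EncodeBlock(w, 2 * w, 2, n, rng),
            _EncodeBlock(2 * w, 4 * w, 2, n, rng),
            _EncodeBlock(4 * w, 8 * w, 2, n, rng),
        ]
        self.dec = [
            _DecodeBlock(8 * w, 4 * w, 4 * w, rng),
            _DecodeBlock(4 * w, 2 * w, 2 * w, rng),
            _DecodeBlock(2 * w, w, w, rng),
        ]
        self.head = Conv2d(w, cfg.out_channels, 1, 1, rng)
        self._skips = None

    def params(self):
        ps = []
        for b in self.enc + self.dec:
            ps += b.params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _check_shape(self, h, w):
        f = self.cfg.downsampling_factor
        if h % f or w % f:
            raise ValueError(
                f"slice height and width must be multiples of {f} "
                f"(the downsampling factor), got {h}x{w}"
            )

    def forward_logits(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Logits for a channels-last batch (N, H, W, 1) -> (N, H, W, 13)."""
        self._check_shape(x.shape[1], x.shape[2])
        skips = []
        h = x.astype(np.float32)
        for i, b in enumerate(self.enc):
            h = b.forward(h, training)
            if i < 3:
                skips.append(h)
        self._skips = skips
        for d, s in zip(self.dec, reversed(skips)):
            h = d.forward(h, s, training)
        return self.head.forward(h, training)

    def backward(self, gz: np.ndarray) -> None:
        g = self.head.backward(gz)
        gskips = [None, None, None]
        for j in (2, 1, 0):  # reverse of forward order; dec[j] consumed skips[2-j]
            g, gs = self.dec[j].backward(g)
            gskips[2 - j] = gs
        g = self.enc[3].backward(g)
        for i in (2, 1, 0):
            g = g + gskips[i]
            g = self.enc[i].backward(g)

    def predict_proba(self, slices: np.ndarray) -> np.ndarray:
        """Probability maps for one (H, W) slice or a (N, H, W) batch.

        Per-pixel channel sums are 1 (softmax head); evaluation mode
        (running batch-norm statistics) is used.
        """
        arr = np.asarray(slices, dtype=np.float32)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        z = self.forward_logits(arr[..., None], training=False)
        p = softmax_channels(z)
        p = np.moveaxis(p, -1, 1)  # public maps are channel-first
        return p[0] if single else p

    def predict_labels(self, slices: np.ndarray) -> np.ndarray:
        from .postprocess import argmax_labels

        return argmax_labels(self.predict_proba(slices))

    # -- checkpointing ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.value for p in self.params()]
        for b in self.enc:
            for layer in b.entry + [l for u in b.units for l in u]:
                if isinstance(layer, BatchNorm2d):
                    arrs += [layer.running_mean, layer.running_var]
        for d in self.dec:
            arrs += [d.bn.running_mean, d.bn.running_var]
        return arrs

    def save(self, path: str | os.PathLike) -> None:
        path = os.fspath(path)
        np.savez(path, *self.state_arrays())
        side = {
            "residual_units": self.cfg.residual_units,
            "base_channel_width": self.cfg.base_channel_width,
            "out_channels": self.cfg.out_channels,
            "seed": self.seed,
        }
        with open(path + ".json" if not path.endswith(".npz") else path[:-4] + ".json", "w") as f:
            json.dump(side, f, indent=1)

    def load(self, path: str | os.PathLike) -> None:
        with np.load(os.fspath(path)) as z:
            arrs = [z[k] for k in z.files]
        targets = self.state_arrays()
        if len(arrs) != len(targets):
            raise ValueError("checkpoint does not match this architecture")
        for t, a in zip(targets, arrs):
            t[...] = a


def build_segmenter(cfg: SegmenterConfig, seed: int = 0) -> ResUNet:
    """Construct a seeded, untrained segmenter from its configuration."""
    return ResUNet(cfg, seed=seed)


def augment_pair(
    image: np.ndarray,
    labels: np.ndarray,
    spec: AugmentationSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random zoom + rotation applied identically to image and labels.

    With probability ``apply_probability`` a zoom factor (1 + u, u uniform in
    ``zoom_range``) and a rotation angle (uniform in ``rotation_range_deg``)
    are drawn and applied about the slice centre — linear interpolation for
    the image, nearest-neighbour for the labels, so the label palette is
    preserved. Otherwise both are returned unchanged.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError(f"image shape {image.shape} != labels shape {labels.shape}")
    if rng.random() >= spec.apply_probability:
        return image.copy(), labels.copy()
    zoom = 1.0 + rng.uniform(*spec.zoom_range)
    angle = np.deg2rad(rng.uniform(*spec.rotation_range_deg))
    c, s = np.cos(angle), np.sin(angle)
    # output -> input map: rotate by -angle and divide by the zoom factor
    mat = np.array([[c, -s], [s, c]]) / zoom
    center = (np.asarray(image.shape) - 1) / 2.0
    offset = center - mat @ center
    img2 = ndimage.affine_transform(
        image.astype(np.float32), mat, offset=offset, order=1, mode="constant", cval=0.0
    )
    lab2 = ndimage.affine_transform(
        labels, mat, offset=offset, order=0, mode="constant", cval=0
    )
    return img2, lab2.astype(labels.dtype)


def _one_hot(labels: np.ndarray, n_channels: int) -> np.ndarray:
    """Channels-last one-hot encoding: (N, H, W) -> (N, H, W, C)."""
    n, h, w = labels.shape
    oh = np.zeros((n, h, w, n_channels), dtype=np.float32)
    for c in range(n_channels):
        oh[..., c] = labels == c
    return oh


def soft_dice_loss(z: np.ndarray, onehot: np.ndarray, eps: float = 1e-6):
    """Mean soft-Dice loss over channels, with the gradient w.r.t. logits.

    ``z`` and ``onehot`` are channels-last (N, H, W, C); the Dice of each
    channel is computed over the whole batch and the loss is one minus the
    channel mean.
    """
    p = softmax_channels(z)
    axes = (0, 1, 2)
    inter = (p * onehot).sum(axis=axes)
    denom = p.sum(axis=axes) + onehot.sum(axis=axes)
    dice = (2.0 * inter + eps) / (denom + eps)
    loss = 1.0 - dice.mean()
    c = z.shape[-1]
    # d(loss)/dp then chain through the softmax
    dldp = -(2.0 * onehot * (denom + eps) - (2.0 * inter + eps)) / (
        c * (denom + eps) ** 2
    )
    gz = p * (dldp - (dldp * p).sum(axis=-1, keepdims=True))
    return float(loss), gz.astype(np.float32)


def cross_entropy_loss(z: np.ndarray, onehot: np.ndarray):
    p = softmax_channels(z)
    n = z.shape[0] * z.shape[1] * z.shape[2]
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / n)
    gz = ((p - onehot) / n).astype(np.float32)
    return loss, gz


def dice_ce_loss(z: np.ndarray, onehot: np.ndarray):
    """Soft-Dice plus cross-entropy, equally weighted.

    Pure soft-Dice can let a channel die: once its predicted mass collapses,
    its gradient is near zero and argmax never recovers the class. The
    cross-entropy term keeps a per-pixel gradient on every channel, while the
    Dice term keeps the objective aligned with the selection metric.
    """
    ld, gd = soft_dice_loss(z, onehot)
    lc, gc = cross_entropy_loss(z, onehot)
    return ld + lc, gd + gc


def mean_foreground_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean Dice over muscle classes 1..12, both-empty classes excluded."""
    from .evalstats import dice

    vals = []
    for c in range(1, N_CHANNELS):
        d = dice(pred == c, truth == c)
        if d is not None:
            vals.append(d)
    return float(np.mean(vals)) if vals else float("nan")


def _stack_slices(studies: Sequence[Study]):
    imgs = np.concatenate([s.images for s in studies], axis=0).astype(np.float32)
    labs = np.concatenate([s.labels for s in studies], axis=0).astype(np.int16)
    return imgs, labs


def train(
    model: ResUNet,
    train_set: Sequence[Study],
    val_set: Sequence[Study],
    cfg: TrainConfig,
) -> tuple[ResUNet, dict]:
    """Train in place through the learning-rate schedule; return (model, history).

    ``history['val_dice']`` holds the per-epoch mean validation Dice
    (foreground classes, both-empty excluded); the model returned is the
    end-of-schedule model. Train and validation sets must be study-level
    disjoint — an overlap is a hard data-leakage error.
    """
    train_ids = {s.study_id for s in train_set}
    val_ids = {s.study_id for s in val_set}
    leak = train_ids & val_ids
    if leak:
        raise ValueError(f"data leakage: studies {sorted(leak)} appear in both train and val")

    rng = np.random.default_rng(cfg.seed)
    x_train, y_train = _stack_slices(train_set)
    x_val, y_val = _stack_slices(val_set)
    loss_fn = {
        "dice": soft_dice_loss,
        "cross_entropy": cross_entropy_loss,
        "dice_ce": dice_ce_loss,
    }[cfg.loss]

    opt = Adam(model.params(), lr=cfg.lr_schedule[0][1])
    history = {"train_loss": [], "val_dice": [], "lr": []}
    for epochs, lr in cfg.lr_schedule:
        opt.lr = lr
        for _epoch in range(epochs):
            order = rng.permutation(len(x_train))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = np.empty((len(idx),) + x_train.shape[1:], dtype=np.float32)
                yb = np.empty((len(idx),) + y_train.shape[1:], dtype=np.int16)
                for j, i in enumerate(idx):
                    if cfg.augmentation is not None:
                        xb[j], yb[j] = augment_pair(
                            x_train[i], y_train[i], cfg.augmentation, rng
                        )
                    else:
                        xb[j], yb[j] = x_train[i], y_train[i]
                z = model.forward_logits(xb[..., None], training=True)
                loss, gz = loss_fn(z, _one_hot(yb, model.cfg.out_channels))
                opt.zero_grad()
                model.backward(gz)
                opt.step()
                losses.append(loss)
            # validation: up to validation_steps_per_epoch batches
            n_val = min(len(x_val), cfg.validation_steps_per_epoch * cfg.batch_size)
            dices = []
            for start in range(0, n_val, cfg.batch_size):
                xb = x_val[start : start + cfg.batch_size]
                yb = y_val[start : start + cfg.batch_size]
                pred = model.predict_labels(xb)
                for p, t in zip(pred, yb):
                    d = mean_foreground_dice(p, t)
                    if np.isfinite(d):
                        dices.append(d)
            history["train_loss"].append(float(np.mean(losses)))
            history["val_dice"].append(float(np.mean(dices)) if dices else float("nan"))
            history["lr"].append(lr)
    return model, history


def crossvalidate(
    dataset: Sequence[Study],
    cfg: TrainConfig | None = None,
    seg_cfg: SegmenterConfig | None = None,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    train_fn: Callable[[Sequence[Study], Sequence[Study], int], Callable] | None = None,
) -> dict:
    """Repeated k-fold cross-validation with study-level folds.

    Per repeat, studies are partitioned into k folds; each fold serves once as
    validation. The per-fold score is the mean foreground Dice across the
    fold's slices; the aggregate per repeat is the mean and SD across the k
    fold-average values. ``train_fn(train_studies, val_studies, seed)`` must
    return a slice-batch -> label-map predictor; the default trains a fresh
    segmenter per fold.
    """
    n = len(dataset)
    if k > n:
        raise ValueError(f"k={k} folds exceed the {n} available studies")
    cfg = cfg or TrainConfig()
    seg_cfg = seg_cfg or SegmenterConfig()

    if train_fn is None:

        def train_fn(tr, va, fold_seed):
            import dataclasses as _dc

            model = build_segmenter(seg_cfg, seed=fold_seed)
            fold_cfg = _dc.replace(cfg, seed=fold_seed)
            train(model, tr, va, fold_cfg)
            return model.predict_labels

    rng = np.random.default_rng(seed)
    fold_dice = np.zeros((repeats, k))
    assignments = []
    for r in range(repeats):
        perm = rng.permutation(n)
        folds = [sorted(perm[i::k].tolist()) for i in range(k)]
        assignments.append(folds)
        for fi, val_idx in enumerate(folds):
            val_studies = [dataset[i] for i in val_idx]
            tr_studies = [dataset[i] for i in range(n) if i not in val_idx]
            predictor = train_fn(tr_studies, val_studies, int(rng.integers(0, 2**31 - 1)))
            scores = []
            for s in val_studies:
                pred = predictor(s.images)
                for p, t in zip(pred, s.labels):
                    d = mean_foreground_dice(p, t)
                    if np.isfinite(d):
                        scores.append(d)
            fold_dice[r, fi] = float(np.mean(scores))
    per_repeat_mean = fold_dice.mean(axis=1)
    per_repeat_sd = fold_dice.std(axis=1, ddof=1)
    return {
        "fold_dice": fold_dice,
        "folds": assignments,
        "repeat_mean": per_repeat_mean,
        "repeat_sd": per_repeat_sd,
        "mean": float(per_repeat_mean.mean()),
        "sd": float(fold_dice.std(ddof=1)),
    }
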