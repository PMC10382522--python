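"""U-Net surrogate for the rule-based focus-score pipeline.

The sliding-window pipeline is accurate but expensive; a compact
encoder-decoder network can learn the mapping from a raw widefield
slice straight to its in-focus mask, using the rule-based Otsu masks as
weak labels.  The architecture is a 7-layer symmetric U-Net — a
3-stage convolutional encoder (256, 128, 64 channels), a 32-channel
bottleneck and a mirrored 3-stage decoder (64, 128, 256) with skip
concatenations and a sigmoid head.  ``width_multiplier`` scales every
stage down for CPU-sized experiments (0.0625 gives 16-8-4-2-4-8-16).

The implementation is self-contained NumPy: convolutions are im2col
matrix products in float32, gradients are derived per layer, and
optimization is Adam.  Training minimizes the sum of focal, Dice and
binary cross-entropy losses and early-stops on validation loss.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .focusmap import FocalStack
from .masking import InFocusMask

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "UNet",
    "build_model",
    "total_loss",
    "loss_components",
    "train",
    "fine_tune",
    "predict_stack",
]

_EPS = 1e-6


@dataclass
class UNetSpec:
    """Architecture hyperparameters.

    With ``width_multiplier=1`` the stage widths are exactly
    (256, 128, 64, 32, 64, 128, 256); smaller multipliers shrink every
    stage proportionally (minimum 1 channel).
    """

    encoder_channels: tuple = (256, 128, 64)
    bottleneck_channels: int = 32
    decoder_channels: tuple = (64, 128, 256)
    kernel_size: int = 3
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must be in (0, 1]")
        if self.kernel_size != 3:
            raise ValueError("only 3x3 convolutions are supported")
        if len(self.encoder_channels) != 3 or len(self.decoder_channels) != 3:
            raise ValueError("the architecture has 3 encoder and 3 decoder stages")

    def stage_widths(self) -> tuple:
        """Channel widths per stage after applying the width multiplier."""
        m = self.width_multiplier
        chans = (*self.encoder_channels, self.bottleneck_channels, *self.decoder_channels)
        return tuple(max(1, round(c * m)) for c in chans)

    def parameter_count(self) -> int:
        """Total number of trainable parameters (pure function of the spec)."""
        e1, e2, e3, b, d1, d2, d3 = self.stage_widths()
        total = 0
        for cin, cout in (
            (1, e1), (e1, e2), (e2, e3), (e3, b),
            (b + e3, d1), (d1 + e2, d2), (d2 + e1, d3),
        ):
            total += 9 * cin * cout + cout
        total += d3 * 1 + 1  # 1x1 sigmoid head
        return total


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Pre-training uses batches of 16 and fine-tuning batches of 1, with
    Adam at a 0.001 starting learning rate, at most 1000 epochs, and
    patience-based early stopping on the validation loss.  The three
    loss components (focal, Dice, binary cross-entropy) are summed with
    unit weights by default.  Augmentations are label-preserving flips
    and 90-degree rotations applied jointly to image and mask.
    """

    learning_rate: float = 1e-3
    batch_size_pretrain: int = 16
    batch_size_finetune: int = 1
    max_epochs: int = 1000
    patience: int = 50
    loss_weights: tuple = (1.0, 1.0, 1.0)
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    augment: bool = True
    seed: int = 0
    prediction_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size_pretrain < 1 or self.batch_size_finetune < 1:
            raise ValueError("batch sizes must be >= 1")
        if any(w < 0 for w in self.loss_weights) or sum(self.loss_weights) == 0:
            raise ValueError("loss weights must be >= 0 and not all zero")


# ---------------------------------------------------------------------------
# layers (forward + explicit backward), float32 throughout


def _conv3(x: np.ndarray, w: np.ndarray, b: np.ndarray, cache: dict | None = None) -> np.ndarray:
    """Same-padded 3x3 convolution via im2col matmul.  x: (B, C, H, W)."""
    bsz, c, h, wd = x.shape
    cout = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B, C, H, W, 3, 3)
    cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(bsz, h * wd, c * 9)
    out = cols @ w.reshape(cout, c * 9).T + b
    if cache is not None:
        cache["cols"] = cols
        cache["xshape"] = x.shape
    return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(bsz, cout, h, wd)


def _conv3_backward(dout: np.ndarray, w: np.ndarray, cache: dict) -> tuple:
    bsz, cout, h, wd = dout.shape
    c = cache["xshape"][1]
    dmat = np.ascontiguousarray(dout.reshape(bsz, cout, h * wd).transpose(0, 2, 1))  # (B, HW, Cout)
    cols = cache["cols"]
    dw = np.tensordot(dmat, cols, axes=([0, 1], [0, 1])).astype(np.float32)  # (Cout, C*9)
    db = dmat.sum(axis=(0, 1)).astype(np.float32)
    dcols = dmat @ w.reshape(cout, c * 9)  # (B, HW, C*9)
    dcols = dcols.reshape(bsz, h, wd, c, 3, 3)
    dxp = np.zeros((bsz, c, h + 2, wd + 2), dtype=np.float32)
    for dy in range(3):
        for dx in range(3):
            dxp[:, :, dy : dy + h, dx : dx + wd] += dcols[:, :, :, :, dy, dx].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dw.reshape(w.shape), db


def _conv1(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("oi,bihw->bohw", w, x) + b[None, :, None, None]


def _conv1_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray) -> tuple:
    dw = np.einsum("bohw,bihw->oi", dout, x).astype(np.float32)
    db = dout.sum(axis=(0, 2, 3)).astype(np.float32)
    dx = np.einsum("oi,bohw->bihw", w, dout).astype(np.float32)
    return dx, dw, db


def _pool2(x: np.ndarray, cache: dict | None = None) -> np.ndarray:
    b, c, h, w = x.shape
    v = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    if cache is not None:
        cache["idx"] = idx
        cache["xshape"] = x.shape
    return out


def _pool2_backward(dout: np.ndarray, cache: dict) -> np.ndarray:
    b, c, h, w = cache["xshape"]
    dv = np.zeros((b, c, h // 2, w // 2, 4), dtype=np.float32)
    np.put_along_axis(dv, cache["idx"][..., None], dout[..., None], axis=-1)
    return dv.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_backward(dout: np.ndarray) -> np.ndarray:
    b, c, h, w = dout.shape
    return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# model


class UNet:
    """Symmetric 3-stage encoder/decoder U-Net with skip concatenations.

    Input images are single-channel (B, 1, H, W) with H and W divisible
    by 8 (three pooling stages); output is a per-pixel in-focus
    probability map of the same H x W.
    """

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        e1, e2, e3, b, d1, d2, d3 = spec.stage_widths()
        self._stage_io = [
            ("enc1", 1, e1), ("enc2", e1, e2), ("enc3", e2, e3), ("bottleneck", e3, b),
            ("dec1", b + e3, d1), ("dec2", d1 + e2, d2), ("dec3", d2 + e1, d3),
        ]
        rng = np.random.default_rng(seed)
        self.params: dict = {}
        for name, cin, cout in self._stage_io:
            std = np.sqrt(2.0 / (9 * cin))
            self.params[f"{name}.w"] = (rng.standard_normal((cout, cin, 3, 3)) * std).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)
        std = np.sqrt(2.0 / d3)
        self.params["head.w"] = (rng.standard_normal((1, d3)) * std).astype(np.float32)
        self.params["head.b"] = np.zeros(1, dtype=np.float32)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def state_copy(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected (B, 1, H, W) input")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("input H and W must be divisible by 8; pad first (see predict_stack)")
        return x

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits of shape (B, H, W); optionally also the layer cache."""
        x = self._check_input(x)
        p = self.params
        cc: dict = {}

        def conv_relu(name, inp):
            c: dict = {}
            z = _conv3(inp, p[f"{name}.w"], p[f"{name}.b"], c if want_cache else None)
            a = np.maximum(z, 0.0)
            if want_cache:
                c["relu_mask"] = z > 0
                cc[name] = c
            return a

        a1 = conv_relu("enc1", x)
        c1: dict = {}
        p1 = _pool2(a1, c1 if want_cache else None)
        a2 = conv_relu("enc2", p1)
        c2: dict = {}
        p2 = _pool2(a2, c2 if want_cache else None)
        a3 = conv_relu("enc3", p2)
        c3: dict = {}
        p3 = _pool2(a3, c3 if want_cache else None)
        bn = conv_relu("bottleneck", p3)

        u1 = np.concatenate([_up2(bn), a3], axis=1)
        d1 = conv_relu("dec1", u1)
        u2 = np.concatenate([_up2(d1), a2], axis=1)
        d2 = conv_relu("dec2", u2)
        u3 = np.concatenate([_up2(d2), a1], axis=1)
        d3 = conv_relu("dec3", u3)
        logits = _conv1(d3, p["head.w"], p["head.b"])[:, 0]
        if not want_cache:
            return logits
        cc["pool1"], cc["pool2"], cc["pool3"] = c1, c2, c3
        cc["d3"] = d3
        cc["nchan"] = {
            "bn": bn.shape[1], "a3": a3.shape[1], "d1": d1.shape[1],
            "a2": a2.shape[1], "d2": d2.shape[1], "a1": a1.shape[1],
        }
        return logits, cc

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        """Parameter gradients from d(loss)/d(logits)."""
        p = self.params
        grads: dict = {}

        def conv_back(name, dout):
            c = cache[name]
            dout = dout * c["relu_mask"]
            dx, dw, db = _conv3_backward(dout.astype(np.float32), p[f"{name}.w"], c)
            grads[f"{name}.w"] = dw
            grads[f"{name}.b"] = db
            return dx

        dd3 = _conv1_backward(dlogits[:, None].astype(np.float32), cache["d3"], p["head.w"])
        dx, grads["head.w"], grads["head.b"] = dd3
        du3 = conv_back("dec3", dx)
        n = cache["nchan"]
        dd2 = _up2_backward(du3[:, : n["d2"]])
        da1 = du3[:, n["d2"] :]
        du2 = conv_back("dec2", dd2)
        dd1 = _up2_backward(du2[:, : n["d1"]])
        da2 = du2[:, n["d1"] :]
        du1 = conv_back("dec1", dd1)
        dbn = _up2_backward(du1[:, : n["bn"]])
        da3 = du1[:, n["bn"] :]
        dp3 = conv_back("bottleneck", dbn)
        da3 = da3 + _pool2_backward(dp3, cache["pool3"])
        dp2 = conv_back("enc3", da3)
        da2 = da2 + _pool2_backward(dp2, cache["pool2"])
        dp1 = conv_back("enc2", da2)
        da1 = da1 + _pool2_backward(dp1, cache["pool1"])
        conv_back("enc1", da1)
        return grads

    def predict_proba(self, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
        """Per-pixel in-focus probabilities for a batch of slices."""
        x = self._check_input(np.asarray(images, dtype=np.float32))
        out = np.empty((x.shape[0], x.shape[2], x.shape[3]), dtype=np.float32)
        for i in range(0, x.shape[0], batch_size):
            out[i : i + batch_size] = _sigmoid(self.forward(x[i : i + batch_size]))
        return out

    def save(self, path) -> None:
        np.savez(path, **self.params, __wm__=self.spec.width_multiplier, __seed__=self.seed)

    @classmethod
    def load(cls, path) -> "UNet":
        data = np.load(path)
        spec = UNetSpec(width_multiplier=float(data["__wm__"]))
        model = cls(spec, seed=int(data["__seed__"]))
        for k in model.params:
            model.params[k] = data[k]
        return model


def build_model(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Instantiate a U-Net with seeded (deterministic) initialization."""
    return UNet(spec or UNetSpec(), seed=seed)


# ---------------------------------------------------------------------------
# losses


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1.0 - _EPS)


def loss_components(pred: np.ndarray, target: np.ndarray, gamma: float = 2.0, alpha: float = 0.25) -> dict:
    """Focal, Dice and BCE losses of a probability map against a binary mask."""
    p = _clamp(np.asarray(pred, dtype=np.float64))
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    bce = float(np.mean(-(t * np.log(p) + (1 - t) * np.log(1 - p))))
    focal = float(
        np.mean(
            -alpha * t * (1 - p) ** gamma * np.log(p)
            - (1 - alpha) * (1 - t) * p ** gamma * np.log(1 - p)
        )
    )
    dice = 1.0 - (2.0 * float((p * t).sum()) + _EPS) / (float(p.sum()) + float(t.sum()) + _EPS)
    return {"focal": focal, "dice": dice, "bce": bce}


def total_loss(
    pred: np.ndarray,
    target: np.ndarray,
    weights: tuple = (1.0, 1.0, 1.0),
    gamma: float = 2.0,
    alpha: float = 0.25,
) -> float:
    """Weighted sum of focal, Dice and binary cross-entropy losses."""
    c = loss_components(pred, target, gamma=gamma, alpha=alpha)
    wf, wd, wb = weights
    return wf * c["focal"] + wd * c["dice"] + wb * c["bce"]


def _loss_and_dlogits(p: np.ndarray, t: np.ndarray, cfg: TrainConfig) -> tuple:
    """Total loss and its gradient w.r.t. the logits (analytic)."""
    wf, wd, wb = cfg.loss_weights
    gamma, alpha = cfg.focal_gamma, cfg.focal_alpha
    pc = _clamp(p.astype(np.float64))
    t = t.astype(np.float64)
    n = pc.size
    loss = total_loss(pc, t, cfg.loss_weights, gamma, alpha)

    dp = np.zeros_like(pc)
    if wb:
        dp += wb * (pc - t) / (pc * (1 - pc)) / n
    if wf:
        pos = alpha * (gamma * (1 - pc) ** (gamma - 1) * np.log(pc) - (1 - pc) ** gamma / pc)
        neg = -(1 - alpha) * (gamma * pc ** (gamma - 1) * np.log(1 - pc) - pc ** gamma / (1 - pc))
        dp += wf * (t * pos + (1 - t) * neg) / n
    if wd:
        denom = pc.sum() + t.sum() + _EPS
        num = 2.0 * (pc * t).sum() + _EPS
        dp += wd * (num / denom**2 - 2.0 * t / denom)
    dz = dp * pc * (1 - pc)
    return loss, dz.astype(np.float32)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


def _augment_batch(x: np.ndarray, t: np.ndarray, rng: np.random.Generator) -> tuple:
    """Random dihedral transform (flips + 90-degree rotations), per sample."""
    xo, to = x.copy(), t.copy()
    ks = rng.integers(0, 8, size=x.shape[0])
    for i, k in enumerate(ks):
        xi, ti = np.rot90(xo[i], k % 4, axes=(-2, -1)), np.rot90(to[i], k % 4, axes=(-2, -1))
        if k >= 4:
            xi, ti = xi[..., ::-1], ti[..., ::-1]
        xo[i], to[i] = xi, ti
    return xo, to


def _as_arrays(images, masks) -> tuple:
    x = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    t = np.stack([m.values if isinstance(m, InFocusMask) else np.asarray(m) for m in masks]).astype(np.float32)
    if x.shape != t.shape:
        raise ValueError("images and masks must pair up in shape")
    return x, t


def _mean_batch_iou(p: np.ndarray, t: np.ndarray, thr: float) -> float:
    vals = []
    for i in range(p.shape[0]):
        a, b = p[i] > thr, t[i] > 0.5
        union = np.count_nonzero(a | b)
        vals.append(1.0 if union == 0 else np.count_nonzero(a & b) / union)
    return float(np.mean(vals))


def train(
    model: UNet,
    images,
    weak_masks,
    val_images=None,
    val_masks=None,
    cfg: TrainConfig | None = None,
    batch_size: int | None = None,
) -> tuple:
    """Fit the surrogate on weakly labelled slices.

    Minimizes the total (focal + Dice + BCE) loss with Adam, recording
    per-epoch train/validation loss and IoU in the history; training
    stops at ``max_epochs`` or when the validation loss has not
    improved for ``patience`` epochs, and the best-validation weights
    are restored.  Without a validation set the early-stopping monitor
    falls back to the training loss.

    Returns ``(model, history)`` with history keys ``train_loss``,
    ``train_iou``, ``val_loss``, ``val_iou``.
    """
    cfg = cfg or TrainConfig()
    if len(images) == 0 or len(images) != len(weak_masks):
        raise ValueError("need equally many (non-zero) images and masks")
    x, t = _as_arrays(images, weak_masks)
    has_val = val_images is not None and len(val_images) > 0
    if has_val:
        xv, tv = _as_arrays(val_images, val_masks)
    bsz = batch_size or cfg.batch_size_pretrain
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.learning_rate)
    history = {"train_loss": [], "train_iou": [], "val_loss": [], "val_iou": []}
    best = (np.inf, model.state_copy())
    wait = 0
    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(x.shape[0])
        losses, ious = [], []
        for i in range(0, len(perm), bsz):
            xb, tb = x[perm[i : i + bsz]], t[perm[i : i + bsz]]
            if cfg.augment:
                xb, tb = _augment_batch(xb, tb, rng)
            logits, cache = model.forward(xb, want_cache=True)
            p = _sigmoid(logits)
            loss, dz = _loss_and_dlogits(p, tb, cfg)
            grads = model.backward(dz, cache)
            opt.step(model.params, grads)
            losses.append(loss)
            ious.append(_mean_batch_iou(p, tb, cfg.prediction_threshold))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_iou"].append(float(np.mean(ious)))
        if has_val:
            pv = model.predict_proba(xv)
            vloss = total_loss(pv, tv, cfg.loss_weights, cfg.focal_gamma, cfg.focal_alpha)
            history["val_loss"].append(float(vloss))
            history["val_iou"].append(_mean_batch_iou(pv, tv, cfg.prediction_threshold))
            monitor = vloss
        else:
            monitor = history["train_loss"][-1]
        if monitor < best[0]:
            best = (monitor, model.state_copy())
            wait = 0
        else:
            wait += 1
            if wait > cfg.patience:
                break
    if cfg.max_epochs > 0:
        model.load_state(best[1])
    return model, history


def fine_tune(model: UNet, images, manual_masks, val_images=None, val_masks=None, cfg: TrainConfig | None = None) -> tuple:
    """Continue training on (manually) annotated masks with batch size 1.

    Starts from the model's current (pre-trained) weights; with
    ``cfg.max_epochs == 0`` the model is returned unchanged.
    """
    cfg = cfg or TrainConfig()
    if cfg.max_epochs == 0:
        return model, {"train_loss": [], "train_iou": [], "val_loss": [], "val_iou": []}
    return train(model, images, manual_masks, val_images, val_masks, cfg, batch_size=cfg.batch_size_finetune)


def predict_stack(model: UNet, stack: FocalStack, threshold: float = 0.5) -> list:
    """Per-slice in-focus masks from the surrogate.

    Slices whose H or W is not divisible by 8 are reflect-padded up to
    the next multiple and the probability map is cropped back.  Slices
    are processed independently; thresholding at 0 marks everything
    in focus and at 1 nothing.
    """
    vox = np.asarray(stack.voxels, dtype=np.float32)
    z, h, w = vox.shape
    ph, pw = (-h) % 8, (-w) % 8
    if ph or pw:
        vox = np.pad(vox, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    proba = model.predict_proba(vox)[:, :h, :w]
    return [InFocusMask(proba[i] > threshold, slice_index=i, origin="surrogate") for i in range(z)]
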