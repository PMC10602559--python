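"""Ventricle segmentation: the ZVSegNet architecture, training, inference,
evaluation, and a classical threshold baseline.

ZVSegNet is a U-Net variant in which

* the plain double convolutions are replaced by 2-step recurrent residual
  convolutional units (RRCU): each unit projects its input with a 1x1
  convolution and stacks two recurrent 3x3 convolution layers whose weights
  are shared across the unrolled recurrence steps, with a residual add;
* each decoder skip connection fuses features from two consecutive encoder
  levels (the same-resolution level plus the next deeper one, upsampled);
* attention is applied twice — additive attention gates on the skip paths
  (gated by the decoder feature at the same resolution) and channel
  (squeeze-excitation) attention after every encoder/decoder unit;
* an atrous spatial pyramid pooling (ASPP) block with parallel dilated
  convolutions sits at the bottleneck.

The network maps an HxW single-channel image (H, W divisible by 2**depth) to
an HxW per-pixel foreground probability map. Training uses Dice + binary
cross-entropy loss with Adam; everything runs on the package's deterministic
numpy tensor engine, so fixed seeds give bit-identical runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from . import nn
from .nn import Tensor
from .simdata import LabeledFrame
from .video import HeartVideo

__all__ = [
    "SegModelConfig", "SegTrainConfig", "SegMetrics", "ZVSegNet",
    "build_zvsegnet", "train_segmenter", "segment_video", "segment_frame",
    "baseline_segment", "seg_metrics", "save_seg_checkpoint",
    "load_seg_checkpoint",
]


@dataclass(frozen=True)
class SegModelConfig:
    input_channels: int = 1
    base_width: int = 8
    depth: int = 3
    rrcu_steps: int = 2
    use_attention: bool = True
    use_aspp: bool = True
    aspp_dilations: tuple[int, ...] = (1, 2, 4, 8)
    dropout: float = 0.0
    init_seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        if self.rrcu_steps < 1:
            raise ValueError("rrcu_steps must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class SegTrainConfig:
    epochs: int = 8
    batch_size: int = 8
    lr: float = 3e-3
    clip_norm: float = 5.0
    threshold: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class SegMetrics:
    """Overlap metrics for binary segmentation; all in [0, 1].

    By construction dice = 2*iou/(1 + iou).
    """

    iou: float
    dice: float
    precision: float
    recall: float


# --------------------------------------------------------------------------
# Architecture blocks
# --------------------------------------------------------------------------

class _RCL(nn.Module):
    """Recurrent convolution layer: h <- relu(conv(x + h)), shared weights."""

    def __init__(self, c: int, steps: int, rng):
        self.steps = steps
        self.conv = nn.Conv2d(c, c, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x).relu()
        for _ in range(self.steps - 1):
            h = self.conv(x + h).relu()
        return h


class _RRCU(nn.Module):
    """Recurrent residual convolutional unit with two stacked RCL layers."""

    def __init__(self, c_in: int, c_out: int, steps: int, rng):
        self.proj = nn.Conv2d(c_in, c_out, 1, rng)
        self.rcl1 = _RCL(c_out, steps, rng)
        self.rcl2 = _RCL(c_out, steps, rng)

    def forward(self, x: Tensor) -> Tensor:
        x1 = self.proj(x)
        return x1 + self.rcl2(self.rcl1(x1))


class _ChannelAttention(nn.Module):
    """Squeeze-excitation channel attention."""

    def __init__(self, c: int, rng, reduction: int = 4):
        hidden = max(2, c // reduction)
        self.fc1 = nn.Conv2d(c, hidden, 1, rng)
        self.fc2 = nn.Conv2d(hidden, c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        s = nn.global_avgpool2d(x)
        s = self.fc2(self.fc1(s).relu()).sigmoid()
        return x * s


class _AttentionGate(nn.Module):
    """Additive attention gate: skip features weighted by a gating signal."""

    def __init__(self, c_skip: int, c_gate: int, rng):
        inter = max(2, c_skip // 2)
        self.wx = nn.Conv2d(c_skip, inter, 1, rng)
        self.wg = nn.Conv2d(c_gate, inter, 1, rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng)

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        att = self.psi((self.wx(x) + self.wg(g)).relu()).sigmoid()
        return x * att


class _ASPP(nn.Module):
    """Parallel dilated 3x3 convolutions, concatenated and fused by 1x1."""

    def __init__(self, c: int, dilations: tuple[int, ...], rng):
        self.branches = [nn.Conv2d(c, c, 3, rng, dilation=d)
                         for d in dilations]
        self.fuse = nn.Conv2d(c * len(dilations), c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = [b(x).relu() for b in self.branches]
        return self.fuse(nn.concat(feats, axis=1)).relu()


class ZVSegNet(nn.Module):
    """Recurrent-residual attention U-Net with two-level skip fusion."""

    def __init__(self, config: SegModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        d, w0 = config.depth, config.base_width
        widths = [w0 * 2 ** i for i in range(d + 1)]  # enc levels + bottleneck
        self.enc = [_RRCU(config.input_channels if i == 0 else widths[i - 1],
                          widths[i], config.rrcu_steps, rng)
                    for i in range(d)]
        self.bottleneck = _RRCU(widths[d - 1], widths[d], config.rrcu_steps,
                                rng)
        self.aspp = (_ASPP(widths[d], config.aspp_dilations, rng)
                     if config.use_aspp else None)
        if config.use_attention:
            self.enc_se = [_ChannelAttention(widths[i], rng) for i in range(d)]
        else:
            self.enc_se = []

        # decoder level i consumes: upsampled deeper feature (widths[i+1]) +
        # skip from enc[i] (widths[i]) + (for i < d-1) skip from enc[i+1]
        self.dec: list[_RRCU] = []
        self.gates: list = []
        self.dec_se: list = []
        for i in reversed(range(d)):
            c_in = widths[i + 1] + widths[i]
            if i < d - 1:
                c_in += widths[i + 1]
            self.dec.append(_RRCU(c_in, widths[i], config.rrcu_steps, rng))
            if config.use_attention:
                gates = [_AttentionGate(widths[i], widths[i + 1], rng)]
                if i < d - 1:
                    gates.append(_AttentionGate(widths[i + 1], widths[i + 1],
                                                rng))
                self.gates.append(gates)
                self.dec_se.append(_ChannelAttention(widths[i], rng))
        self.head = nn.Conv2d(w0, 1, 1, rng)
        self._dropout_rng = np.random.default_rng(config.init_seed + 1)

    # -----
    def _check_size(self, h: int, w: int) -> None:
        m = 2 ** self.config.depth
        if h % m or w % m:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2**depth = {m}; "
                "pad the frames (see segment_video, which pads and crops "
                "automatically)")

    def forward_logits(self, x, train: bool = False) -> Tensor:
        """(N, C, H, W) array or Tensor -> (N, 1, H, W) pre-sigmoid logits."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        _, _, H, W = x.shape
        self._check_size(H, W)
        cfg = self.config
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if cfg.use_attention:
                h = self.enc_se[i](h)
            skips.append(h)
            h = nn.maxpool2d(h)
        h = self.bottleneck(h)
        if self.aspp is not None:
            h = self.aspp(h)
        if train and cfg.dropout > 0:
            keep = (self._dropout_rng.random(h.shape) >= cfg.dropout)
            h = h * Tensor(keep.astype(np.float32) / (1.0 - cfg.dropout))
        for j, i in enumerate(reversed(range(cfg.depth))):
            up = nn.upsample2d(h)
            parts = [up]
            skip_same = skips[i]
            skip_deep = (nn.upsample2d(skips[i + 1])
                         if i < cfg.depth - 1 else None)
            if cfg.use_attention:
                skip_same = self.gates[j][0](skip_same, up)
                if skip_deep is not None:
                    skip_deep = self.gates[j][1](skip_deep, up)
            parts.append(skip_same)
            if skip_deep is not None:
                parts.append(skip_deep)
            h = self.dec[j](nn.concat(parts, axis=1))
            if cfg.use_attention:
                h = self.dec_se[j](h)
        return self.head(h)

    def forward(self, x, train: bool = False) -> Tensor:
        """(N, C, H, W) array or Tensor -> (N, 1, H, W) probabilities."""
        return self.forward_logits(x, train=train).sigmoid()


def build_zvsegnet(config: SegModelConfig | None = None) -> ZVSegNet:
    """Construct a ZVSegNet from its configuration."""
    return ZVSegNet(config or SegModelConfig())


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def _normalize(img: np.ndarray) -> np.ndarray:
    """Per-frame min-max normalization to [0, 1]; flat frames map to 0."""
    img = np.asarray(img, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _to_batch(frames: list[LabeledFrame]):
    x = np.stack([_normalize(f.image)[None] for f in frames])
    y = np.stack([np.asarray(f.mask, dtype=np.float32)[None] for f in frames])
    return x, y


def _seg_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    # BCE on logits keeps a nonvanishing gradient when the output saturates
    # (early all-background collapse on class-imbalanced masks); Dice on the
    # probabilities drives the overlap once foreground appears
    return (nn.bce_with_logits_loss(logits, target)
            + nn.dice_loss(logits.sigmoid(), target))


def train_segmenter(train_set: list[LabeledFrame],
                    val_set: list[LabeledFrame],
                    config: SegTrainConfig | None = None,
                    model: ZVSegNet | None = None):
    """Supervised training loop; returns (best model, per-epoch history).

    Loss is Dice + BCE on the sigmoid output, optimized with Adam. The model
    with the lowest validation loss is returned; the history records, per
    epoch, the mean training loss, validation loss, and validation SegMetrics
    at the configured binarization threshold. Fully deterministic per seed.
    """
    config = config or SegTrainConfig()
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    for f in train_set + val_set:
        if not np.isin(np.asarray(f.mask), (0, 1)).all():
            raise ValueError("masks must be binary")
    if model is None:
        model = build_zvsegnet(SegModelConfig(init_seed=config.seed))
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    xv, yv = _to_batch(val_set)

    history: list[dict] = []
    best_state, best_val = None, np.inf
    n = len(train_set)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            xb, yb = _to_batch(batch)
            logits = model.forward_logits(xb, train=True)
            loss = _seg_loss(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.clip_grad_norm(config.clip_norm)
            opt.step()
            losses.append(float(loss.data))
        # validation (no autograd graph, in mini-batches to bound memory)
        val_losses, vpred = [], []
        with nn.autograd.no_grad():
            for start in range(0, len(val_set), config.batch_size):
                xb = xv[start:start + config.batch_size]
                yb = yv[start:start + config.batch_size]
                logits = model.forward_logits(xb)
                val_losses.append(float(_seg_loss(logits, yb).data) * len(xb))
                vpred.append(logits.data)
        val_loss = float(np.sum(val_losses) / len(val_set))
        from scipy.special import expit
        pred_masks = expit(np.concatenate(vpred)[:, 0]) >= config.threshold
        metrics = seg_metrics(pred_masks, yv[:, 0] > 0.5)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "metrics": metrics})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, history


# --------------------------------------------------------------------------
# Inference
# --------------------------------------------------------------------------

def _largest_cc(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest connected foreground component."""
    if not mask.any():
        return mask
    lab = cc_label(mask)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(counts.argmax())


def _pad_to_multiple(img: np.ndarray, m: int):
    h, w = img.shape
    ph, pw = (-h) % m, (-w) % m
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    return img, (h, w)


def segment_frame(model: ZVSegNet, frame: np.ndarray,
                  threshold: float = 0.5) -> np.ndarray:
    """Segment a single frame; pads to the model's size contract and crops
    the mask back to the original coordinates."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    m = 2 ** model.config.depth
    x, (h, w) = _pad_to_multiple(_normalize(frame), m)
    with nn.autograd.no_grad():
        prob = model.forward(x[None, None]).data[0, 0, :h, :w]
    return _largest_cc(prob >= threshold)


def segment_video(model: ZVSegNet, video: HeartVideo,
                  threshold: float = 0.5, batch_size: int = 8) -> np.ndarray:
    """Per-frame probability maps binarized at `threshold`, post-processed to
    the single largest connected component. Returns a (T, H, W) bool array;
    frames with no pixel above threshold yield empty masks."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    m = 2 ** model.config.depth
    T, H, W = video.shape
    padded = [_pad_to_multiple(_normalize(f), m)[0] for f in video.frames]
    out = np.zeros((T, H, W), dtype=bool)
    with nn.autograd.no_grad():
        for start in range(0, T, batch_size):
            xb = np.stack(padded[start:start + batch_size])[:, None]
            prob = model.forward(xb).data[:, 0, :H, :W]
            for k in range(prob.shape[0]):
                out[start + k] = _largest_cc(prob[k] >= threshold)
    return out


def baseline_segment(video: HeartVideo, min_range: float = 1e-6) -> np.ndarray:
    """Classical model-free segmenter: per-frame Otsu threshold followed by
    largest-connected-component selection.

    Otsu's threshold is computed on the intensity histogram, so the result is
    invariant to any positive affine rescaling of the intensities. Frames with
    no separable foreground (dynamic range below `min_range`) yield empty
    masks. Deterministic; used as the clean-data oracle and as the --baseline
    pipeline mode.
    """
    T, H, W = video.shape
    out = np.zeros((T, H, W), dtype=bool)
    for i, frame in enumerate(video.frames):
        if float(frame.max() - frame.min()) < min_range:
            continue
        thr = threshold_otsu(frame)
        out[i] = _largest_cc(frame > thr)
    return out


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def _metrics_from_counts(tp: float, fp: float, fn: float) -> SegMetrics:
    union = tp + fp + fn
    iou = tp / union if union > 0 else 1.0
    dice = 2 * tp / (2 * tp + fp + fn) if union > 0 else 1.0
    precision = tp / (tp + fp) if tp + fp > 0 else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if tp + fn > 0 else (1.0 if fp == 0 else 0.0)
    return SegMetrics(iou=iou, dice=dice, precision=precision, recall=recall)


def seg_metrics(predicted: np.ndarray, truth: np.ndarray,
                mode: str = "pooled") -> SegMetrics:
    """IoU, Dice, precision and recall between aligned binary mask arrays.

    mode="pooled" accumulates TP/FP/FN over all frames before dividing
    (micro-average); mode="per-frame" averages the per-frame metrics
    (macro-average). An empty predicted and empty truth pair counts as
    perfect agreement (all metrics 1), and one-sided empties resolve as the
    corresponding zero-overlap case.
    """
    p = np.asarray(predicted).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError("mask arrays must have identical shapes")
    if mode == "pooled":
        tp = float(np.count_nonzero(p & t))
        fp = float(np.count_nonzero(p & ~t))
        fn = float(np.count_nonzero(~p & t))
        return _metrics_from_counts(tp, fp, fn)
    if mode == "per-frame":
        if p.ndim != 3:
            raise ValueError("per-frame mode needs (T, H, W) arrays")
        per = [seg_metrics(p[i], t[i], mode="pooled") for i in range(p.shape[0])]
        return SegMetrics(*(float(np.mean([getattr(m, f) for m in per]))
                            for f in ("iou", "dice", "precision", "recall")))
    raise ValueError(f"unknown mode {mode!r}")


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------

def save_seg_checkpoint(model: ZVSegNet, path) -> None:
    """Weights as .npz with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, *model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_seg_checkpoint(path) -> ZVSegNet:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["aspp_dilations"] = tuple(cfg["aspp_dilations"])
    model = build_zvsegnet(SegModelConfig(**cfg))
    with np.load(path) as data:
        model.load_state_dict([data[k] for k in data.files])
    return model
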