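"""Heart-rate estimation from 1-D ventricular-area sequences.

HRNet regresses beats-per-minute from the time-varying ventricular area
produced by segmentation. The architecture has three parts: a 3-layer 1-D CNN
extracting low-level features from the input sequence, an inception layer
whose parallel multi-kernel branches capture peak structure at several time
scales, and a 3-layer MLP that integrates the sequence globally (suppressing
spurious noise peaks) and predicts the rate through a softplus so the output
is nonnegative.

A classical peak-counting oracle (cycle detection + cycles/duration x 60) is
provided alongside; on clean periodic traces it is exact, and trained models
are evaluated against it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .cardiometrics import (NO_HEARTBEAT, OK, AreaTrace, detect_cycles,
                            hr_from_cycles)
from .simdata import split_dataset

__all__ = [
    "HRModelConfig", "HRTrainConfig", "HRMetrics", "HREstimate", "HRNet",
    "preprocess_trace", "build_hrnet", "hr_peak_oracle", "train_hrnet",
    "predict_hr", "hr_metrics", "save_hr_checkpoint", "load_hr_checkpoint",
]


@dataclass(frozen=True)
class HRModelConfig:
    input_length: int = 100
    cnn_channels: tuple[int, int, int] = (8, 16, 16)
    cnn_kernel: int = 5
    inception_kernel_sizes: tuple[int, ...] = (3, 7, 15)
    inception_width: int = 8
    mlp_widths: tuple[int, int, int] = (64, 32, 1)
    init_seed: int = 0

    def __post_init__(self):
        if len(self.cnn_channels) != 3:
            raise ValueError("exactly 3 CNN layers are required")
        if len(self.mlp_widths) != 3:
            raise ValueError("exactly 3 MLP layers are required")
        if self.mlp_widths[-1] != 1:
            raise ValueError("the final MLP layer must output one value")
        if not self.inception_kernel_sizes:
            raise ValueError("inception needs at least one kernel size")
        if any(k % 2 == 0 for k in self.inception_kernel_sizes):
            raise ValueError("inception kernel sizes must be odd")
        if self.input_length % 4 != 0:
            raise ValueError("input_length must be divisible by 4 "
                             "(two pooling stages)")


@dataclass(frozen=True)
class HRTrainConfig:
    epochs: int = 150
    batch_size: int = 32
    lr: float = 2e-3
    seed: int = 0
    split_ratio: tuple[int, int] = (4, 1)


@dataclass(frozen=True)
class HRMetrics:
    """rmse >= mae always; rmse^2 = bias^2 + sd^2 (population form);
    r is NaN when either side has zero variance (undefined, not 0)."""

    rmse: float
    mae: float
    r: float
    sd: float


@dataclass(frozen=True)
class HREstimate:
    bpm: float
    status: str = OK


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def preprocess_trace(trace, input_length: int = 100) -> np.ndarray:
    """Linear resample to `input_length` samples, then standardize to zero
    mean / unit variance. Constant traces map to all-zeros."""
    areas = trace.areas if isinstance(trace, AreaTrace) else np.asarray(
        trace, dtype=float)
    if areas.ndim != 1 or len(areas) < 2:
        raise ValueError("trace must be 1-D with length >= 2")
    n = len(areas)
    x = np.interp(np.linspace(0.0, n - 1.0, input_length),
                  np.arange(n), areas)
    sd = x.std()
    if sd == 0:
        return np.zeros(input_length, dtype=np.float32)
    return ((x - x.mean()) / sd).astype(np.float32)


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

class HRNet(nn.Module):
    """3-layer 1-D CNN -> multi-kernel inception -> 3-layer MLP -> softplus."""

    def __init__(self, config: HRModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        c1, c2, c3 = config.cnn_channels
        k = config.cnn_kernel
        self.conv1 = nn.Conv1d(1, c1, k, rng)
        self.conv2 = nn.Conv1d(c1, c2, k, rng)
        self.conv3 = nn.Conv1d(c2, c3, k, rng)
        self.inception = [nn.Conv1d(c3, config.inception_width, ks, rng)
                          for ks in config.inception_kernel_sizes]
        feat_len = config.input_length // 4
        feat_dim = config.inception_width * len(config.inception_kernel_sizes)
        w1, w2, w3 = config.mlp_widths
        self.fc1 = nn.Linear(feat_dim * feat_len, w1, rng)
        self.fc2 = nn.Linear(w1, w2, rng)
        self.fc3 = nn.Linear(w2, w3, rng)

    def forward(self, x) -> Tensor:
        """(N, L) or (L,) standardized sequences -> (N,) bpm predictions."""
        arr = x.data if isinstance(x, Tensor) else np.asarray(
            x, dtype=np.float32)
        squeeze = arr.ndim == 1
        if squeeze:
            arr = arr[None]
        if arr.shape[1] != self.config.input_length:
            raise ValueError(f"expected length {self.config.input_length}, "
                             f"got {arr.shape[1]}")
        h = Tensor(arr[:, None, :]) if not isinstance(x, Tensor) else \
            x.reshape(arr.shape[0], 1, arr.shape[1])
        h = nn.maxpool1d(self.conv1(h).relu())
        h = nn.maxpool1d(self.conv2(h).relu())
        h = self.conv3(h).relu()
        h = nn.concat([b(h).relu() for b in self.inception], axis=1)
        n, c, l = h.shape
        h = h.reshape(n, c * l)
        h = self.fc2(self.fc1(h).relu()).relu()
        return self.fc3(h).softplus().reshape(n)


def build_hrnet(config: HRModelConfig | None = None) -> HRNet:
    """Construct an HRNet from its configuration."""
    return HRNet(config or HRModelConfig())


# --------------------------------------------------------------------------
# Classical oracle
# --------------------------------------------------------------------------

def hr_peak_oracle(trace: AreaTrace) -> HREstimate:
    """Peak-counting heart rate: detected contraction cycles over the video
    length, times 60. Deterministic; exact on clean periodic traces."""
    markers = detect_cycles(trace)
    if markers.n_cycles == 0:
        return HREstimate(bpm=0.0, status=NO_HEARTBEAT)
    return HREstimate(
        bpm=hr_from_cycles(markers.n_cycles, trace.duration_seconds),
        status=OK)


# --------------------------------------------------------------------------
# Training / evaluation
# --------------------------------------------------------------------------

def train_hrnet(dataset, model_config: HRModelConfig | None = None,
                train_config: HRTrainConfig | None = None):
    """Train on (areas, true_bpm) pairs; returns (model, validation HRMetrics).

    The dataset is split 4:1 (seeded) following the training protocol; the
    loss is mean squared error on bpm, optimized with Adam. Deterministic per
    seed.
    """
    model_config = model_config or HRModelConfig()
    train_config = train_config or HRTrainConfig()
    data = list(dataset)
    if len(data) < 10:
        raise ValueError("need at least 10 examples")
    labels = np.array([float(b) for _, b in data])
    if np.any(labels <= 0):
        raise ValueError("heart-rate labels must be positive")
    if np.all(labels == labels[0]):
        warnings.warn("all labels identical: Pearson r will be undefined")

    train, val = split_dataset(data, ratio=train_config.split_ratio,
                               seed=train_config.seed)
    xtr = np.stack([preprocess_trace(a, model_config.input_length)
                    for a, _ in train])
    ytr = np.array([b for _, b in train], dtype=np.float32)
    xva = np.stack([preprocess_trace(a, model_config.input_length)
                    for a, _ in val])
    yva = np.array([b for _, b in val], dtype=np.float32)

    model = build_hrnet(model_config)
    rng = np.random.default_rng(train_config.seed)
    opt = nn.Adam(model.parameters(), lr=train_config.lr)
    n = len(xtr)
    for _ in range(train_config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            pred = model.forward(xtr[idx])
            loss = nn.mse_loss(pred, ytr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    with nn.autograd.no_grad():
        metrics = hr_metrics(model.forward(xva).data, yva)
    return model, metrics


def predict_hr(model: HRNet, trace) -> float:
    """Estimate bpm for one trace (resampled + standardized internally)."""
    x = preprocess_trace(trace, model.config.input_length)
    with nn.autograd.no_grad():
        return float(model.forward(x[None]).data[0])


def hr_metrics(predicted, truth) -> HRMetrics:
    """RMSE, MAE, Pearson r and the population SD of signed errors (bpm)."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("predicted and truth must be equal-length nonempty")
    err = p - t
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    sd = float(np.std(err))
    if p.std() == 0 or t.std() == 0:
        warnings.warn("zero variance: Pearson r undefined")
        r = float("nan")
    else:
        r = float(np.corrcoef(p, t)[0, 1])
    return HRMetrics(rmse=rmse, mae=mae, r=r, sd=sd)


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------

def save_hr_checkpoint(model: HRNet, path) -> None:
    path = Path(path)
    np.savez(path, *model.state_dict())
    path.with_suffix(".json").write_text(
        json.dumps(asdict(model.config), indent=2))


def load_hr_checkpoint(path) -> HRNet:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    for key in ("cnn_channels", "inception_kernel_sizes", "mlp_widths"):
        cfg[key] = tuple(cfg[key])
    model = build_hrnet(HRModelConfig(**cfg))
    with np.load(path) as data:
        model.load_state_dict([data[k] for k in data.files])
    return model
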