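"""Layers, parameter containers, optimizer and losses for the tensor engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv1d, conv2d

_DTYPE = np.float32


class Module:
    """Base class: recursively collects Tensor parameters from attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match model parameters")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {s.shape}")
            p.data = s.astype(_DTYPE).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v):
    if isinstance(v, Tensor):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DTYPE)
    return Tensor(w, requires_grad=True)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dilation: int = 1):
        self.dilation = dilation
        self.w = _he(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = Tensor(np.zeros(c_out, dtype=_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, dilation=self.dilation)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dilation: int = 1):
        self.dilation = dilation
        self.w = _he(rng, (c_out, c_in, k), c_in * k)
        self.b = Tensor(np.zeros(c_out, dtype=_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, dilation=self.dilation)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _he(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out, dtype=_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Adam:
    """Adam with bias correction; operates in-place on parameter data."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale gradients so their global L2 norm is at most max_norm."""
        total = float(np.sqrt(sum(float((p.grad ** 2).sum())
                                  for p in self.params if p.grad is not None)))
        if total > max_norm > 0:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return total

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on logits:
    mean(softplus(z) - z*t); its gradient sigmoid(z) - t never vanishes in
    saturation, unlike BCE on clamped probabilities."""
    t = Tensor(target)
    return (logits.softplus() - logits * t).mean()


def bce_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy on probabilities (clamped away from 0/1)."""
    p = prob * (1.0 - 2.0 * eps) + eps
    t = Tensor(target)
    return -((t * p.log()) + ((1.0 - t) * (1.0 - p).log())).mean()


def dice_loss(prob: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss, 1 - 2|P∩T| / (|P| + |T|), smoothed by `eps`."""
    t = Tensor(target)
    inter = (prob * t).sum()
    denom = prob.sum() + t.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = Tensor(np.asarray(target, dtype=_DTYPE))
    d = pred - t
    return (d * d).mean()
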