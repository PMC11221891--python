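"""Layers, initializers and the Adam optimizer used by the three model stages.

Parameters are plain :class:`~stgat.autograd.Tensor` objects with
``requires_grad=True`` collected in ordered dicts, which keeps checkpoint
serialization trivial and byte-deterministic.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

CHECKPOINT_FORMAT = "stgat-checkpoint-1"


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype), requires_grad=True)


def zeros(shape, dtype):
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

@dataclass
class Linear:
    """Affine map ``x @ W + b`` with W of shape (in_features, out_features)."""

    weight: Tensor
    bias: Tensor

    @classmethod
    def init(cls, rng, in_features: int, out_features: int, dtype) -> "Linear":
        w = glorot_uniform(rng, (in_features, out_features), in_features, out_features, dtype)
        return cls(weight=w, bias=zeros((out_features,), dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.weight": self.weight, f"{prefix}.bias": self.bias}


@dataclass
class Conv2d:
    """Stride-1 'same' convolution with a 3x3 (configurable) kernel."""

    weight: Tensor  # (out_ch, in_ch, k, k)
    bias: Tensor  # (out_ch,)
    padding: int

    @classmethod
    def init(cls, rng, in_ch: int, out_ch: int, kernel_size: int, dtype) -> "Conv2d":
        fan_in = in_ch * kernel_size * kernel_size
        fan_out = out_ch * kernel_size * kernel_size
        w = glorot_uniform(rng, (out_ch, in_ch, kernel_size, kernel_size), fan_in, fan_out, dtype)
        return cls(weight=w, bias=zeros((out_ch,), dtype), padding=kernel_size // 2)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.weight": self.weight, f"{prefix}.bias": self.bias}


@dataclass
class ConvBlock:
    """One CNN block: convolution + ReLU, with optional 2x2 max pooling."""

    conv: Conv2d
    pool: bool

    def __call__(self, x: Tensor) -> Tensor:
        out = self.conv(x).relu()
        if self.pool:
            out = out.maxpool2d(2)
        return out

    def params(self, prefix: str) -> dict[str, Tensor]:
        return self.conv.params(f"{prefix}.conv")


def nonlinearity(name: str):
    if name == "relu":
        return lambda t: t.relu()
    if name == "elu":
        return lambda t: t.elu()
    raise ValueError(f"unknown nonlinearity {name!r}")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse(pred: Tensor, target: Tensor | np.ndarray) -> Tensor:
    target = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=pred.dtype))
    diff = pred - target
    return (diff * diff).mean()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer `labels` under softmax(logits)."""
    n, k = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant; softmax-invariant
    z = logits - shift
    lse = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - lse
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def softmax_rows(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    e = (logits - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


def zscore(t: Tensor, axis: int) -> Tensor:
    """Z-score along `axis`; constant slices map to zero (guarded variance)."""
    mu = t.mean(axis=axis, keepdims=True)
    centered = t - mu
    var = (centered * centered).mean(axis=axis, keepdims=True)
    sd = (var + 1e-12) ** 0.5
    return centered / sd


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# checkpoint serialization
# ---------------------------------------------------------------------------

def params_hash(params: dict[str, Tensor]) -> str:
    h = hashlib.sha256()
    for name in sorted(params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(params[name].data).tobytes())
    return h.hexdigest()


def serialize_state(kind: str, config_dict: dict, params: dict[str, Tensor],
                    extra: dict | None = None) -> bytes:
    payload = {
        "format": CHECKPOINT_FORMAT,
        "kind": kind,
        "config": config_dict,
        "params": {k: np.ascontiguousarray(v.data) for k, v in params.items()},
        "params_hash": params_hash(params),
        "extra": extra or {},
    }
    return pickle.dumps(payload, protocol=4)


def deserialize_state(blob: bytes) -> dict:
    payload = pickle.loads(blob)
    if payload.get("format") != CHECKPOINT_FORMAT:
        raise ValueError("not a recognized checkpoint")
    return payload
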