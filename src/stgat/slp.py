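"""Spot Label Predictor (SLP): tumor / non-tumor classification of spots.

A five-block CNN (each block convolution + ReLU + 2x2 max pooling), a global
max pool, two FC layers and a two-class softmax.  The F1 objective stated
for this stage is not differentiable, so training minimizes cross-entropy
while model selection follows the stated procedure: after each epoch the
decision threshold is chosen on a held-out validation split by maximizing
Youden's J = sensitivity + specificity - 1, and the epoch whose validation
F1 (at its Youden threshold) is best supplies the final parameters and
threshold.  The trained threshold is persisted with the checkpoint and
reused as-is on new slides.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import train_test_split

from .autograd import Tensor, concat
from .datatypes import BulkVector, ExpressionMatrix, PatchStack
from .nn import (
    Adam,
    ConvBlock,
    Conv2d,
    Linear,
    cross_entropy,
    deserialize_state,
    serialize_state,
    softmax_rows,
    params_hash,
)

logger = logging.getLogger(__name__)


@dataclass
class SlpConfig:
    conv_channels: tuple = (32, 64, 64, 128, 128)
    patch_side: int = 224
    input_downsample: int = 1
    kernel_size: int = 3
    fc_hidden: int = 128
    val_fraction: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 30
    seed: int = 0
    dtype: str = "float32"


def reduced_slp_config(seed: int = 0, **overrides) -> SlpConfig:
    cfg = dict(conv_channels=(8, 8, 16, 16, 32), input_downsample=7,
               fc_hidden=32, epochs=30, seed=seed)
    cfg.update(overrides)
    return SlpConfig(**cfg)


class SlpModel:
    kind = "slp"

    def __init__(self, config: SlpConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        side = config.patch_side // config.input_downsample
        self.blocks: list[ConvBlock] = []
        in_ch = 3
        for out_ch in config.conv_channels:
            pool = side % 2 == 0 and side > 1
            self.blocks.append(ConvBlock(
                conv=Conv2d.init(rng, in_ch, out_ch, config.kernel_size, dtype),
                pool=pool))
            if pool:
                side //= 2
            in_ch = out_ch
        self.final_side = side  # global max pool reduces this to 1
        self.fc1 = Linear.init(rng, config.conv_channels[-1], config.fc_hidden, dtype)
        self.fc2 = Linear.init(rng, config.fc_hidden, 2, dtype)
        self.decision_threshold = 0.5

    def params(self) -> dict[str, Tensor]:
        out = {}
        for i, block in enumerate(self.blocks):
            out.update(block.params(f"cnn{i}"))
        out.update(self.fc1.params("fc1"))
        out.update(self.fc2.params("fc2"))
        return out

    def params_hash(self) -> str:
        return params_hash(self.params())

    def save(self, path: str) -> None:
        blob = serialize_state(self.kind, asdict(self.config), self.params(),
                               extra={"decision_threshold": self.decision_threshold})
        with open(path, "wb") as fh:
            fh.write(blob)

    @classmethod
    def load(cls, path: str) -> "SlpModel":
        with open(path, "rb") as fh:
            payload = deserialize_state(fh.read())
        if payload["kind"] != cls.kind:
            raise ValueError(f"checkpoint holds a {payload['kind']!r} model")
        cfg = payload["config"]
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        model = cls(SlpConfig(**cfg))
        for name, tensor in model.params().items():
            tensor.data = payload["params"][name].copy()
        model.decision_threshold = payload["extra"]["decision_threshold"]
        return model


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _prepare(patches: PatchStack | np.ndarray, config: SlpConfig) -> np.ndarray:
    arr = patches.patches if isinstance(patches, PatchStack) else np.asarray(patches)
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValueError("patches must be (g, side, side, 3)")
    if arr.shape[1] != config.patch_side:
        raise ValueError(
            f"patch side {arr.shape[1]} does not match configured {config.patch_side}")
    x = arr.astype(np.dtype(config.dtype)) / 255.0
    d = config.input_downsample
    if d > 1:
        g, s, _, _ = x.shape
        x = x.reshape(g, s // d, d, s // d, d, 3).mean(axis=(2, 4))
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _logits(x_np: np.ndarray, model: SlpModel, batch_size: int) -> Tensor:
    outs = []
    for start in range(0, x_np.shape[0], batch_size):
        x = Tensor(x_np[start:start + batch_size])
        for block in model.blocks:
            x = block(x)
        x = x.maxpool2d(model.final_side) if model.final_side > 1 else x
        x = x.reshape(x.shape[0], int(np.prod(x.shape[1:])))
        outs.append(model.fc2(model.fc1(x).relu()))
    return outs[0] if len(outs) == 1 else concat(outs, axis=0)


def slp_forward(patches, model: SlpModel, prepared: bool = False) -> np.ndarray:
    """Tumor-class probability for each spot (two-class softmax, class 1)."""
    x_np = patches if prepared else _prepare(patches, model.config)
    logits = _logits(x_np, model, model.config.batch_size)
    probs = softmax_rows(logits).data
    return np.asarray(probs[:, 1], dtype=float)


def youden_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the observed probabilities; classification at a candidate
    t counts prob >= t as tumor.  Ties on J are broken by the smallest
    threshold.  Both classes must be present.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have the same length")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present to compute Youden's index")
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(probs)):
        pred = probs >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / (labels.size - n_pos)
        j = sens + spec - 1.0
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def classify_spots(probs: np.ndarray, threshold: float) -> np.ndarray:
    """Binary tumor mask: tumor iff probability >= threshold."""
    return np.asarray(probs, dtype=float) >= threshold


def f1_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Harmonic mean of precision and recall; 0 when precision + recall = 0."""
    return float(_sk_f1(np.asarray(truth).astype(int), np.asarray(pred).astype(int),
                        zero_division=0))


def tumor_average_expression(expr: ExpressionMatrix, tumor_mask: np.ndarray,
                             fallback_all_spots: bool = False) -> BulkVector:
    """Column mean of expression over tumor-masked spots.

    With an all-negative mask, raises unless ``fallback_all_spots=True`` in
    which case the plain all-spot average is returned.
    """
    mask = np.asarray(tumor_mask, dtype=bool)
    if mask.shape[0] != expr.n_spots:
        raise ValueError("mask length must equal the number of spots")
    if not mask.any():
        if not fallback_all_spots:
            raise ValueError("no tumor spots; pass fallback_all_spots=True to "
                             "average over all spots instead")
        mask = np.ones_like(mask)
    return BulkVector(values=expr.values[mask].mean(axis=0),
                      gene_ids=list(expr.gene_ids))


def train_slp(samples: list[tuple[PatchStack, np.ndarray]],
              config: SlpConfig) -> SlpModel:
    """Fit the classifier on labeled spot patches.

    Spots from all samples are pooled, split 80/20 stratified (seeded) for
    validation; cross-entropy is minimized, and the epoch with the best
    validation F1 at its Youden threshold is returned.
    """
    if not samples:
        raise ValueError("at least one training sample is required")
    xs = np.concatenate([_prepare(p, config) for p, _ in samples])
    ys = np.concatenate([np.asarray(lab).astype(int) for _, lab in samples])
    if set(np.unique(ys)) != {0, 1}:
        raise ValueError("training labels must contain both classes")
    idx_train, idx_val = train_test_split(
        np.arange(ys.size), test_size=config.val_fraction,
        stratify=ys, random_state=config.seed)
    x_train, y_train = xs[idx_train], ys[idx_train]
    x_val, y_val = xs[idx_val], ys[idx_val]

    model = SlpModel(config)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    best = {"f1": -1.0, "threshold": 0.5, "params": None, "epoch": -1}
    for epoch in range(config.epochs):
        order = rng.permutation(y_train.size)
        total, batches = 0.0, 0
        for start in range(0, y_train.size, config.batch_size):
            sel = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = cross_entropy(_logits(x_train[sel], model, config.batch_size),
                                 y_train[sel])
            loss.backward()
            opt.step()
            total += float(loss.data)
            batches += 1
        val_probs = slp_forward(x_val, model, prepared=True)
        threshold = youden_threshold(val_probs, y_val)
        f1 = f1_score(classify_spots(val_probs, threshold), y_val)
        logger.info("SLP epoch %d/%d: loss %.4f, val F1 %.3f at threshold %.3f",
                    epoch + 1, config.epochs, total / max(batches, 1), f1, threshold)
        if f1 > best["f1"]:
            best = {"f1": f1, "threshold": threshold, "epoch": epoch,
                    "params": {k: v.data.copy() for k, v in model.params().items()}}
    for name, tensor in model.params().items():
        tensor.data = best["params"][name]
    model.decision_threshold = best["threshold"]
    logger.info("SLP selected epoch %d (val F1 %.3f)", best["epoch"] + 1, best["f1"])
    return model
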