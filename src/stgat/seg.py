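"""Spot Embedding Generator (SEG).

Maps spot images plus the sample's spatial adjacency to per-spot gene
expression.  The architecture is a stack of CNN blocks (convolution + ReLU,
with 2x2 max pooling from the second block on), a projection to the CNN
embedding length ``e_c``, an intermediate fully connected layer
``ReLU(W E + B)``, a single multi-head graph-attention layer with separate
self and neighbor coefficients, and a two-layer expression head that is
detached when the trained encoder is reused on whole-slide images.

Attention for spot j over its neighbor set N(j):

    score(j, k) = ReLU(a_s . (W_s E_j) + a_n . (W_n E_k))
    alpha_n(j, .) = softmax over k in N(j)   (non-neighbors are excluded)
    alpha_s(j) = 1 / (1 + sum_k alpha_n(j, k))

so a spot with at least one neighbor has alpha_s = 1/2 exactly and an
isolated spot has alpha_s = 1: the layer deliberately down-weights a spot's
own features in favor of its spatial context.  Each head h emits
``f(alpha_s W'_s E_j + sum_k alpha_n(j,k) W'_n E_k)`` and head outputs are
concatenated.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor, concat
from .datatypes import AdjacencyMatrix, ExpressionMatrix, PatchStack
from .nn import (
    Adam,
    ConvBlock,
    Conv2d,
    Linear,
    deserialize_state,
    mse,
    nonlinearity,
    params_hash,
    serialize_state,
)

logger = logging.getLogger(__name__)


@dataclass
class SegConfig:
    n_genes: int
    conv_channels: tuple = (32, 64, 64, 128, 128, 256)
    patch_side: int = 224
    input_downsample: int = 1  # average-pool factor applied before block 1
    kernel_size: int = 3
    embed_cnn: int = 512  # e_c
    embed_attn: int = 256  # e_a (per head)
    n_heads: int = 2
    head_hidden: int = 256
    attn_nonlinearity: str = "relu"
    head_nonlinearity: str = "relu"  # f in the attention output
    tie_value_weights: bool = False
    alpha_self_from_scores: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0
    dtype: str = "float32"

    @property
    def embed_total(self) -> int:
        """Concatenated embedding length e = h * e_a."""
        return self.n_heads * self.embed_attn

    def __post_init__(self):
        if self.patch_side % self.input_downsample:
            raise ValueError("input_downsample must divide patch_side")
        if len(self.conv_channels) < 1:
            raise ValueError("at least one CNN block is required")


def reduced_seg_config(n_genes: int, seed: int = 0, **overrides) -> SegConfig:
    """Desk-scale configuration used for the bundled synthetic studies."""
    cfg = dict(
        n_genes=n_genes,
        conv_channels=(8, 8, 16, 16, 32, 32),
        input_downsample=7,  # work on 32x32 renditions of the 224x224 patches
        embed_cnn=32,
        embed_attn=16,
        n_heads=2,
        head_hidden=64,
        learning_rate=1e-3,
        epochs=200,
        seed=seed,
    )
    cfg.update(overrides)
    return SegConfig(**cfg)


def _pool_schedule(side: int, n_blocks: int) -> list[bool]:
    """Pool from block 2 on, while the spatial side remains even and > 1."""
    schedule = []
    for i in range(n_blocks):
        pool = i >= 1 and side % 2 == 0 and side > 1
        schedule.append(pool)
        if pool:
            side //= 2
    return schedule


class SegModel:
    """Parameter container + forward pieces for the embedding generator."""

    kind = "seg"

    def __init__(self, config: SegConfig):
        self.config = config
        cfg = config
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        side = cfg.patch_side // cfg.input_downsample
        self.pool_schedule = _pool_schedule(side, len(cfg.conv_channels))
        self.blocks: list[ConvBlock] = []
        in_ch = 3
        for out_ch, pool in zip(cfg.conv_channels, self.pool_schedule):
            self.blocks.append(ConvBlock(
                conv=Conv2d.init(rng, in_ch, out_ch, cfg.kernel_size, dtype), pool=pool))
            in_ch = out_ch
            if pool:
                side //= 2
        self.final_side = side
        flat = side * side * cfg.conv_channels[-1]
        self.fc_proj = Linear.init(rng, flat, cfg.embed_cnn, dtype)  # flatten -> e_c
        self.fc_mid = Linear.init(rng, cfg.embed_cnn, cfg.embed_cnn, dtype)  # Eq. W, B
        e_c, e_a = cfg.embed_cnn, cfg.embed_attn
        self.heads = []
        for _ in range(cfg.n_heads):
            head = {
                "a_s": Linear.init(rng, e_a, 1, dtype).weight,  # attention vectors
                "a_n": Linear.init(rng, e_a, 1, dtype).weight,
                "W_s": Linear.init(rng, e_c, e_a, dtype).weight,
                "W_n": Linear.init(rng, e_c, e_a, dtype).weight,
            }
            if cfg.tie_value_weights:
                head["Wv_s"], head["Wv_n"] = head["W_s"], head["W_n"]
            else:
                head["Wv_s"] = Linear.init(rng, e_c, e_a, dtype).weight
                head["Wv_n"] = Linear.init(rng, e_c, e_a, dtype).weight
            self.heads.append(head)
        self.fc_head1 = Linear.init(rng, cfg.embed_total, cfg.head_hidden, dtype)
        self.fc_head2 = Linear.init(rng, cfg.head_hidden, cfg.n_genes, dtype)
        self._f = nonlinearity(cfg.head_nonlinearity)
        self._attn_f = nonlinearity(cfg.attn_nonlinearity)

    # -- parameter bookkeeping ------------------------------------------------
    def params(self, include_head: bool = True) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for i, block in enumerate(self.blocks):
            out.update(block.params(f"cnn{i}"))
        out.update(self.fc_proj.params("fc_proj"))
        out.update(self.fc_mid.params("fc_mid"))
        for l, head in enumerate(self.heads):
            for name in ("a_s", "a_n", "W_s", "W_n"):
                out[f"head{l}.{name}"] = head[name]
            if not self.config.tie_value_weights:
                out[f"head{l}.Wv_s"] = head["Wv_s"]
                out[f"head{l}.Wv_n"] = head["Wv_n"]
        if include_head:
            out.update(self.fc_head1.params("fc_head1"))
            out.update(self.fc_head2.params("fc_head2"))
        return out

    def params_hash(self) -> str:
        return params_hash(self.params())

    def save(self, path: str) -> None:
        blob = serialize_state(self.kind, asdict(self.config), self.params())
        with open(path, "wb") as fh:
            fh.write(blob)

    @classmethod
    def load(cls, path: str) -> "SegModel":
        with open(path, "rb") as fh:
            payload = deserialize_state(fh.read())
        if payload["kind"] != cls.kind:
            raise ValueError(f"checkpoint holds a {payload['kind']!r} model")
        cfg_dict = payload["config"]
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        model = cls(SegConfig(**cfg_dict))
        for name, tensor in model.params().items():
            tensor.data = payload["params"][name].copy()
        return model


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def prepare_patches(patches: PatchStack | np.ndarray, config: SegConfig) -> np.ndarray:
    """Scale patches to [0, 1], downsample, and lay out as (g, 3, H, W)."""
    arr = patches.patches if isinstance(patches, PatchStack) else np.asarray(patches)
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValueError("patches must be (g, side, side, 3)")
    if arr.shape[1] != config.patch_side or arr.shape[2] != config.patch_side:
        raise ValueError(
            f"patch side {arr.shape[1]} does not match configured {config.patch_side}")
    x = arr.astype(np.dtype(config.dtype)) / 255.0
    d = config.input_downsample
    if d > 1:
        g, s, _, _ = x.shape
        x = x.reshape(g, s // d, d, s // d, d, 3).mean(axis=(2, 4))
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def cnn_encode(patches, model: SegModel, prepared: bool = False) -> Tensor:
    """Run the CNN blocks and the projection FC; returns E1 of shape (g, e_c)."""
    cfg = model.config
    x_np = patches if prepared else prepare_patches(patches, cfg)
    outs = []
    for start in range(0, x_np.shape[0], cfg.batch_size):
        x = Tensor(x_np[start:start + cfg.batch_size])
        for block in model.blocks:
            x = block(x)
        x = x.reshape(x.shape[0], int(np.prod(x.shape[1:])))
        outs.append(model.fc_proj(x))
    return outs[0] if len(outs) == 1 else concat(outs, axis=0)


def intermediate_fc(e1: Tensor, model: SegModel) -> Tensor:
    """E2 = ReLU(E1 W + B), row-wise affine + ReLU."""
    return model.fc_mid(e1).relu()


def attention_coefficients(e2: Tensor, adj: AdjacencyMatrix, model: SegModel,
                           head: int) -> tuple[Tensor, Tensor]:
    """Per-head neighbor coefficients (g x g) and self coefficients (g,).

    Raw scores are computed for neighbor pairs only; the softmax is masked so
    each row is supported on its neighbor set.  ``alpha_s = 1/(1 + sum alpha_n)``
    evaluates to exactly 1/2 for spots with neighbors and 1 for isolated spots.
    """
    h = model.heads[head]
    cfg = model.config
    mask = Tensor(adj.entries.astype(e2.dtype))
    self_part = (e2 @ h["W_s"]) @ h["a_s"]  # (g, 1)
    neigh_part = (e2 @ h["W_n"]) @ h["a_n"]  # (g, 1)
    raw = model._attn_f(self_part + neigh_part.T)  # raw[j, k], broadcast outer sum
    # masked softmax over each row's neighbor set.  Non-neighbor entries get
    # a -1e9 additive offset before the per-row shift, so the shift equals
    # the neighbor maximum: the largest neighbor exponent is exactly 1 (no
    # underflow to an empty row) and non-neighbor exponents cannot overflow.
    offset = Tensor(np.where(adj.entries == 0, -1e9, 0.0).astype(e2.dtype))
    masked = raw * mask + offset
    shift = Tensor(masked.data.max(axis=1, keepdims=True))
    e = (masked - shift).exp() * mask
    row_sum = e.sum(axis=1, keepdims=True)
    has_neighbors = (adj.entries.sum(axis=1, keepdims=True) > 0)
    denom = row_sum + Tensor((~has_neighbors).astype(e2.dtype))
    alpha_n = e / denom
    if cfg.alpha_self_from_scores:
        alpha_total = (raw * mask).sum(axis=1)
    else:
        alpha_total = (row_sum / denom).reshape(row_sum.shape[0])
    alpha_s = 1.0 / (1.0 + alpha_total)
    return alpha_n, alpha_s


def gat_forward(e2: Tensor, adj: AdjacencyMatrix, model: SegModel) -> Tensor:
    """Multi-head attention aggregation; returns E3 of shape (g, h * e_a)."""
    outs = []
    g = e2.shape[0]
    for l in range(model.config.n_heads):
        h = model.heads[l]
        alpha_n, alpha_s = attention_coefficients(e2, adj, model, l)
        v_self = e2 @ h["Wv_s"]  # (g, e_a)
        v_neigh = e2 @ h["Wv_n"]
        mixed = alpha_s.reshape(g, 1) * v_self + alpha_n @ v_neigh
        outs.append(model._f(mixed))
    return concat(outs, axis=1)


def embed_spots(patches, adj: AdjacencyMatrix, model: SegModel) -> np.ndarray:
    """Detached-head forward: patch stack + adjacency -> E3 as a numpy array."""
    e1 = cnn_encode(patches, model)
    e3 = gat_forward(intermediate_fc(e1, model), adj, model)
    return e3.data.copy()


def expression_head(e3: Tensor | np.ndarray, model: SegModel) -> Tensor:
    """Two FC layers projecting spot embeddings onto gene expression."""
    t = e3 if isinstance(e3, Tensor) else Tensor(np.asarray(e3, dtype=model.config.dtype))
    return model.fc_head2(model.fc_head1(t).relu())


def seg_forward(patches, adj: AdjacencyMatrix, model: SegModel,
                prepared: bool = False) -> Tensor:
    e1 = cnn_encode(patches, model, prepared=prepared)
    e3 = gat_forward(intermediate_fc(e1, model), adj, model)
    return expression_head(e3, model)


def predict_expression(patches, adj: AdjacencyMatrix, model: SegModel,
                       gene_ids: list[str] | None = None,
                       spot_ids: list[str] | None = None) -> ExpressionMatrix:
    pred = seg_forward(patches, adj, model).data
    genes = gene_ids if gene_ids is not None else [f"gene_{i}" for i in range(pred.shape[1])]
    return ExpressionMatrix(values=np.asarray(pred, dtype=float), gene_ids=genes,
                            spot_ids=spot_ids)


def seg_loss(pred, truth) -> float | Tensor:
    """Mean squared error over all spot x gene entries."""
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(
        pred.values if isinstance(pred, ExpressionMatrix) else pred))
    t = truth.values if isinstance(truth, ExpressionMatrix) else truth
    out = mse(p, np.asarray(t, dtype=p.dtype))
    return out if isinstance(pred, Tensor) else float(out.data)


def train_seg(samples: list[tuple[PatchStack, AdjacencyMatrix, ExpressionMatrix]],
              config: SegConfig) -> SegModel:
    """Fit the embedding generator on spatial-transcriptomics samples.

    All samples must share the same gene list; training is seeded and
    reproducible bit-for-bit for a fixed config on the same platform class.
    """
    if not samples:
        raise ValueError("at least one training sample is required")
    gene_ids = samples[0][2].gene_ids
    for _, _, expr in samples[1:]:
        if expr.gene_ids != gene_ids:
            raise ValueError("all samples must share the same gene set and order")
    if len(gene_ids) != config.n_genes:
        raise ValueError(f"config.n_genes={config.n_genes} but samples have {len(gene_ids)}")
    model = SegModel(config)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    prepped = [(prepare_patches(p, config), adj,
                np.asarray(expr.values, dtype=config.dtype))
               for p, adj, expr in samples]
    for epoch in range(config.epochs):
        order = rng.permutation(len(prepped))
        total = 0.0
        for idx in order:
            x, adj, y = prepped[idx]
            opt.zero_grad()
            pred = seg_forward(x, adj, model, prepared=True)
            loss = mse(pred, y)
            loss.backward()
            opt.step()
            total += float(loss.data)
        logger.info("SEG epoch %d/%d: mean loss %.6f",
                    epoch + 1, config.epochs, total / len(prepped))
    return model
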