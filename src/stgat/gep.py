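"""Gene Expression Predictor (GEP).

Transfers the frozen, head-less embedding generator to whole-slide images
paired with bulk RNA-seq.  The bulk profile is encoded by two FC layers into
the embedding space; spot embeddings and the bulk embedding are projected by
learnable alignment matrices ``W_spots`` and ``W_bulk``, z-score normalized
(each across the embedding-feature axis; see ``align_and_fuse``), the
normalized bulk embedding is broadcast-added to every spot column, and three
FC layers decode the fused representation into per-spot expression.  The
training signal is indirect: the spot-average of the decoded expression must
reconstruct the sample's true bulk profile (mean squared error).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor
from .datatypes import AdjacencyMatrix, BulkVector, ExpressionMatrix, PatchStack
from .nn import (
    Adam,
    Linear,
    deserialize_state,
    mse,
    params_hash,
    serialize_state,
    zscore,
)
from .seg import SegModel, embed_spots

logger = logging.getLogger(__name__)


@dataclass
class GepConfig:
    n_genes: int
    embed_total: int  # e; must match the SEG checkpoint
    bulk_hidden: int = 256
    decoder_hidden: int = 256
    spot_norm_axis: str = "features"  # z-score each spot column across features
    learning_rate: float = 1e-3
    epochs: int = 1000
    seed: int = 0
    dtype: str = "float32"


def reduced_gep_config(n_genes: int, embed_total: int, seed: int = 0, **overrides) -> GepConfig:
    cfg = dict(n_genes=n_genes, embed_total=embed_total, bulk_hidden=64,
               decoder_hidden=64, epochs=1000, seed=seed)
    cfg.update(overrides)
    return GepConfig(**cfg)


class GepModel:
    kind = "gep"

    def __init__(self, config: GepConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        e, p = config.embed_total, config.n_genes
        self.bulk_fc1 = Linear.init(rng, p, config.bulk_hidden, dtype)
        self.bulk_fc2 = Linear.init(rng, config.bulk_hidden, e, dtype)
        self.W_spots = Linear.init(rng, e, e, dtype).weight  # (e, e), applied as W @ E3^T
        self.W_bulk = Linear.init(rng, e, e, dtype).weight
        self.dec_fc1 = Linear.init(rng, e, config.decoder_hidden, dtype)
        self.dec_fc2 = Linear.init(rng, config.decoder_hidden, config.decoder_hidden, dtype)
        self.dec_fc3 = Linear.init(rng, config.decoder_hidden, p, dtype)

    def params(self) -> dict[str, Tensor]:
        out = {}
        out.update(self.bulk_fc1.params("bulk_fc1"))
        out.update(self.bulk_fc2.params("bulk_fc2"))
        out["W_spots"] = self.W_spots
        out["W_bulk"] = self.W_bulk
        out.update(self.dec_fc1.params("dec_fc1"))
        out.update(self.dec_fc2.params("dec_fc2"))
        out.update(self.dec_fc3.params("dec_fc3"))
        return out

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            fh.write(serialize_state(self.kind, asdict(self.config), self.params()))

    @classmethod
    def load(cls, path: str) -> "GepModel":
        with open(path, "rb") as fh:
            payload = deserialize_state(fh.read())
        if payload["kind"] != cls.kind:
            raise ValueError(f"checkpoint holds a {payload['kind']!r} model")
        model = cls(GepConfig(**payload["config"]))
        for name, tensor in model.params().items():
            tensor.data = payload["params"][name].copy()
        return model


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def encode_bulk(bulk: BulkVector | np.ndarray, model: GepModel) -> Tensor:
    """Two FC layers (ReLU after the first) mapping the bulk profile to Z1 (e,)."""
    values = bulk.values if isinstance(bulk, BulkVector) else np.asarray(bulk)
    x = Tensor(values.astype(model.config.dtype).reshape(1, -1))
    z1 = model.bulk_fc2(model.bulk_fc1(x).relu())
    return z1.reshape(model.config.embed_total)


def align_and_fuse(e3: Tensor | np.ndarray, z1: Tensor, model: GepModel) -> Tensor:
    """Project, normalize and fuse spot and bulk embeddings; returns Z3 (e x m).

    ``E4 = W_spots @ E3^T`` and ``Z2 = W_bulk @ Z1`` are both z-score
    normalized.  By default each spot column of E4 is normalized across its
    e features — the only axis Z2 has, so both summands are normalized the
    same way, and the relative spread between spots (the embedding's
    signal-to-noise structure) is preserved.  ``spot_norm_axis='spots'``
    instead normalizes each feature across the m spots; that axis rejects
    single-spot samples (the variance is identically zero) and forces every
    feature, informative or not, to unit variance.  The normalized bulk
    vector is added to every spot column.
    """
    t3 = e3 if isinstance(e3, Tensor) else Tensor(np.asarray(e3, dtype=model.config.dtype))
    m = t3.shape[0]
    e = model.config.embed_total
    if t3.shape[1] != e:
        raise ValueError(f"embedding length {t3.shape[1]} != configured e={e}")
    e4 = model.W_spots @ t3.T  # (e, m)
    if model.config.spot_norm_axis == "spots":
        if m == 1:
            raise ValueError(
                "cannot z-score a single spot across the spot axis; "
                "use spot_norm_axis='features' for single-spot samples")
        e5 = zscore(e4, axis=1)
    else:
        e5 = zscore(e4, axis=0)
    z2 = zscore((model.W_bulk @ z1.reshape(e, 1)).reshape(e), axis=0)
    return e5 + z2.reshape(e, 1)


def decode_spots(z3: Tensor, model: GepModel) -> Tensor:
    """Three FC layers (ReLU, ReLU, linear) from fused embeddings to (m, p)."""
    x = z3.T
    h = model.dec_fc1(x).relu()
    h = model.dec_fc2(h).relu()
    return model.dec_fc3(h)


def gep_forward(e3: np.ndarray, bulk: BulkVector, model: GepModel) -> Tensor:
    return decode_spots(align_and_fuse(e3, encode_bulk(bulk, model), model), model)


def predict_spot_expression(patches: PatchStack, adj: AdjacencyMatrix,
                            bulk: BulkVector, seg_model: SegModel,
                            gep_model: GepModel,
                            spot_ids: list[str] | None = None) -> ExpressionMatrix:
    """Full WSI route: frozen SEG embeddings -> fused decode -> spot expression."""
    e3 = embed_spots(patches, adj, seg_model)
    pred = gep_forward(e3, bulk, gep_model).data
    return ExpressionMatrix(values=np.asarray(pred, dtype=float),
                            gene_ids=list(bulk.gene_ids), spot_ids=spot_ids)


def gep_loss(pred, bulk: BulkVector | np.ndarray) -> float | Tensor:
    """MSE between the spot-average of the prediction and the true bulk profile."""
    target = bulk.values if isinstance(bulk, BulkVector) else np.asarray(bulk)
    if isinstance(pred, Tensor):
        u = pred.mean(axis=0)
        return mse(u, target.astype(pred.dtype))
    values = pred.values if isinstance(pred, ExpressionMatrix) else np.asarray(pred)
    u = values.mean(axis=0)
    return float(np.mean((u - target) ** 2))


def train_gep(samples: list[tuple[PatchStack, AdjacencyMatrix, BulkVector]],
              seg_model: SegModel, config: GepConfig) -> GepModel:
    """Fit the predictor on (image, bulk) samples with the SEG frozen.

    Because the embedding generator receives no gradient, per-sample spot
    embeddings are computed once up front; the epoch loop then touches only
    the (small) GEP parameters.  The SEG parameter hash is asserted unchanged.
    """
    if not samples:
        raise ValueError("at least one training sample is required")
    gene_ids = samples[0][2].gene_ids
    for _, _, bulk in samples[1:]:
        if bulk.gene_ids != gene_ids:
            raise ValueError("all bulk vectors must share the same gene set and order")
    if len(gene_ids) != config.n_genes:
        raise ValueError(f"config.n_genes={config.n_genes} but bulk has {len(gene_ids)}")
    if seg_model.config.embed_total != config.embed_total:
        raise ValueError("GEP embed_total must match the SEG checkpoint")
    seg_hash_before = seg_model.params_hash()
    embedded = [(embed_spots(patches, adj, seg_model), bulk)
                for patches, adj, bulk in samples]
    model = GepModel(config)
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    for epoch in range(config.epochs):
        order = rng.permutation(len(embedded))
        total = 0.0
        for idx in order:
            e3, bulk = embedded[idx]
            opt.zero_grad()
            pred = gep_forward(e3, bulk, model)
            loss = gep_loss(pred, bulk)
            loss.backward()
            opt.step()
            total += float(loss.data)
        if (epoch + 1) % 100 == 0 or epoch == 0:
            logger.info("GEP epoch %d/%d: mean loss %.6f",
                        epoch + 1, config.epochs, total / len(embedded))
    assert seg_model.params_hash() == seg_hash_before, "SEG must remain frozen"
    return model
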