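"""Synthetic spatial-transcriptomics and pseudo-WSI samples.

The generator plants exactly the structure the models assume so that every
stage is trainable and testable at desk scale without downloads:

* spots on a regular grid inside a tissue rectangle, with a spatially
  contiguous tumor region (disk or half-plane in grid coordinates);
* patch texture whose mean gray level differs between tumor and non-tumor
  spots by ``intensity_contrast`` (per-pixel Gaussian noise on top);
* log-normal base expression with per-gene baselines, a log-scale shift of
  ``marker_effect`` for marker genes inside the tumor region, Gaussian
  log-scale noise, and one pass of neighbor mixing over the same adjacency
  the models consume (spatial autocorrelation);
* a bulk profile equal to the spot-average expression plus Gaussian noise.

Outputs use exactly the formats the other modules read (PNG + TSV), so the
fixtures double as format-conformance tests.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import (
    BulkVector,
    ExpressionMatrix,
    NON_TUMOR,
    TUMOR,
    make_spot_table,
)
from .io import write_bulk, write_expression, write_image, write_spot_table
from .spot_graph import DEFAULT_THRESHOLD, build_adjacency

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    grid: tuple[int, int] = (12, 12)  # rows x cols of spots
    spacing: int = 224  # pixels between neighboring spots (~ crop side)
    margin: int = 136  # pixels from image edge to the first spot (>= 112)
    n_genes: int = 50
    n_marker_genes: int = 5
    marker_effect: float = 2.0  # log-scale shift in tumor spots
    tumor_region: tuple = ("disk", 0.4, 0.4, 0.3)  # kind, cx, cy, radius (grid fracs)
    intensity_contrast: float = 40.0  # mean gray offset, tumor vs non-tumor
    tissue_gray: float = 200.0
    background_gray: float = 245.0
    pixel_noise_sd: float = 8.0
    base_logmean_sd: float = 1.0
    spatial_autocorrelation: float = 0.3  # neighbor-mixing weight in [0, 1)
    noise_sd: float = 0.3  # log-scale expression noise
    bulk_noise_sd: float = 0.01
    adjacency_threshold: float = DEFAULT_THRESHOLD
    gene_seed: int = 1234  # gene baselines shared across a cohort
    seed: int = 0

    @property
    def image_side(self) -> int:
        rows, cols = self.grid
        return 2 * self.margin + (max(rows, cols) - 1) * self.spacing

    def __post_init__(self):
        if self.n_marker_genes > self.n_genes:
            raise ValueError("n_marker_genes must be <= n_genes")
        if not (0.0 <= self.spatial_autocorrelation < 1.0):
            raise ValueError("spatial_autocorrelation must be in [0, 1)")


@dataclass
class SimSample:
    sample_id: str
    image: np.ndarray
    spots: pd.DataFrame
    expression: ExpressionMatrix
    labels: np.ndarray  # boolean, True = tumor
    bulk: BulkVector
    marker_genes: list[str]


def _tumor_mask(cfg: SimConfig) -> np.ndarray:
    rows, cols = cfg.grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    u = cc / max(cols - 1, 1)
    v = rr / max(rows - 1, 1)
    kind = cfg.tumor_region[0]
    if kind == "disk":
        _, cx, cy, radius = cfg.tumor_region
        mask = (u - cx) ** 2 + (v - cy) ** 2 <= radius**2
    elif kind == "halfplane":
        _, frac = cfg.tumor_region
        mask = (u + v) / 2.0 < frac
    else:
        raise ValueError(f"unknown tumor_region kind {kind!r}")
    mask = mask.ravel()
    if not mask.any() or mask.all():
        raise ValueError("tumor_region yields 0 or all tumor spots; adjust it")
    return mask


def gene_ids(cfg: SimConfig) -> list[str]:
    return [f"gene_{i:04d}" for i in range(cfg.n_genes)]


def simulate_sample(cfg: SimConfig, sample_id: str = "sample_0") -> SimSample:
    """Generate one paired (image, spots, expression, labels, bulk) sample."""
    rng_genes = np.random.default_rng(cfg.gene_seed)
    mu = rng_genes.normal(0.0, cfg.base_logmean_sd, size=cfg.n_genes)
    marker_idx = rng_genes.choice(cfg.n_genes, size=cfg.n_marker_genes, replace=False)
    beta = np.zeros(cfg.n_genes)
    beta[marker_idx] = cfg.marker_effect

    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    xs = cfg.margin + cc.ravel() * cfg.spacing
    ys = cfg.margin + rr.ravel() * cfg.spacing
    tumor = _tumor_mask(cfg)
    spots = make_spot_table(
        [f"spot_{r}_{c}" for r, c in zip(rr.ravel(), cc.ravel())], xs, ys,
        label=[TUMOR if t else NON_TUMOR for t in tumor])

    # image: tissue rectangle of spot cells over a bright background
    side = cfg.image_side
    half = cfg.spacing // 2
    mean_gray = np.full((side, side), cfg.background_gray)
    for x, y, t in zip(xs, ys, tumor):
        gray = cfg.tissue_gray - (cfg.intensity_contrast if t else 0.0)
        mean_gray[max(y - half, 0): y + half, max(x - half, 0): x + half] = gray
    noisy = mean_gray + rng.normal(0.0, cfg.pixel_noise_sd, size=mean_gray.shape)
    image = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    image = np.stack([image] * 3, axis=-1)

    # expression: log-normal base + marker shift in tumor spots + noise
    g = rows * cols
    log_y = mu[None, :] + np.outer(tumor.astype(float), beta)
    if cfg.noise_sd > 0:
        log_y = log_y + rng.normal(0.0, cfg.noise_sd, size=(g, cfg.n_genes))
    values = np.exp(log_y)
    # one pass of neighbor mixing over the adjacency the models will use
    w = cfg.spatial_autocorrelation
    if w > 0:
        adj = build_adjacency(spots, cfg.adjacency_threshold)
        deg = adj.entries.sum(axis=1, keepdims=True)
        neighbor_mean = np.divide(adj.entries @ values, deg,
                                  out=values.copy(), where=deg > 0)
        values = (1.0 - w) * values + w * neighbor_mean
    expr = ExpressionMatrix(values=values, gene_ids=gene_ids(cfg),
                            spot_ids=list(spots["spot_id"]))

    bulk_values = values.mean(axis=0)
    if cfg.bulk_noise_sd > 0:
        bulk_values = bulk_values + rng.normal(0.0, cfg.bulk_noise_sd, size=cfg.n_genes)
    bulk = BulkVector(values=bulk_values, gene_ids=gene_ids(cfg), sample_id=sample_id)
    return SimSample(sample_id=sample_id, image=image, spots=spots, expression=expr,
                     labels=tumor, bulk=bulk,
                     marker_genes=[gene_ids(cfg)[i] for i in sorted(marker_idx)])


def cohort_configs(n_samples: int, cfg: SimConfig) -> list[SimConfig]:
    """Per-sample configs: distinct seeds and varied tumor geometry.

    Tumor disk center and radius vary deterministically per sample so the
    cohort spans a range of tumor fractions, as real cohorts do.
    """
    configs = []
    for i in range(n_samples):
        rng = np.random.default_rng(cfg.seed * 100003 + i)
        if cfg.tumor_region[0] == "disk":
            region = ("disk",
                      float(rng.uniform(0.3, 0.7)),
                      float(rng.uniform(0.3, 0.7)),
                      float(rng.uniform(0.25, 0.42)))
        else:
            region = cfg.tumor_region
        configs.append(replace(cfg, seed=cfg.seed + i, tumor_region=region))
    return configs


def simulate_cohort_samples(n_samples: int, cfg: SimConfig) -> list[SimSample]:
    return [simulate_sample(c, sample_id=f"sample_{i}")
            for i, c in enumerate(cohort_configs(n_samples, cfg))]


def simulate_cohort(n_samples: int, cfg: SimConfig, out_dir: str) -> pd.DataFrame:
    """Write a cohort to disk and return the manifest (also saved as TSV)."""
    os.makedirs(out_dir, exist_ok=True)
    records = []
    for sample in simulate_cohort_samples(n_samples, cfg):
        base = os.path.join(out_dir, sample.sample_id)
        paths = {
            "image": base + "_image.png",
            "spots": base + "_spots.tsv",
            "expression": base + "_expression.tsv",
            "bulk": base + "_bulk.tsv",
        }
        write_image(paths["image"], sample.image)
        write_spot_table(paths["spots"], sample.spots)
        write_expression(paths["expression"], sample.expression)
        write_bulk(paths["bulk"], sample.bulk)
        records.append({"sample_id": sample.sample_id, **paths})
    manifest = pd.DataFrame(records)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    logger.info("wrote %d synthetic samples to %s", n_samples, out_dir)
    return manifest
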