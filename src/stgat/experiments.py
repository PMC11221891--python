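"""End-to-end desk-scale studies on synthetic tissue.

These functions wire the full pipeline together at sizes a laptop CPU can
train in minutes: simulate a cohort, train a stage, and measure recovery of
the planted signal on held-out samples.  They are used both by the test
suite and by ``scripts/acceptance.py``; all randomness flows from the single
``seed`` argument.

Problem sizes (the package's study conditions): cohorts of 8 samples (6
train / 2 held out), 12 x 12 spot grids, 50 genes with 5 tumor markers at a
log-scale effect of 2, tumor/non-tumor patch contrast of 40 gray levels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from dataclasses import asdict, replace

from .evaluation import sample_correlation
from .gep import gep_forward, reduced_gep_config, train_gep
from .nn import serialize_state
from .patching import crop_spot_patches, tile_wsi
from .seg import (
    SegModel,
    embed_spots,
    predict_expression,
    reduced_seg_config,
    train_seg,
)
from .simulate import SimConfig, SimSample, simulate_cohort_samples, simulate_sample
from .slp import (
    classify_spots,
    f1_score,
    reduced_slp_config,
    slp_forward,
    train_slp,
    tumor_average_expression,
)
from .spot_graph import build_adjacency

logger = logging.getLogger(__name__)

N_TRAIN = 6
N_TEST = 2


def st_tuple(sample: SimSample, threshold: float):
    """(PatchStack, AdjacencyMatrix, ExpressionMatrix) for one ST sample."""
    patches = crop_spot_patches(sample.image, sample.spots)
    adj = build_adjacency(sample.spots, threshold)
    return patches, adj, sample.expression


def seg_study(seed: int, epochs: int = 200) -> dict:
    """Train the embedding generator on synthetic ST data, score held-out
    correlation against the planted truth and against an untrained baseline."""
    sim_cfg = SimConfig(seed=seed)
    samples = simulate_cohort_samples(N_TRAIN + N_TEST, sim_cfg)
    tuples = [st_tuple(s, sim_cfg.adjacency_threshold) for s in samples]
    cfg = reduced_seg_config(n_genes=sim_cfg.n_genes, seed=seed, epochs=epochs)
    model = train_seg(tuples[:N_TRAIN], cfg)
    untrained = SegModel(replace(cfg, seed=seed + 777))

    def mean_corr(m: SegModel) -> float:
        rs = []
        for patches, adj, expr in tuples[N_TRAIN:]:
            pred = predict_expression(patches, adj, m, gene_ids=expr.gene_ids)
            rs.append(sample_correlation(pred, expr))
        return float(np.mean(rs))

    corr_trained = mean_corr(model)
    corr_untrained = mean_corr(untrained)
    logger.info("SEG study: held-out r=%.3f (untrained %.3f)",
                corr_trained, corr_untrained)
    return {
        "model": model,
        "sim_config": sim_cfg,
        "corr_trained": corr_trained,
        "corr_untrained": corr_untrained,
        "margin_over_untrained": corr_trained - corr_untrained,
        "n_heldout": N_TEST,
    }


def _wsi_tuple(sample: SimSample, sim_cfg: SimConfig):
    """Tile a synthetic slide (no coordinates used) and map tiles to the
    nearest planted spot for truth lookup."""
    spots, stack = tile_wsi(sample.image, tile_side=sim_cfg.spacing)
    adj = build_adjacency(spots, sim_cfg.adjacency_threshold)
    rows, cols = sim_cfg.grid
    centers_r = (spots["x"].to_numpy() + 0.5) * sim_cfg.spacing
    centers_c = (spots["y"].to_numpy() + 0.5) * sim_cfg.spacing
    nearest_r = np.clip(np.rint((centers_r - sim_cfg.margin) / sim_cfg.spacing
                                ).astype(int), 0, rows - 1)
    nearest_c = np.clip(np.rint((centers_c - sim_cfg.margin) / sim_cfg.spacing
                                ).astype(int), 0, cols - 1)
    truth_rows = nearest_r * cols + nearest_c
    truth = sample.expression.values[truth_rows]
    return stack, adj, sample.bulk, truth


N_TEST_GEP = 10  # the resolution margin is small; average it over 10 slides


def gep_study(seed: int, seg_model: SegModel, epochs: int = 1000) -> dict:
    """Train the bulk-guided predictor on synthetic slides with the frozen
    embedding generator; score bulk reconstruction and per-spot resolution
    on held-out slides (the small resolution margin is averaged over
    ``N_TEST_GEP`` samples)."""
    sim_cfg = SimConfig(seed=seed + 50)
    samples = simulate_cohort_samples(N_TRAIN + N_TEST_GEP, sim_cfg)
    tuples = [_wsi_tuple(s, sim_cfg) for s in samples]
    train_tuples = [(stack, adj, bulk) for stack, adj, bulk, _ in tuples[:N_TRAIN]]
    cfg = reduced_gep_config(n_genes=sim_cfg.n_genes,
                             embed_total=seg_model.config.embed_total,
                             seed=seed, epochs=epochs)
    model = train_gep(train_tuples, seg_model, cfg)

    bulk_rs, spot_rs, bulk_baseline_rs = [], [], []
    for stack, adj, bulk, truth in tuples[N_TRAIN:]:
        e3 = embed_spots(stack, adj, seg_model)
        pred = gep_forward(e3, bulk, model).data
        bulk_rs.append(stats.pearsonr(pred.mean(axis=0), bulk.values).statistic)
        spot_rs.append(stats.pearsonr(pred.ravel(), truth.ravel()).statistic)
        broadcast = np.tile(bulk.values, (truth.shape[0], 1))
        bulk_baseline_rs.append(stats.pearsonr(broadcast.ravel(), truth.ravel()).statistic)
    out = {
        "model": model,
        "bulk_consistency_r": float(np.mean(bulk_rs)),
        "spot_truth_r": float(np.mean(spot_rs)),
        "bulk_baseline_r": float(np.mean(bulk_baseline_rs)),
        "resolution_margin": float(np.mean(spot_rs) - np.mean(bulk_baseline_rs)),
        "n_heldout": N_TEST_GEP,
    }
    logger.info("GEP study: bulk r=%.3f, spot r=%.3f vs baseline %.3f",
                out["bulk_consistency_r"], out["spot_truth_r"], out["bulk_baseline_r"])
    return out


def slp_study(seed: int, epochs: int = 30) -> dict:
    """Train the tumor classifier on synthetic ST patches; score held-out F1
    and the tumor-only average-expression recovery."""
    sim_cfg = SimConfig(seed=seed + 100)
    samples = simulate_cohort_samples(N_TRAIN + N_TEST, sim_cfg)
    train_samples = [(crop_spot_patches(s.image, s.spots), s.labels.astype(int))
                     for s in samples[:N_TRAIN]]
    cfg = reduced_slp_config(seed=seed, epochs=epochs)
    model = train_slp(train_samples, cfg)

    preds, truths = [], []
    mse_pred_mask, mse_all_spots = [], []
    for s in samples[N_TRAIN:]:
        probs = slp_forward(crop_spot_patches(s.image, s.spots), model)
        mask = classify_spots(probs, model.decision_threshold)
        preds.append(mask.astype(int))
        truths.append(s.labels.astype(int))
        planted_tumor_mean = s.expression.values[s.labels].mean(axis=0)
        tumor_avg = tumor_average_expression(s.expression, mask,
                                             fallback_all_spots=True).values
        all_avg = s.expression.values.mean(axis=0)
        mse_pred_mask.append(float(np.mean((tumor_avg - planted_tumor_mean) ** 2)))
        mse_all_spots.append(float(np.mean((all_avg - planted_tumor_mean) ** 2)))
    f1 = f1_score(np.concatenate(preds), np.concatenate(truths))
    out = {
        "model": model,
        "heldout_f1": f1,
        "decision_threshold": model.decision_threshold,
        "tumor_avg_mse_predicted_mask": float(np.mean(mse_pred_mask)),
        "tumor_avg_mse_all_spots": float(np.mean(mse_all_spots)),
        "n_heldout": N_TEST,
    }
    logger.info("SLP study: held-out F1=%.3f; tumor-avg MSE %.4f vs all-spot %.4f",
                f1, out["tumor_avg_mse_predicted_mask"], out["tumor_avg_mse_all_spots"])
    return out


def determinism_study(seed: int) -> dict:
    """Re-run simulation and a short training twice with identical seeds and
    compare the serialized results byte for byte."""
    sim_cfg = SimConfig(grid=(6, 6), seed=seed)
    s1, s2 = simulate_sample(sim_cfg), simulate_sample(sim_cfg)
    sim_identical = (s1.image.tobytes() == s2.image.tobytes()
                     and s1.expression.values.tobytes() == s2.expression.values.tobytes()
                     and s1.bulk.values.tobytes() == s2.bulk.values.tobytes())

    threshold = sim_cfg.adjacency_threshold
    cfg = reduced_seg_config(n_genes=sim_cfg.n_genes, seed=seed, epochs=3)
    blobs = []
    for _ in range(2):
        sample = simulate_sample(sim_cfg)
        model = train_seg([st_tuple(sample, threshold)], cfg)
        blobs.append(serialize_state(model.kind, asdict(model.config), model.params()))
    ckpt_identical = blobs[0] == blobs[1]
    return {
        "simulation_identical": bool(sim_identical),
        "checkpoint_identical": bool(ckpt_identical),
    }
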