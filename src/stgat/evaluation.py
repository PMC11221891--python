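"""Evaluation metrics: per-sample correlation and MSE of predicted spot
expression, AUROC for labels, and marker-gene ranking by Welch t-test among
the highest-variance genes.

The per-sample correlation is the Pearson r over all flattened spot x gene
pairs of one sample (a `per_spot` option emits one r per spot instead).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)


def sample_correlation(pred, truth, per_spot: bool = False):
    """Pearson r between predicted and true expression of one sample."""
    p, t = _values(pred), _values(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if per_spot:
        return np.array([stats.pearsonr(pi, ti).statistic for pi, ti in zip(p, t)])
    return float(stats.pearsonr(p.ravel(), t.ravel()).statistic)


def sample_mse(pred, truth) -> float:
    """Mean squared entrywise difference."""
    p, t = _values(pred), _values(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outranks a random negative.

    Mann-Whitney formulation: ties count one half.
    """
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) != 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def rank_marker_genes(expr: ExpressionMatrix, labels: np.ndarray,
                      top_var: int = 100) -> pd.DataFrame:
    """Rank high-variance genes by tumor/non-tumor differential expression.

    The ``top_var`` genes with the largest variance across spots are tested
    with a two-sided Welch t-test between the two label groups and ordered
    by ascending p-value.  Zero-variance genes inside the selection get
    p = 1 (logged).  A Benjamini-Hochberg FDR column is included for users;
    the ordering uses the raw p-values.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if top_var > expr.n_genes:
        raise ValueError("top_var exceeds the number of genes")
    variances = expr.values.var(axis=0)
    selected = np.sort(np.argsort(variances)[::-1][:top_var])
    tumor = expr.values[labels][:, selected]
    normal = expr.values[~labels][:, selected]
    tstat, pval = stats.ttest_ind(tumor, normal, equal_var=False, axis=0)
    degenerate = ~np.isfinite(pval)
    if degenerate.any():
        logger.warning("%d zero-variance genes in selection; p-value set to 1",
                       int(degenerate.sum()))
        pval = np.where(degenerate, 1.0, pval)
        tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    report = pd.DataFrame({
        "gene_id": [expr.gene_ids[i] for i in selected],
        "variance": variances[selected],
        "t_statistic": tstat,
        "p_value": pval,
        "p_adjusted_bh": multipletests(pval, method="fdr_bh")[1],
    })
    return report.sort_values("p_value", kind="stable").reset_index(drop=True)


def evaluation_report(pairs: list[tuple[str, ExpressionMatrix, ExpressionMatrix]]
                      ) -> pd.DataFrame:
    """One row per sample: flattened-entry correlation and MSE."""
    rows = [{"sample_id": sid,
             "correlation": sample_correlation(pred, truth),
             "mse": sample_mse(pred, truth)}
            for sid, pred, truth in pairs]
    return pd.DataFrame(rows)
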