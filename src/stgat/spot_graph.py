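"""Spatial adjacency of a sample's spots, as consumed by the attention layer.

Each spot's Euclidean distances to all other spots are normalized by that
row's maximum, and an edge i -> j is kept when the normalized distance is
strictly below the threshold.  Because normalization is per row, the
resulting binary matrix may be asymmetric; the attention layer consumes
row-wise neighbor sets, so no symmetrization is applied by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import AdjacencyMatrix, validate_spot_table

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1


def pairwise_distances(spots: pd.DataFrame) -> np.ndarray:
    """Symmetric zero-diagonal matrix of Euclidean distances between spots."""
    validate_spot_table(spots)
    coords = spots[["x", "y"]].to_numpy(dtype=float)
    d = cdist(coords, coords)
    np.fill_diagonal(d, 0.0)
    off_diag_zero = (d == 0).sum() - len(spots)
    if off_diag_zero > 0:
        logger.warning("%d spot pairs share identical coordinates", off_diag_zero // 2)
    return d


def build_adjacency(spots: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                    symmetrize: bool = False) -> AdjacencyMatrix:
    """Binary adjacency from row-normalized distances.

    For each spot the distance row is divided by its maximum; entries with a
    normalized distance strictly below ``threshold`` become neighbors.  The
    diagonal is forced to zero.  With ``symmetrize=True`` the matrix is OR-ed
    with its transpose.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    d = pairwise_distances(spots)
    g = d.shape[0]
    logger.info("building adjacency for %d spots at threshold %g", g, threshold)
    if g == 1:
        logger.warning("single spot: empty adjacency")
        return AdjacencyMatrix(entries=np.zeros((1, 1), dtype=np.uint8),
                               threshold=threshold)
    row_max = d.max(axis=1, keepdims=True)
    row_max[row_max == 0] = 1.0  # all spots coincident: no edges either way
    normalized = d / row_max
    entries = (normalized < threshold).astype(np.uint8)
    np.fill_diagonal(entries, 0)
    if symmetrize:
        entries = np.maximum(entries, entries.T)
    isolated = int((entries.sum(axis=1) == 0).sum())
    if isolated:
        logger.info("%d spots have no neighbors", isolated)
    return AdjacencyMatrix(entries=entries, threshold=threshold)
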