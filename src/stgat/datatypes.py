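"""Shared containers: spot tables, patch stacks, expression matrices.

A spot table is a pandas DataFrame with columns ``spot_id``, ``x``, ``y`` and
an optional ``label`` column (``tumor`` / ``non_tumor``).  ``x`` is the column
(horizontal) pixel coordinate and ``y`` the row (vertical) one; for tiled
whole-slide images they instead hold integer tile indices (row, column).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SPOT_COLUMNS = ["spot_id", "x", "y"]
TUMOR = "tumor"
NON_TUMOR = "non_tumor"


def validate_spot_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a spot table and return it unchanged."""
    for col in SPOT_COLUMNS:
        if col not in spots.columns:
            raise ValueError(f"spot table missing column {col!r}")
    if spots["spot_id"].duplicated().any():
        dup = spots.loc[spots["spot_id"].duplicated(), "spot_id"].iloc[0]
        raise ValueError(f"duplicate spot_id {dup!r}")
    if (spots["x"] < 0).any() or (spots["y"] < 0).any():
        raise ValueError("spot coordinates must be non-negative")
    if "label" in spots.columns:
        bad = set(spots["label"].dropna()) - {TUMOR, NON_TUMOR}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
    return spots


def make_spot_table(spot_ids, x, y, label=None) -> pd.DataFrame:
    data = {"spot_id": list(spot_ids), "x": np.asarray(x, dtype=int), "y": np.asarray(y, dtype=int)}
    if label is not None:
        data["label"] = list(label)
    return validate_spot_table(pd.DataFrame(data))


@dataclass
class PatchStack:
    """Ordered stack of square RGB patches aligned with a spot table."""

    patches: np.ndarray  # (g, side, side, 3) uint8
    side: int

    def __post_init__(self):
        self.patches = np.asarray(self.patches)
        if self.patches.ndim != 4 or self.patches.shape[3] != 3:
            raise ValueError("patches must have shape (g, side, side, 3)")
        if self.patches.shape[1] != self.side or self.patches.shape[2] != self.side:
            raise ValueError("patch dimensions disagree with declared side")

    def __len__(self):
        return self.patches.shape[0]


@dataclass
class ExpressionMatrix:
    """Spots-by-genes expression values with a fixed gene order."""

    values: np.ndarray  # (g, p)
    gene_ids: list[str]
    spot_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (spots x genes)")
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length disagrees with value columns")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def n_spots(self):
        return self.values.shape[0]

    @property
    def n_genes(self):
        return self.values.shape[1]


@dataclass
class BulkVector:
    """One bulk RNA-seq profile; gene order matches the expression matrices."""

    values: np.ndarray  # (p,)
    gene_ids: list[str]
    sample_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length disagrees with bulk values")
        if not np.isfinite(self.values).all():
            raise ValueError("bulk values must be finite")


@dataclass
class AdjacencyMatrix:
    """Binary, zero-diagonal neighbor structure; may be asymmetric."""

    entries: np.ndarray  # (g, g) in {0, 1}
    threshold: float

    def __post_init__(self):
        self.entries = np.asarray(self.entries)
        g = self.entries.shape[0]
        if self.entries.shape != (g, g):
            raise ValueError("adjacency must be square")
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("adjacency entries must be binary")
        if np.diagonal(self.entries).any():
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_spots(self):
        return self.entries.shape[0]

    def neighbor_sets(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.entries]


def intersect_genes(*gene_lists: list[str]) -> list[str]:
    """Exact-name gene intersection, ordered as in the first list."""
    common = set(gene_lists[0])
    for gl in gene_lists[1:]:
        common &= set(gl)
    return [g for g in gene_lists[0] if g in common]
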