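"""Readers and writers for the plain-text/PNG formats used across the package.

Spot tables, expression matrices, bulk vectors, adjacency edge lists and
cohort manifests are all TSV; images are PNG or TIFF read through imageio.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .datatypes import (
    AdjacencyMatrix,
    BulkVector,
    ExpressionMatrix,
    PatchStack,
    validate_spot_table,
)


def read_image(path: str) -> np.ndarray:
    """Read a PNG/TIFF image as an H x W x 3 uint8 array."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return img.astype(np.uint8)


def write_image(path: str, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_spot_table(path: str) -> pd.DataFrame:
    spots = pd.read_csv(path, sep="\t", dtype={"spot_id": str})
    return validate_spot_table(spots)


def write_spot_table(path: str, spots: pd.DataFrame) -> None:
    validate_spot_table(spots).to_csv(path, sep="\t", index=False)


def read_expression(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=list(df.columns),
        spot_ids=[str(s) for s in df.index],
    )


def write_expression(path: str, expr: ExpressionMatrix) -> None:
    index = expr.spot_ids if expr.spot_ids is not None else range(expr.n_spots)
    df = pd.DataFrame(expr.values, index=index, columns=expr.gene_ids)
    df.index.name = "spot_id"
    df.to_csv(path, sep="\t")


def read_bulk(path: str, sample_id: str = "") -> BulkVector:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "value"]:
        raise ValueError("bulk TSV must have columns gene_id, value")
    return BulkVector(values=df["value"].to_numpy(dtype=float),
                      gene_ids=[str(g) for g in df["gene_id"]],
                      sample_id=sample_id or os.path.splitext(os.path.basename(path))[0])


def write_bulk(path: str, bulk: BulkVector) -> None:
    pd.DataFrame({"gene_id": bulk.gene_ids, "value": bulk.values}).to_csv(
        path, sep="\t", index=False
    )


def write_adjacency(path: str, adj: AdjacencyMatrix, spot_ids: list[str]) -> None:
    src, dst = np.nonzero(adj.entries)
    pd.DataFrame({"src": [spot_ids[i] for i in src],
                  "dst": [spot_ids[j] for j in dst]}).to_csv(path, sep="\t", index=False)


def read_adjacency(path: str, spot_ids: list[str], threshold: float) -> AdjacencyMatrix:
    edges = pd.read_csv(path, sep="\t", dtype=str)
    index = {s: i for i, s in enumerate(spot_ids)}
    g = len(spot_ids)
    entries = np.zeros((g, g), dtype=np.uint8)
    for s, d in zip(edges["src"], edges["dst"]):
        entries[index[s], index[d]] = 1
    return AdjacencyMatrix(entries=entries, threshold=threshold)


def write_patch_stack(out_dir: str, stack: PatchStack, spots: pd.DataFrame) -> None:
    """Persist patches as `{spot_id}.png` plus the TSV manifest."""
    os.makedirs(out_dir, exist_ok=True)
    write_spot_table(os.path.join(out_dir, "spots.tsv"), spots)
    for patch, spot_id in zip(stack.patches, spots["spot_id"]):
        write_image(os.path.join(out_dir, f"{spot_id}.png"), patch)


def read_patch_stack(in_dir: str) -> tuple[pd.DataFrame, PatchStack]:
    spots = read_spot_table(os.path.join(in_dir, "spots.tsv"))
    patches = np.stack([read_image(os.path.join(in_dir, f"{s}.png"))
                        for s in spots["spot_id"]])
    return spots, PatchStack(patches=patches, side=patches.shape[1])
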