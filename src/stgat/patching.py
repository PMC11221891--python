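"""Spot-image extraction from histology images.

Two regimes are supported:

* spatial-transcriptomics samples carry per-spot pixel coordinates, and a
  fixed window centered on each spot is cropped (`crop_spot_patches`);
* whole-slide images lack coordinates, so the slide is tiled on a regular
  grid, background tiles are dropped by a brightness rule, and the surviving
  tiles are resized to the working patch size (`tile_wsi`).

Conventions (recorded once here, relied on everywhere): crop windows are
half-open ``[x - half_side, x + half_side) x [y - half_side, y + half_side)``
in 0-based pixel indices, so ``half_side=112`` yields exactly 224 x 224
patches; a pixel counts as foreground when the arithmetic mean of its three
channel values is strictly below ``rgb_threshold``; a tile is kept when its
foreground fraction is at least ``min_fg_fraction`` (a tie at exactly half
keeps the tile); trailing partial tiles are discarded; a kept tile's (row,
column) indices become its (x, y) coordinates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import PatchStack, make_spot_table, validate_spot_table

logger = logging.getLogger(__name__)

DEFAULT_HALF_SIDE = 112
DEFAULT_TILE_SIDE = 512
DEFAULT_RGB_THRESHOLD = 220
DEFAULT_MIN_FG_FRACTION = 0.5
WORKING_SIDE = 224


def crop_spot_patches(image: np.ndarray, spots: pd.DataFrame,
                      half_side: int = DEFAULT_HALF_SIDE) -> PatchStack:
    """Crop one ``2*half_side``-sided patch centered on each spot.

    Raises ``ValueError`` naming the first spot whose window leaves the image
    bounds; no silent clamping is performed.
    """
    if half_side < 1:
        raise ValueError("half_side must be >= 1")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    validate_spot_table(spots)
    h, w, _ = image.shape
    patches = np.empty((len(spots), 2 * half_side, 2 * half_side, 3), dtype=image.dtype)
    for i, (spot_id, x, y) in enumerate(zip(spots["spot_id"], spots["x"], spots["y"])):
        x0, x1 = int(x) - half_side, int(x) + half_side
        y0, y1 = int(y) - half_side, int(y) + half_side
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise ValueError(
                f"spot {spot_id!r}: crop window cols [{x0},{x1}) x rows [{y0},{y1}) "
                f"exceeds image bounds {h}x{w}"
            )
        patches[i] = image[y0:y1, x0:x1]
    return PatchStack(patches=patches, side=2 * half_side)


def tile_wsi(image: np.ndarray, tile_side: int = DEFAULT_TILE_SIDE,
             rgb_threshold: float = DEFAULT_RGB_THRESHOLD,
             min_fg_fraction: float = DEFAULT_MIN_FG_FRACTION,
             working_side: int = WORKING_SIDE) -> tuple[pd.DataFrame, PatchStack]:
    """Tile a coordinate-free slide and keep tissue tiles.

    Tiles are scanned row-major from (0, 0); a tile is valid iff the number
    of pixels whose channel mean is below ``rgb_threshold`` is at least
    ``min_fg_fraction * tile_side**2``.  Valid tiles are resized to
    ``working_side`` and their (row, column) tile indices recorded as (x, y).
    """
    if tile_side < 2:
        raise ValueError("tile_side must be >= 2")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    h, w, _ = image.shape
    n_rows, n_cols = h // tile_side, w // tile_side
    if n_rows == 0 or n_cols == 0:
        logger.warning("image %dx%d smaller than one %d tile; empty result",
                       h, w, tile_side)
        empty = make_spot_table([], [], [])
        return empty, PatchStack(
            patches=np.empty((0, working_side, working_side, 3), dtype=image.dtype),
            side=working_side)

    cropped = image[: n_rows * tile_side, : n_cols * tile_side]
    fg = cropped.mean(axis=2) < rgb_threshold
    fg_counts = fg.reshape(n_rows, tile_side, n_cols, tile_side).sum(axis=(1, 3))
    valid = fg_counts >= min_fg_fraction * tile_side**2

    ids, xs, ys, patches = [], [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            if not valid[r, c]:
                continue
            tile = cropped[r * tile_side:(r + 1) * tile_side,
                           c * tile_side:(c + 1) * tile_side]
            patches.append(resize_patch(tile, working_side))
            ids.append(f"tile_{r}_{c}")
            xs.append(r)
            ys.append(c)
    logger.info("tiling: %d candidates, %d valid, %d background",
                n_rows * n_cols, len(ids), n_rows * n_cols - len(ids))
    spots = make_spot_table(ids, xs, ys)
    if patches:
        stack = PatchStack(patches=np.stack(patches), side=working_side)
    else:
        stack = PatchStack(
            patches=np.empty((0, working_side, working_side, 3), dtype=image.dtype),
            side=working_side)
    return spots, stack


def resize_patch(patch: np.ndarray, target_side: int) -> np.ndarray:
    """Bilinear resize of a square RGB patch (half-pixel center alignment).

    The interpolation method is fixed (bilinear) and logged; a non-square
    input is an error.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"resize_patch expects a square patch, got {patch.shape}")
    side = patch.shape[0]
    if side == target_side:
        return patch.copy()
    logger.debug("resize %d -> %d (bilinear)", side, target_side)
    scale = side / target_side
    # source coordinates of the output pixel centers, clamped to the edges
    coords = (np.arange(target_side) + 0.5) * scale - 0.5
    lo = np.clip(np.floor(coords).astype(int), 0, side - 1)
    hi = np.clip(lo + 1, 0, side - 1)
    frac = np.clip(coords - lo, 0.0, 1.0)

    vals = patch.astype(np.float64)
    top = vals[lo][:, lo] * (1 - frac[None, :, None]) + vals[lo][:, hi] * frac[None, :, None]
    bot = vals[hi][:, lo] * (1 - frac[None, :, None]) + vals[hi][:, hi] * frac[None, :, None]
    out = top * (1 - frac[:, None, None]) + bot * frac[:, None, None]
    if np.issubdtype(patch.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(patch.dtype)
    return out.astype(patch.dtype)
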