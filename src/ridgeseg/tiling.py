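"""Tiled inference over arbitrarily large rasters.

A large aerial image is zero-padded on the right/bottom to the next
multiple of the tile size, cut into a rows x cols grid of non-overlapping
tiles (row-major, 0-based), each tile is segmented independently, and the
per-tile masks are spliced back and cropped to the original extent. No
overlap or seam blending is applied — plain splicing is the point of the
pipeline's simplicity.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["TileGrid", "Tile", "split_image", "stitch", "segment_large"]


@dataclass(frozen=True)
class TileGrid:
    """Geometry binding a raster to its rows x cols grid of square tiles."""

    original_height: int
    original_width: int
    tile_size: int

    @property
    def n_rows(self) -> int:
        return -(-self.original_height // self.tile_size)  # ceil division

    @property
    def n_cols(self) -> int:
        return -(-self.original_width // self.tile_size)

    @property
    def padded_height(self) -> int:
        return self.n_rows * self.tile_size

    @property
    def padded_width(self) -> int:
        return self.n_cols * self.tile_size

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def window(self, index: int) -> tuple[int, int, tuple[int, int, int, int]]:
        """(row, col, (y0, y1, x0, x1)) half-open pixel window of one tile."""
        if not 0 <= index < self.n_tiles:
            raise IndexError(f"tile index {index} out of range [0, {self.n_tiles})")
        r, c = divmod(index, self.n_cols)
        ts = self.tile_size
        return r, c, (r * ts, (r + 1) * ts, c * ts, (c + 1) * ts)


@dataclass
class Tile:
    """One grid cell's data, tagged with its index so stitching can audit order."""

    index: int
    row: int
    col: int
    data: np.ndarray

    def with_data(self, data: np.ndarray) -> "Tile":
        return Tile(self.index, self.row, self.col, data)


def split_image(img: np.ndarray, tile_size: int = 512) -> tuple[TileGrid, list[Tile]]:
    """Zero-pad ``img`` to tile multiples and cut it row-major into tiles."""
    if tile_size < 1:
        raise ValueError("tile_size must be at least 1")
    img = np.asarray(img)
    if img.ndim not in (2, 3) or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected a non-empty HxW or HxWxC raster, got shape {img.shape}")
    grid = TileGrid(img.shape[0], img.shape[1], tile_size)
    pad = [(0, grid.padded_height - img.shape[0]), (0, grid.padded_width - img.shape[1])]
    if img.ndim == 3:
        pad.append((0, 0))
    padded = np.pad(img, pad)
    tiles = []
    for i in range(grid.n_tiles):
        r, c, (y0, y1, x0, x1) = grid.window(i)
        tiles.append(Tile(i, r, c, padded[y0:y1, x0:x1]))
    return grid, tiles


def stitch(grid: TileGrid, tile_masks: list[Tile]) -> np.ndarray:
    """Reassemble per-tile masks row-major and crop to the original extent."""
    if len(tile_masks) != grid.n_tiles:
        raise ValueError(f"expected {grid.n_tiles} tiles, got {len(tile_masks)}")
    ts = grid.tile_size
    first = tile_masks[0].data
    out = np.zeros((grid.padded_height, grid.padded_width) + first.shape[2:],
                   dtype=first.dtype)
    for pos, t in enumerate(tile_masks):
        if t.index != pos:
            raise ValueError(f"tile order violated at position {pos}: "
                             f"found tile index {t.index}")
        r, c, (y0, y1, x0, x1) = grid.window(pos)
        if (t.row, t.col) != (r, c):
            raise ValueError(f"tile {pos} carries grid position {(t.row, t.col)}, "
                             f"expected {(r, c)}")
        if t.data.shape[:2] != (ts, ts):
            raise ValueError(f"tile {pos} has shape {t.data.shape[:2]}, "
                             f"expected {(ts, ts)}")
        out[y0:y1, x0:x1] = t.data
    return out[:grid.original_height, :grid.original_width]


def segment_large(img: np.ndarray, model, tile_size: int = 512) -> np.ndarray:
    """Segment an arbitrarily large RGB raster: split, predict per tile, stitch."""
    t0 = time.perf_counter()
    grid, tiles = split_image(img, tile_size)
    t1 = time.perf_counter()
    logger.info("split %dx%d raster into %dx%d grid (%d tiles) in %.3fs",
                grid.original_height, grid.original_width,
                grid.n_rows, grid.n_cols, grid.n_tiles, t1 - t0)
    masks = [t.with_data(model.predict(t.data)) for t in tiles]
    t2 = time.perf_counter()
    logger.info("segmented %d tiles in %.3fs (%.3fs/tile)",
                len(masks), t2 - t1, (t2 - t1) / max(len(masks), 1))
    out = stitch(grid, masks)
    logger.info("stitched result %s in %.3fs", out.shape, time.perf_counter() - t2)
    return out
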