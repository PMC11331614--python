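"""Tile enumeration and extraction from whole-slide images.

Slides are cut into 256 px tiles at a target resolution of 0.5 µm/px with a
50% overlap between adjacent tiles (stride = 128 px at the target scale).
Slides scanned at a finer resolution (commonly 0.25 µm/px) are read through a
proportionally larger level-0 window and downscaled by area averaging.

Coordinates are 0-based, half-open, and always expressed in level-0 pixels.
Edge strips narrower than one tile are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

TILE_PX = 256
TARGET_MPP = 0.5


@dataclass
class TileGrid:
    """Tile coordinate grid for one slide, in level-0 pixels."""

    slide_id: str
    width_px: int
    height_px: int
    source_mpp: float = TARGET_MPP
    target_mpp: float = TARGET_MPP
    tile_px: int = TILE_PX
    stride_px: int = TILE_PX // 2
    coords: np.ndarray = field(default=None)  # (n, 2) int64 (x, y), row-major

    def __post_init__(self):
        if self.coords is None:
            scale = self.scale_factor
            tile0 = int(round(self.tile_px * scale))
            stride0 = int(round(self.stride_px * scale))
            self.coords = enumerate_tiles(self.width_px, self.height_px, tile0, stride0)

    @property
    def scale_factor(self) -> float:
        """Level-0 pixels per output pixel (≥ 1 when the scan is finer than the target)."""
        return self.target_mpp / self.source_mpp

    @property
    def tile_px_level0(self) -> int:
        return int(round(self.tile_px * self.scale_factor))

    def __len__(self):
        return len(self.coords)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"slide_id": self.slide_id, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )


def enumerate_tiles(width_px: int, height_px: int, tile_px: int = TILE_PX, stride_px: int = TILE_PX // 2) -> np.ndarray:
    """Enumerate all fully-contained tile positions on a regular stride grid.

    Returns an (n, 2) array of (x, y) top-left corners in row-major order;
    n = (⌊(W − tile)/stride⌋ + 1) · (⌊(H − tile)/stride⌋ + 1) when both
    dimensions fit at least one tile, else 0 (with a warning).
    """
    if tile_px <= 0 or stride_px <= 0:
        raise ValueError("tile_px and stride_px must be positive")
    if width_px < tile_px or height_px < tile_px:
        warnings.warn(
            f"slide {width_px}x{height_px} smaller than tile {tile_px}; empty grid",
            stacklevel=2,
        )
        return np.empty((0, 2), dtype=np.int64)
    xs = np.arange(0, width_px - tile_px + 1, stride_px, dtype=np.int64)
    ys = np.arange(0, height_px - tile_px + 1, stride_px, dtype=np.int64)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def open_slide(source) -> np.ndarray:
    """Load a slide as an (H, W, 3) uint8 array.

    Accepts an array, a PIL image, or a path to a PNG/TIFF file. Pyramidal
    TIFFs are read at their base level; MIRAX is unsupported.
    """
    if isinstance(source, np.ndarray):
        arr = source
    elif isinstance(source, Image.Image):
        arr = np.asarray(source.convert("RGB"))
    else:
        path = str(source)
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected an RGB slide, got shape {arr.shape}")
    return np.ascontiguousarray(arr[:, :, :3]).astype(np.uint8, copy=False)


def read_tile(slide, coord, scale_factor: float = 1.0, tile_px: int = TILE_PX) -> np.ndarray:
    """Extract one tile at a level-0 coordinate, downscaling to ``tile_px``.

    The level-0 window spans ``round(tile_px * scale_factor)`` pixels; integer
    scale factors are reduced by exact area averaging, non-integer factors by
    anti-aliased resampling of the nearest integer-sized window.
    """
    arr = open_slide(slide)
    x, y = int(coord[0]), int(coord[1])
    win = int(round(tile_px * scale_factor))
    if x < 0 or y < 0 or x + win > arr.shape[1] or y + win > arr.shape[0]:
        raise ValueError(f"tile footprint ({x},{y})+{win} outside slide {arr.shape[1]}x{arr.shape[0]}")
    patch = arr[y : y + win, x : x + win].astype(np.float64)
    if win == tile_px:
        out = patch
    elif win % tile_px == 0:
        f = win // tile_px
        out = patch.reshape(tile_px, f, tile_px, f, 3).mean(axis=(1, 3))
    else:
        out = resize(patch, (tile_px, tile_px, 3), anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def extract_tiles(slide, grid: TileGrid):
    """Yield (coord, tile) pairs for every position of a grid."""
    arr = open_slide(slide)
    for coord in grid.coords:
        yield tuple(coord), read_tile(arr, coord, grid.scale_factor, grid.tile_px)
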