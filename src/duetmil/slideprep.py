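"""Whole-slide preprocessing: tissue segmentation, control-region exclusion,
tessellation into fixed-size tiles, and capped random tile sampling.

Coordinates are 0-based with a top-left origin; tile boxes are half-open
``[x0, x0+w) x [y0, y0+h)``. The tessellation grid is anchored at (0, 0) with
stride equal to the tile size, so tiles from one tessellation are pairwise
disjoint and partial edge tiles are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import color, filters, morphology

TILE_SIZE = 224  # pixels at ~1.0 micron/pixel (x10 magnification)
MAX_TRAIN_TILES = 500  # per-slide cap used during training and validation


@dataclass(frozen=True)
class TileBox:
    """Axis-aligned tile footprint in slide pixel coordinates."""

    x0: int
    y0: int
    width: int = TILE_SIZE
    height: int = TILE_SIZE
    level: str = "10x"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("tile box must have positive extent")

    def as_array(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.width, self.height], dtype=np.int64)


@dataclass
class TissueMask:
    """Binary tissue mask at a (possibly) downsampled resolution.

    ``grid`` has shape (H, W); the slide it describes spans
    ``H * downsample`` by ``W * downsample`` pixels.
    """

    grid: np.ndarray
    downsample: int = 1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    @property
    def slide_shape(self) -> tuple[int, int]:
        return (self.grid.shape[0] * self.downsample, self.grid.shape[1] * self.downsample)

    def copy(self) -> "TissueMask":
        return TissueMask(self.grid.copy(), self.downsample)


def segment_tissue(image: np.ndarray, min_object_px: int = 64) -> TissueMask:
    """Segment tissue from a white background on an RGB slide image.

    Thresholds the HSV saturation channel with Otsu's method and removes
    connected components smaller than ``min_object_px``. Stained tissue
    (pink/brown) is saturated; glass background is near-white with
    saturation ~0. Deterministic. Degenerate (constant-saturation) images
    resolve by comparing saturation against a fixed 0.1 cutoff so that a
    blank slide yields an empty mask and a uniformly stained field a full one.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    sat = color.rgb2hsv(image)[:, :, 1]
    if float(sat.max() - sat.min()) < 1e-6:
        mask = np.full(sat.shape, sat.mean() > 0.1, dtype=bool)
        return TissueMask(mask, downsample=1)
    thr = filters.threshold_otsu(sat)
    mask = sat > thr
    # drops connected components strictly smaller than min_object_px
    mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    return TissueMask(mask, downsample=1)


def exclude_regions(mask: TissueMask, regions: Sequence[TileBox]) -> TissueMask:
    """Zero the mask inside each region (e.g. detected control-tissue cores).

    Regions are given in slide pixel coordinates and must lie within the
    slide bounds. Idempotent; overlapping regions behave as their union.
    """
    out = mask.copy()
    h, w = mask.slide_shape
    ds = mask.downsample
    for r in regions:
        if r.x0 < 0 or r.y0 < 0 or r.x0 + r.width > w or r.y0 + r.height > h:
            raise ValueError(f"region {r} outside slide bounds {(h, w)}")
        y0, y1 = r.y0 // ds, -(-(r.y0 + r.height) // ds)
        x0, x1 = r.x0 // ds, -(-(r.x0 + r.width) // ds)
        out.grid[y0:y1, x0:x1] = False
    return out


def tessellate(
    mask: TissueMask, tile_size: int = TILE_SIZE, min_coverage: float = 0.5
) -> list[TileBox]:
    """Grid-aligned tessellation of the masked slide into square tiles.

    A tile is kept iff the fraction of masked pixels under its footprint is
    at least ``min_coverage``. The grid starts at (0, 0) with stride
    ``tile_size``; remainders at the right/bottom edges are dropped.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not (0.0 < min_coverage <= 1.0):
        raise ValueError("min_coverage must be in (0, 1]")
    ds = mask.downsample
    if tile_size % ds != 0:
        raise ValueError("tile_size must be a multiple of the mask downsample")
    h, w = mask.slide_shape
    if h < tile_size or w < tile_size:
        raise ValueError("mask smaller than one tile")
    step = tile_size // ds
    ny, nx = mask.grid.shape[0] // step, mask.grid.shape[1] // step
    # block means via a single reshape: coverage of each step x step cell
    cropped = mask.grid[: ny * step, : nx * step].astype(np.float64)
    cover = cropped.reshape(ny, step, nx, step).mean(axis=(1, 3))
    keep = np.argwhere(cover >= min_coverage - 1e-12)
    return [TileBox(int(x * tile_size), int(y * tile_size), tile_size, tile_size) for y, x in keep]


def sample_tiles(
    n_tiles: int, max_n: int = MAX_TRAIN_TILES, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Random without-replacement subset of tile indices, capped at ``max_n``.

    Mirrors the training/validation-time cap on tiles per slide: if the slide
    has at most ``max_n`` tiles all indices are returned, otherwise a uniform
    subset of size ``max_n`` (sorted, for stable downstream indexing).
    Test-time inference uses all tiles and never calls this.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if n_tiles <= max_n:
        return np.arange(n_tiles)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.sort(rng.choice(n_tiles, size=max_n, replace=False))
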