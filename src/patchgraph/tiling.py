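"""Slide tiling and background filtering.

A whole-slide image (or any RGB raster standing in for one) is divided into
fixed-size patches on a regular grid; patches that are mostly background are
discarded.  The surviving patches, their integer ``(row, col)`` grid
coordinates and their tissue fractions form a :class:`PatchGrid` — the bag of
tissue tiles every downstream stage (feature extraction, graph construction,
heatmap reconstruction) is indexed against.

Background is decided per pixel by a brightness/saturation heuristic suited to
H&E-stained tissue: a pixel is background when it is near-white
(``min(R,G,B) >= 220``) or nearly achromatic (``max-min <= 15``).  Both
thresholds are overridable.  A patch is discarded when its non-tissue area
exceeds ``background_max`` (default 0.5, strict inequality: exactly half
background is kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SlideImage",
    "PatchGrid",
    "tile_slide",
    "tissue_fraction",
    "filter_background",
    "load_slide",
]

#: near-white brightness threshold for the background rule
WHITE_MIN = 220
#: maximum channel spread (saturation proxy) for the background rule
SATURATION_MAX = 15


@dataclass
class SlideImage:
    """An RGB raster at working magnification plus identifying metadata."""

    slide_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    magnification_tag: str = "20x"
    pixel_spacing: float | None = None  # microns per pixel, if known

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide pixels must be an (H, W, 3) RGB array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("slide pixels must be 8-bit")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class PatchGrid:
    """Kept patches of one slide with grid coordinates and tissue fractions."""

    slide_id: str
    patch_size: int
    coords: list[tuple[int, int]]
    patches: list[np.ndarray]
    tissue_fractions: list[float]
    slide_shape: tuple[int, int] = (0, 0)  # (H, W) of the source raster
    stride: int = 0

    def __post_init__(self):
        n = len(self.coords)
        if not (len(self.patches) == len(self.tissue_fractions) == n):
            raise ValueError("coords, patches and tissue_fractions must align")
        if n < 1:
            raise ValueError("a PatchGrid needs at least one patch")
        if len(set(self.coords)) != n:
            raise ValueError("duplicate grid coordinates")
        if self.stride == 0:
            self.stride = self.patch_size

    def __len__(self):
        return len(self.coords)

    def manifest(self):
        """Rows of (slide_id, row, col, tissue_fraction) for the TSV manifest."""
        return [
            (self.slide_id, r, c, tf)
            for (r, c), tf in zip(self.coords, self.tissue_fractions)
        ]


def load_slide(path: str | Path, slide_id: str | None = None) -> SlideImage:
    """Read an RGB PNG/TIFF raster into a :class:`SlideImage`.

    The raster is treated as already being at working magnification; callers
    with pyramidal sources should extract the desired level first.
    """
    from PIL import Image

    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return SlideImage(slide_id=slide_id or path.stem, pixels=arr)


def tile_slide(
    slide: SlideImage, patch_size: int, overlap_fraction: float = 0.0
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Cut the slide into a regular grid of ``patch_size`` tiles.

    ``stride = round(patch_size * (1 - overlap_fraction))``; border tiles that
    do not fit a full patch are dropped.  Returns row-major
    ``((row, col), patch)`` pairs with 0-based grid indices.
    """
    if patch_size < 16:
        raise ValueError("patch_size must be >= 16")
    if not (0.0 <= overlap_fraction < 0.5):
        raise ValueError("overlap_fraction must lie in [0, 0.5)")
    H, W = slide.pixels.shape[:2]
    if H < patch_size or W < patch_size:
        raise ValueError("slide too small")
    stride = int(round(patch_size * (1.0 - overlap_fraction)))
    n_rows = (H - patch_size) // stride + 1
    n_cols = (W - patch_size) // stride + 1
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            y, x = r * stride, c * stride
            tiles.append(((r, c), slide.pixels[y : y + patch_size, x : x + patch_size]))
    return tiles


def background_mask(
    patch: np.ndarray, white_min: int = WHITE_MIN, saturation_max: int = SATURATION_MAX
) -> np.ndarray:
    """Boolean per-pixel background mask under the brightness/saturation rule."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3 or patch.dtype != np.uint8:
        raise ValueError("patch must be an 8-bit RGB array")
    lo = patch.min(axis=2).astype(np.int16)
    hi = patch.max(axis=2).astype(np.int16)
    return (lo >= white_min) | ((hi - lo) <= saturation_max)


def tissue_fraction(
    patch: np.ndarray, white_min: int = WHITE_MIN, saturation_max: int = SATURATION_MAX
) -> float:
    """Fraction of pixels classified as tissue, in [0, 1]."""
    return float(1.0 - background_mask(patch, white_min, saturation_max).mean())


def filter_background(
    tiles: list[tuple[tuple[int, int], np.ndarray]],
    background_max: float = 0.5,
    slide_id: str = "",
    patch_size: int | None = None,
    slide_shape: tuple[int, int] = (0, 0),
    stride: int = 0,
    white_min: int = WHITE_MIN,
    saturation_max: int = SATURATION_MAX,
) -> PatchGrid:
    """Keep the tiles whose non-tissue area does not exceed ``background_max``.

    The inequality is strict on the discard side: a tile with non-tissue
    fraction exactly equal to ``background_max`` is kept.  Idempotent, order
    preserving; raises if nothing survives.
    """
    if not tiles:
        raise ValueError("no tiles to filter")
    if patch_size is None:
        patch_size = tiles[0][1].shape[0]
    coords, patches, fractions = [], [], []
    for coord, patch in tiles:
        tf = tissue_fraction(patch, white_min, saturation_max)
        if (1.0 - tf) <= background_max + 1e-12:
            coords.append(tuple(coord))
            patches.append(patch)
            fractions.append(tf)
    if not coords:
        raise ValueError("no tissue patches")
    return PatchGrid(
        slide_id=slide_id,
        patch_size=patch_size,
        coords=coords,
        patches=patches,
        tissue_fractions=fractions,
        slide_shape=slide_shape,
        stride=stride,
    )


def tile_and_filter(
    slide: SlideImage,
    patch_size: int,
    overlap_fraction: float = 0.0,
    background_max: float = 0.5,
) -> PatchGrid:
    """Convenience: :func:`tile_slide` followed by :func:`filter_background`."""
    tiles = tile_slide(slide, patch_size, overlap_fraction)
    stride = int(round(patch_size * (1.0 - overlap_fraction)))
    return filter_background(
        tiles,
        background_max=background_max,
        slide_id=slide.slide_id,
        patch_size=patch_size,
        slide_shape=slide.pixels.shape[:2],
        stride=stride,
    )
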