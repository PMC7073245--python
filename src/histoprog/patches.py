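"""Random crop sampling from slide images and crop-coverage accounting.

Crops are sampled with replacement over valid top-left origins (uniform),
optionally rejecting crops whose tissue fraction — the share of pixels with
mean optical density above a threshold — falls below ``min_tissue_fraction``.
Rejection redraws up to a fixed attempt budget and then keeps the best crop
seen, with a warning, so degenerate (mostly background) images still yield
the requested number of crops. Coordinates are 0-based, row-major, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CropSizeError, ParameterError
from .image_io import SlideImage
from .stain import rgb_to_od

__all__ = ["Crop", "tissue_fraction", "sample_crops", "crop_coverage_percent"]

_MAX_ATTEMPTS = 100


@dataclass
class Crop:
    """A size x size sub-raster plus its origin and provenance."""

    pixels: np.ndarray
    origin_row: int
    origin_col: int
    size: int
    source_image_id: str = ""
    augmentation_index: int = 0
    tissue_fraction: float = float("nan")


def tissue_fraction(pixels: np.ndarray, od_threshold: float = 0.15) -> float:
    """Share of pixels whose mean OD across channels exceeds ``od_threshold``."""
    od = rgb_to_od(pixels)
    return float((od.mean(axis=-1) > od_threshold).mean())


def sample_crops(
    image: SlideImage,
    size: int,
    count: int = 20,
    seed: int = 0,
    min_tissue_fraction: float = 0.5,
    od_threshold: float = 0.15,
    source_image_id: str = "",
    augmentation_index: int = 0,
) -> list:
    """Draw ``count`` random crops of ``size`` x ``size`` pixels.

    Set ``min_tissue_fraction=0`` to disable background rejection and sample
    origins purely uniformly.
    """
    if size < 1 or count < 1:
        raise ParameterError("size and count must be positive")
    h, w = image.height, image.width
    if h < size or w < size:
        raise CropSizeError(f"image {w}x{h} smaller than crop size {size}")
    rng = np.random.default_rng(seed)
    max_row = h - size
    max_col = w - size
    crops = []
    n_below = 0
    for _ in range(count):
        best = None
        for _attempt in range(_MAX_ATTEMPTS):
            r = int(rng.integers(0, max_row + 1))
            c = int(rng.integers(0, max_col + 1))
            sub = image.pixels[r : r + size, c : c + size]
            tf = tissue_fraction(sub, od_threshold)
            if best is None or tf > best.tissue_fraction:
                best = Crop(
                    pixels=sub.copy(),
                    origin_row=r,
                    origin_col=c,
                    size=size,
                    source_image_id=source_image_id,
                    augmentation_index=augmentation_index,
                    tissue_fraction=tf,
                )
            if tf >= min_tissue_fraction:
                break
        if best.tissue_fraction < min_tissue_fraction:
            n_below += 1
        crops.append(best)
    if n_below:
        warnings.warn(
            f"{n_below}/{count} crops below tissue fraction "
            f"{min_tissue_fraction}; kept best-of-{_MAX_ATTEMPTS} draws",
            stacklevel=2,
        )
    return crops


def crop_coverage_percent(
    image_width: float, image_height: float, size: int, count: int
) -> float:
    """Percentage of image pixels covered by ``count`` crops of ``size``^2 pixels.

    Overlap is ignored: this is the nominal sampled-pixel budget
    ``100 * count * size^2 / (width * height)``.
    """
    if image_width <= 0 or image_height <= 0:
        raise ParameterError("image dimensions must be positive")
    return 100.0 * count * size * size / (image_width * image_height)
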