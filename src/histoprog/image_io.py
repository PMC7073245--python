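"""Reading, downsampling and per-subject grouping of slide-derived images.

Whole-slide scanners store pyramids of resolutions; desk-scale analysis works
on plain 8-bit RGB rasters (PNG/TIFF) exported from a chosen pyramid level,
optionally reduced further by an integer factor. Downsampling is block-mean
(area) interpolation with ceiling dimension rounding, so a partial edge block
is averaged over the pixels it actually contains rather than discarded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ImageLoadError, ParameterError

__all__ = [
    "SlideImage",
    "Cohort",
    "load_image",
    "block_mean_downsample",
    "group_by_subject",
    "read_manifest",
]


@dataclass
class SlideImage:
    """An 8-bit RGB raster with subject/sample provenance.

    ``pixels`` has shape (height, width, 3), dtype uint8.
    """

    pixels: np.ndarray
    subject_id: str = ""
    sample_type: str = "tumor"
    source_level: Optional[int] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ParameterError("SlideImage requires an (H, W, 3) raster")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError("SlideImage dimensions must be >= 1")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class Cohort:
    """A set of slide images plus survival records and provenance notes."""

    images: list = field(default_factory=list)
    survival: list = field(default_factory=list)
    notes: str = ""


def block_mean_downsample(pixels: np.ndarray, factor: int) -> np.ndarray:
    """Reduce an (H, W, C) raster by ``factor`` using block means.

    Output dimensions are ``ceil(H / factor)`` by ``ceil(W / factor)``; edge
    blocks average only the pixels present. ``factor == 1`` is the identity.
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return pixels.copy()
    h, w = pixels.shape[:2]
    acc = pixels.astype(np.float64)
    row_idx = np.arange(0, h, factor)
    col_idx = np.arange(0, w, factor)
    acc = np.add.reduceat(acc, row_idx, axis=0)
    acc = np.add.reduceat(acc, col_idx, axis=1)
    row_counts = np.minimum(row_idx + factor, h) - row_idx
    col_counts = np.minimum(col_idx + factor, w) - col_idx
    counts = row_counts[:, None] * col_counts[None, :]
    out = acc / counts[..., None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def load_image(
    path,
    downsample_factor: int = 1,
    subject_id: str = "",
    sample_type: str = "tumor",
) -> SlideImage:
    """Load a PNG/TIFF image as RGB and reduce it by an integer factor.

    Raises :class:`ImageLoadError` for unreadable or corrupt files — such
    files are dropped from a cohort rather than silently producing garbage.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            rgb = np.asarray(im.convert("RGB"))
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise ImageLoadError(f"cannot read image {path}: {exc}") from exc
    pixels = block_mean_downsample(rgb, downsample_factor)
    return SlideImage(pixels=pixels, subject_id=subject_id, sample_type=sample_type)


def group_by_subject(cohort: Cohort) -> dict:
    """Partition a cohort's images into per-subject buckets.

    Returns a dict keyed by subject_id in sorted order; every image lands in
    exactly one bucket.
    """
    buckets: dict = {}
    for img in cohort.images:
        buckets.setdefault(img.subject_id, []).append(img)
    return {sid: buckets[sid] for sid in sorted(buckets)}


def read_manifest(path) -> list:
    """Read a cohort manifest CSV with columns subject_id, path, sample_type."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "path", "sample_type"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParameterError(
                f"manifest must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            rows.append(
                {
                    "subject_id": row["subject_id"].strip(),
                    "path": row["path"].strip(),
                    "sample_type": row["sample_type"].strip(),
                }
            )
    return rows
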