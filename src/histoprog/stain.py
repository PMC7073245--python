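"""H&E stain deconvolution, normalization and density-space augmentation.

Light absorption by hematoxylin and eosin is additive in optical density
(Beer-Lambert): ``OD = -log10(I / I0)`` per RGB channel, so each pixel's OD
vector is (approximately) a non-negative combination of two unit "stain
vectors". The stain matrix is estimated per image with the classic
plane-fitting procedure: project tissue-pixel OD onto the top-2 singular
plane, take extreme percentile angles as the stain directions. Deconvolving
onto the estimated matrix yields per-pixel stain concentrations, which
support (a) normalization — re-render concentrations through a common
reference matrix after matching robust concentration maxima — and (b) color
augmentation — multiply each stain's concentration channel by a random
factor and re-render.

Log base 10 is used throughout; changing the base only rescales
concentrations and the per-stain maxima together, leaving rendered images
unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (
    DegenerateStainError,
    InsufficientTissueError,
    ParameterError,
)
from .image_io import SlideImage

__all__ = [
    "StainModel",
    "DensityImage",
    "AugmentationPolicy",
    "default_reference",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "compute_concentrations",
    "render_concentrations",
    "normalize_to_reference",
    "augment",
    "angle_degrees",
]

# Classical published H&E optical-density vectors (columns, before
# normalization) and conventional concentration maxima used as the
# normalization target when none is supplied.
_H_REF = np.array([0.65, 0.70, 0.29])
_E_REF = np.array([0.07, 0.99, 0.11])
_MAXC_REF = np.array([1.9705, 1.0308])

#: Minimum angle (degrees) between stain columns before the model counts as
#: degenerate.
_MIN_STAIN_ANGLE_DEG = 1.0


def angle_degrees(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees (direction-sensitive)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class StainModel:
    """A 3x2 unit-column stain matrix plus robust per-stain maxima.

    Column 0 is hematoxylin, column 1 eosin; hematoxylin is identified as the
    column with the larger red-channel OD component (hematoxylin absorbs
    strongly in red, eosin barely).
    """

    matrix: np.ndarray
    max_density: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (3, 2):
            raise ParameterError(f"stain matrix must be 3x2, got {m.shape}")
        if np.any(m < -1e-9):
            raise ParameterError("stain matrix entries must be non-negative")
        m = np.clip(m, 0.0, None)
        norms = np.linalg.norm(m, axis=0)
        if np.any(norms <= 0):
            raise ParameterError("stain matrix columns must be nonzero")
        m = m / norms
        if angle_degrees(m[:, 0], m[:, 1]) <= _MIN_STAIN_ANGLE_DEG:
            raise DegenerateStainError("stain columns are (near-)collinear")
        self.matrix = m
        md = np.asarray(self.max_density, float).reshape(2)
        if np.any(md <= 0):
            raise ParameterError("max_density entries must be positive")
        self.max_density = md

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix.ravel().tolist(),  # row-major 3x2
                "max_density": self.max_density.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StainModel":
        obj = json.loads(text)
        return cls(
            matrix=np.asarray(obj["matrix"], float).reshape(3, 2),
            max_density=np.asarray(obj["max_density"], float),
        )


@dataclass
class DensityImage:
    """Per-pixel 2-channel stain concentrations plus the model that made them."""

    concentrations: np.ndarray  # (H, W, 2), non-negative
    stain_model: StainModel


@dataclass
class AugmentationPolicy:
    """How many color augmentations to draw and from which multiplier range."""

    count: int = 50
    multiplier_low: float = 0.95
    multiplier_high: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ParameterError("augmentation count must be positive")
        if not (0 < self.multiplier_low <= self.multiplier_high):
            raise ParameterError("need 0 < multiplier_low <= multiplier_high")


def default_reference() -> StainModel:
    """The classical H&E stain matrix with conventional concentration maxima."""
    m = np.stack([_H_REF / np.linalg.norm(_H_REF), _E_REF / np.linalg.norm(_E_REF)], axis=1)
    return StainModel(matrix=m, max_density=_MAXC_REF.copy())


def rgb_to_od(pixels: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Convert an RGB raster (or pixel array) to optical density.

    ``OD_c = -log10(max(I_c, 1) / background_intensity)``. Intensities are
    floored at 1 so saturated-dark pixels stay finite.
    """
    if background_intensity <= 0:
        raise ParameterError("background_intensity must be positive")
    I = np.maximum(np.asarray(pixels, float), 1.0)
    return -np.log10(I / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Invert :func:`rgb_to_od`, returning a uint8 raster clipped to [0, 255]."""
    I = background_intensity * np.power(10.0, -np.asarray(od, float))
    return np.clip(np.rint(I), 0, 255).astype(np.uint8)


def _tissue_mask(od_flat: np.ndarray, od_min: float) -> np.ndarray:
    return od_flat.mean(axis=1) > od_min


def estimate_stain_matrix(
    od: np.ndarray,
    od_min: float = 0.15,
    angle_percentile: float = 1.0,
) -> StainModel:
    """Estimate the per-image H&E stain matrix from an OD raster.

    SVD of the tissue-pixel OD cloud gives the 2-D absorption plane; the
    extreme ``angle_percentile``/``100 - angle_percentile`` angles of the
    projected pixels are taken as the two stain directions. Raises
    :class:`InsufficientTissueError` when fewer than 100 pixels exceed
    ``od_min`` mean OD and :class:`DegenerateStainError` when the cloud is
    effectively one-dimensional (top-2 singular value ratio > 50).
    """
    od_flat = np.asarray(od, float).reshape(-1, 3)
    tissue = od_flat[_tissue_mask(od_flat, od_min)]
    if tissue.shape[0] < 100:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} tissue pixels above mean OD {od_min}; need >= 100"
        )
    # Plane fit. Right singular vectors of the (N, 3) cloud span the stains.
    _, svals, vt = np.linalg.svd(tissue, full_matrices=False)
    if svals[1] <= 0 or svals[0] / svals[1] > 50:
        raise DegenerateStainError(
            f"singular value ratio {svals[0] / max(svals[1], 1e-300):.1f} > 50; "
            "input looks single-stain"
        )
    basis = vt[:2]  # (2, 3)
    # Orient basis vectors so projections are predominantly positive.
    proj = tissue @ basis.T
    flip = np.sign(proj.sum(axis=0))
    flip[flip == 0] = 1.0
    basis = basis * flip[:, None]
    proj = proj * flip[None, :]
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    v_lo = np.cos(lo) * basis[0] + np.sin(lo) * basis[1]
    v_hi = np.cos(hi) * basis[0] + np.sin(hi) * basis[1]
    cols = []
    for v in (v_lo, v_hi):
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n <= 0:
            raise DegenerateStainError("extreme-angle stain vector collapsed to zero")
        cols.append(v / n)
    # Hematoxylin = larger red-channel OD component.
    if cols[0][0] >= cols[1][0]:
        matrix = np.stack([cols[0], cols[1]], axis=1)
    else:
        matrix = np.stack([cols[1], cols[0]], axis=1)
    model = StainModel(matrix=matrix)
    conc = _concentrations_flat(tissue, model)
    model.max_density = np.maximum(np.percentile(conc, 99, axis=0), 1e-6)
    return model


def _concentrations_flat(od_flat: np.ndarray, model: StainModel) -> np.ndarray:
    """Vectorized 2-variable non-negative least squares per OD pixel."""
    M = model.matrix
    G = M.T @ M
    b = od_flat @ M  # (N, 2)
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    # Unconstrained solution of the 2x2 normal equations.
    c1 = (G[1, 1] * b[:, 0] - G[0, 1] * b[:, 1]) / det
    c2 = (G[0, 0] * b[:, 1] - G[0, 1] * b[:, 0]) / det
    interior = np.stack([c1, c2], axis=1)
    feasible = (interior >= -1e-12).all(axis=1)
    out = np.clip(interior, 0.0, None)
    if not feasible.all():
        idx = np.flatnonzero(~feasible)
        # Boundary candidates: one concentration pinned at zero.
        a1 = np.clip(b[idx, 0] / G[0, 0], 0.0, None)
        a2 = np.clip(b[idx, 1] / G[1, 1], 0.0, None)

        def obj(x1, x2):
            return (
                G[0, 0] * x1 * x1
                + 2 * G[0, 1] * x1 * x2
                + G[1, 1] * x2 * x2
                - 2 * (b[idx, 0] * x1 + b[idx, 1] * x2)
            )

        zero = np.zeros_like(a1)
        pick2 = obj(zero, a2) < obj(a1, zero)
        out[idx, 0] = np.where(pick2, 0.0, a1)
        out[idx, 1] = np.where(pick2, a2, 0.0)
    return out


def compute_concentrations(od: np.ndarray, model: StainModel) -> DensityImage:
    """Deconvolve an OD raster onto a stain model (non-negative least squares)."""
    od = np.asarray(od, float)
    flat = _concentrations_flat(od.reshape(-1, 3), model)
    return DensityImage(
        concentrations=flat.reshape(od.shape[:-1] + (2,)), stain_model=model
    )


def render_concentrations(
    concentrations: np.ndarray,
    model: StainModel,
    background_intensity: float = 255.0,
) -> np.ndarray:
    """Re-render a concentration raster to RGB through a stain matrix."""
    od = np.asarray(concentrations, float) @ model.matrix.T
    return od_to_rgb(od, background_intensity)


def normalize_to_reference(
    image: SlideImage,
    reference: Optional[StainModel] = None,
    od_min: float = 0.15,
    angle_percentile: float = 1.0,
    background_intensity: float = 255.0,
) -> SlideImage:
    """Map an image's stains onto a reference stain model.

    Estimates the source stain matrix, deconvolves, rescales each stain's
    concentrations by ``reference.max_density / source.max_density`` and
    re-renders through the reference matrix. Stain-estimation errors
    propagate unchanged.
    """
    if reference is None:
        reference = default_reference()
    od = rgb_to_od(image.pixels, background_intensity)
    source = estimate_stain_matrix(od, od_min=od_min, angle_percentile=angle_percentile)
    dens = compute_concentrations(od, source)
    scale = reference.max_density / source.max_density
    conc = dens.concentrations * scale
    pixels = render_concentrations(conc, reference, background_intensity)
    return SlideImage(
        pixels=pixels,
        subject_id=image.subject_id,
        sample_type=image.sample_type,
        source_level=image.source_level,
    )


def augment(
    image: SlideImage,
    policy: AugmentationPolicy,
    od_min: float = 0.15,
    angle_percentile: float = 1.0,
    background_intensity: float = 255.0,
) -> list:
    """Generate ``policy.count`` density-space color augmentations.

    Each augmentation multiplies the two stain-concentration channels by
    independent draws from Uniform[multiplier_low, multiplier_high] and
    re-renders through the image's own estimated stain matrix. Identical
    seeds give identical outputs.
    """
    od = rgb_to_od(image.pixels, background_intensity)
    model = estimate_stain_matrix(od, od_min=od_min, angle_percentile=angle_percentile)
    conc = compute_concentrations(od, model).concentrations
    rng = np.random.default_rng(policy.seed)
    out = []
    for _ in range(policy.count):
        m = rng.uniform(policy.multiplier_low, policy.multiplier_high, size=2)
        pixels = render_concentrations(conc * m, model, background_intensity)
        out.append(
            SlideImage(
                pixels=pixels,
                subject_id=image.subject_id,
                sample_type=image.sample_type,
                source_level=image.source_level,
            )
        )
    return out
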