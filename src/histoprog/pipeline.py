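"""End-to-end orchestration: images -> features -> prognosis -> pathways.

``run_pipeline`` executes the full analysis on a cohort manifest: stain
normalization, color augmentation, random crops, per-crop feature
extraction, median aggregation to image- and subject-level tables,
tumor/normal classification, univariate survival screening, elastic-net Cox
prognosis, K-means subgroup discovery on doubly-significant features, and
(when an IPL matrix is provided) feature-pathway correlation plus
differential pathway activity between subgroups. Every stage draws its seed
deterministically from the master seed, and outputs carry the configuration
hash so a rerun with identical inputs is bit-identical for deterministic
extractors.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from contextlib import contextmanager

from . import embed_classify, features as feat, image_io, patches, pathways, stain, subgroups, survival as surv
from .errors import ConfigError, HistoprogError


@contextmanager
def _stage(name: str):
    """Prefix any pipeline error with the failing stage's name."""
    try:
        yield
    except HistoprogError as exc:
        raise type(exc)(f"stage '{name}' failed: {exc}") from exc

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed", "extract_image_features"]

_STANDARD_CROP_SIZES = (256, 512)


@dataclass
class PipelineConfig:
    manifest: str = ""
    survival_csv: str = ""
    ipl_path: str = ""
    out_dir: str = "results/pipeline"
    downsample_factor: int = 1
    augment_count: int = 50
    multiplier_low: float = 0.95
    multiplier_high: float = 1.05
    crop_size: int = 256
    crop_count: int = 20
    min_tissue_fraction: float = 0.5
    extractor: str = "histogram"
    extractor_dim: int = 256
    classifier_folds: int = 6
    classifier_c: float = 1.0
    elasticnet_alpha: float = 0.5
    survival_folds: int = 10
    screen_threshold: float = 0.05
    k_min: int = 2
    k_max: int = 12
    correlation_threshold: float = 0.05
    differential_threshold: float = 0.1
    master_seed: int = 0
    allow_any_size: bool = False

    def validate(self) -> None:
        for name in ("screen_threshold", "correlation_threshold", "differential_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.crop_count < 1 or self.augment_count < 1:
            raise ConfigError("crop_count and augment_count must be >= 1")
        if self.crop_size not in _STANDARD_CROP_SIZES and not self.allow_any_size:
            raise ConfigError(
                f"crop_size {self.crop_size} is non-standard; pass allow_any_size=True "
                f"to use sizes outside {_STANDARD_CROP_SIZES}"
            )
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigError("need 2 <= k_min <= k_max")

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("out_dir")  # analysis identity is independent of destination
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    image_features: "feat.FeatureTable"
    subject_features: Optional["feat.FeatureTable"]
    classification: Optional[embed_classify.ClassificationReport]
    screen: dict = field(default_factory=dict)  # endpoint -> (indices, pct, pvals)
    elasticnet: Optional[surv.ElasticNetCoxModel] = None
    cluster_scan: Optional[subgroups.ClusteringScan] = None
    subgroup_survival: dict = field(default_factory=dict)  # endpoint -> result
    correlations: Optional[pd.DataFrame] = None
    differential: Optional[pd.DataFrame] = None
    config_hash: str = ""
    bundle_hash: str = ""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _make_extractor(config: PipelineConfig):
    if config.extractor in ("histogram", "histogram-rp"):
        return feat.HistogramProjectionExtractor(output_dim=config.extractor_dim)
    return feat.PretrainedCNNExtractor(config.extractor)


def extract_image_features(
    image: image_io.SlideImage,
    extractor,
    config: PipelineConfig,
    image_index: int = 0,
    reference: Optional[stain.StainModel] = None,
) -> np.ndarray:
    """Normalize, augment, crop and extract one image's median feature vector."""
    normalized = stain.normalize_to_reference(image, reference)
    policy = stain.AugmentationPolicy(
        count=config.augment_count,
        multiplier_low=config.multiplier_low,
        multiplier_high=config.multiplier_high,
        seed=stage_seed(config.master_seed, f"augment:{image_index}"),
    )
    augmented = stain.augment(normalized, policy)
    vectors = []
    for aug_idx, aug in enumerate(augmented):
        crops = patches.sample_crops(
            aug,
            size=config.crop_size,
            count=config.crop_count,
            seed=stage_seed(config.master_seed, f"crops:{image_index}:{aug_idx}"),
            min_tissue_fraction=config.min_tissue_fraction,
            source_image_id=str(image_index),
            augmentation_index=aug_idx,
        )
        for crop in crops:
            vectors.append(feat.extract_crop_features(crop, extractor))
    return feat.aggregate_to_image(vectors)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config`` and write the bundle."""
    config.validate()
    chash = config.config_hash()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    extractor = _make_extractor(config)

    rows = image_io.read_manifest(config.manifest)
    if not rows:
        raise ConfigError("empty manifest")
    vectors, sample_ids, labels, subject_of = [], [], [], []
    for i, row in enumerate(rows):
        with _stage(f"features (image {i}: {row['path']})"):
            image = image_io.load_image(
                    row["path"],
                    downsample_factor=config.downsample_factor,
                    subject_id=row["subject_id"],
                    sample_type=row["sample_type"],
                )
            vectors.append(extract_image_features(image, extractor, config, image_index=i))
        sample_ids.append(f"{row['subject_id']}:{row['sample_type']}:{i}")
        labels.append(row["sample_type"])
        subject_of.append((row["subject_id"], row["sample_type"]))
    values = pd.DataFrame(np.stack(vectors), index=sample_ids)
    image_table = feat.FeatureTable(
        values=values,
        labels=pd.Series(labels, index=sample_ids),
        extractor_name=extractor.name,
        crop_size=config.crop_size,
    )
    image_table.to_tsv(out_dir / f"features_image_{chash}.tsv")

    # Subject-level tumor table: median across a subject's tumor images.
    tumor_rows = [i for i, (_, st) in enumerate(subject_of) if st == "tumor"]
    subject_table = None
    if tumor_rows:
        by_subject: dict = {}
        for i in tumor_rows:
            by_subject.setdefault(subject_of[i][0], []).append(values.iloc[i].to_numpy())
        subj_ids = sorted(by_subject)
        subj_vals = pd.DataFrame(
            np.stack([feat.aggregate_to_subject(by_subject[s]) for s in subj_ids]),
            index=subj_ids,
        )
        subject_table = feat.FeatureTable(
            values=subj_vals, extractor_name=extractor.name, crop_size=config.crop_size
        )
        subject_table.to_tsv(out_dir / f"features_subject_{chash}.tsv")

    classification = None
    if len(set(labels)) == 2:
        with _stage("classification"):
            classification = embed_classify.classify_cv(
                    image_table,
                    image_table.labels,
                    folds=config.classifier_folds,
                    c=config.classifier_c,
                    seed=stage_seed(config.master_seed, "classify"),
                )
        (out_dir / f"classification_{chash}.json").write_text(
            json.dumps(classification.to_dict(), indent=2)
        )

    screen: dict = {}
    elasticnet = None
    scan = None
    sub_surv: dict = {}
    correlations = None
    differential = None
    if config.survival_csv and subject_table is not None:
        records = surv.read_survival_csv(config.survival_csv)
        for endpoint in ("OS", "DFS"):
            frame = surv.records_to_frame(records, endpoint=endpoint)
            shared = subject_table.values.index.intersection(frame.index)
            if len(shared) < 3 or frame.loc[shared, "event"].sum() < 2:
                continue
            Xs = subject_table.values.loc[shared]
            with _stage(f"survival screen ({endpoint})"):
                sel, pct, pvals = surv.screen_features(
                    Xs,
                    frame.loc[shared, "time"].to_numpy(),
                    frame.loc[shared, "event"].to_numpy(),
                    threshold=config.screen_threshold,
                )
                screen[endpoint] = (sel, pct, pvals)
                pd.DataFrame(
                    {"feature": Xs.columns, "p": pvals, "selected": np.isin(np.arange(len(pvals)), sel)}
                ).to_csv(out_dir / f"screen_{endpoint}_{chash}.tsv", sep="\t", index=False)
            if "OS" in screen:
                frame = surv.records_to_frame(records, endpoint="OS")
                shared = subject_table.values.index.intersection(frame.index)
                Xs = subject_table.values.loc[shared]
                t = frame.loc[shared, "time"].to_numpy()
                e = frame.loc[shared, "event"].to_numpy()
                if e.sum() >= config.survival_folds:
                    with _stage("elastic-net Cox (OS)"):
                        elasticnet = surv.fit_elasticnet_cox(
                        Xs,
                        t,
                        e,
                        alpha=config.elasticnet_alpha,
                        folds=config.survival_folds,
                        seed=stage_seed(config.master_seed, "elasticnet"),
                    )
                (out_dir / f"elasticnet_OS_{chash}.json").write_text(
                    json.dumps(
                        {
                            "lambda": elasticnet.lambda_selected,
                            "alpha": elasticnet.alpha,
                            "c_index": elasticnet.c_index,
                            "logrank_p": elasticnet.logrank_p,
                            "nonzero": {str(k): float(v) for k, v in elasticnet.nonzero.items()},
                        },
                        indent=2,
                    )
                )
        if "OS" in screen and "DFS" in screen:
            both = np.intersect1d(screen["OS"][0], screen["DFS"][0])
            if len(both) >= 1:
                frame = surv.records_to_frame(records, endpoint="OS")
                shared = subject_table.values.index.intersection(frame.index)
                Xsig = subject_table.values.loc[shared].iloc[:, both]
                if len(shared) > config.k_min:
                    with _stage("subgroup discovery"):
                        scan = subgroups.cluster_scan(
                            Xsig,
                            k_min=config.k_min,
                            k_max=config.k_max,
                            seed=stage_seed(config.master_seed, "kmeans"),
                        )
                        for endpoint in ("OS", "DFS"):
                            fr = surv.records_to_frame(records, endpoint=endpoint)
                            sh = Xsig.index.intersection(fr.index)
                            lab = scan.chosen_labels[[list(Xsig.index).index(s) for s in sh]]
                            if len(np.unique(lab)) >= 2 and fr.loc[sh, "event"].sum() >= 2:
                                sub_surv[endpoint] = subgroups.subgroup_survival(
                                    lab,
                                    fr.loc[sh, "time"].to_numpy(),
                                    fr.loc[sh, "event"].to_numpy(),
                                )
                        if scan is not None:
                            pd.DataFrame(
                                {"subject_id": Xsig.index, "group": scan.chosen_labels}
                            ).to_csv(out_dir / f"subgroups_{chash}.csv", index=False)
                if config.ipl_path:
                    ipl = pathways.parse_ipl(config.ipl_path)
                    try:
                        correlations = pathways.correlate(
                            Xsig, ipl, threshold=config.correlation_threshold
                        )
                        correlations.to_csv(
                            out_dir / f"correlations_{chash}.tsv", sep="\t", index=False
                        )
                    except Exception as exc:  # alignment failures are non-fatal
                        warnings.warn(f"correlation stage skipped: {exc}", stacklevel=2)
                    if scan is not None and scan.chosen_k == 2:
                        shared_ipl = [s for s in Xsig.index if s in ipl.values.columns]
                        if len(shared_ipl) >= 4:
                            lab = np.array(
                                [
                                    scan.chosen_labels[list(Xsig.index).index(s)]
                                    for s in shared_ipl
                                ]
                            )
                            if len(np.unique(lab)) == 2 and min(np.bincount(lab)[np.unique(lab)]) >= 2:
                                sub = pathways.IPLMatrix(
                                    values=ipl.values[shared_ipl],
                                    pathway_index=ipl.pathway_index,
                                    concept=ipl.concept,
                                )
                                differential = pathways.differential_ipl(
                                    sub, lab, threshold=config.differential_threshold
                                )
                                differential.to_csv(
                                    out_dir / f"differential_{chash}.tsv", sep="\t"
                                )

    bundle = {
        "config_hash": chash,
        "n_images": len(rows),
        "feature_dim": int(values.shape[1]),
        "classification": classification.to_dict() if classification else None,
        "screen": {
            k: {"n_selected": int(len(v[0])), "percent": float(v[1])} for k, v in screen.items()
        },
        "elasticnet": None
        if elasticnet is None
        else {
            "lambda": elasticnet.lambda_selected,
            "c_index": elasticnet.c_index,
            "logrank_p": elasticnet.logrank_p,
            "n_nonzero": int((elasticnet.coefficients != 0).sum()),
        },
        "chosen_k": None if scan is None else int(scan.chosen_k),
        "subgroup_survival": {
            k: {"logrank_p": v.logrank_p, "c_index": v.c_index} for k, v in sub_surv.items()
        },
    }
    bundle_text = json.dumps(bundle, sort_keys=True)
    bundle_hash = hashlib.sha256(
        (bundle_text + values.to_csv()).encode()
    ).hexdigest()[:16]
    bundle["bundle_hash"] = bundle_hash
    (out_dir / f"bundle_{chash}.json").write_text(json.dumps(bundle, indent=2))

    return PipelineResult(
        image_features=image_table,
        subject_features=subject_table,
        classification=classification,
        screen=screen,
        elasticnet=elasticnet,
        cluster_scan=scan,
        subgroup_survival=sub_surv,
        correlations=correlations,
        differential=differential,
        config_hash=chash,
        bundle_hash=bundle_hash,
    )
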