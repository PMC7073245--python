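"""Image route: stain-normalize, augment, crop and extract median features.

Reads results/data/manifest.csv, pushes every slide through normalization,
5 color augmentations and 8 random 32x32 crops per augmented image (scaled
down from the production 50 x 20 x 256 defaults to keep the desk-scale run
fast), extracts histogram-projection features and writes the per-image
feature table plus the per-subject (tumor) table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from histoprog import features as feat, image_io
from histoprog.pipeline import PipelineConfig, extract_image_features

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    config = PipelineConfig(
        manifest=str(DATA / "manifest.csv"),
        augment_count=5,
        crop_size=32,
        crop_count=8,
        allow_any_size=True,
        extractor_dim=64,
        master_seed=1,
    )
    extractor = feat.HistogramProjectionExtractor(output_dim=config.extractor_dim)
    rows = image_io.read_manifest(config.manifest)
    vectors, ids, labels = [], [], []
    for i, row in enumerate(rows):
        image = image_io.load_image(row["path"], subject_id=row["subject_id"],
                                    sample_type=row["sample_type"])
        vectors.append(extract_image_features(image, extractor, config, image_index=i))
        ids.append(f"{row['subject_id']}:{row['sample_type']}:{i}")
        labels.append(row["sample_type"])
    table = feat.FeatureTable(
        values=pd.DataFrame(np.stack(vectors), index=ids),
        labels=pd.Series(labels, index=ids),
        extractor_name=extractor.name,
        crop_size=config.crop_size,
    )
    table.to_tsv(OUT / "image_features.tsv")
    print(f"extracted {table.values.shape[1]}-dim features for {len(ids)} images")
    print(f"({config.augment_count} augmentations x {config.crop_count} crops each)")


if __name__ == "__main__":
    main()
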