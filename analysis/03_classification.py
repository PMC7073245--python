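"""Visualization and tumor/normal classification on both feature routes.

Embeds the cohort feature table (PCA-10 then t-SNE, perplexity 15), runs
stratified 6-fold linear-SVM classification on the image-route features and
the cohort table, and repeats the random feature-subset experiment
(sizes 10/25/50) on the cohort table.
"""

import json
from pathlib import Path

import pandas as pd

from histoprog.embed_classify import classify_cv, embed, feature_subset_experiment
from histoprog.features import FeatureTable

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    cohort = FeatureTable.from_tsv(DATA / "cohort_features.tsv")
    images = FeatureTable.from_tsv(OUT / "image_features.tsv")

    coords = embed(cohort, n_components=10, perplexity=15, seed=0)
    pd.DataFrame(
        {"sample_id": cohort.sample_ids, "x": coords[:, 0], "y": coords[:, 1],
         "label": cohort.labels.to_numpy()}
    ).to_csv(OUT / "embedding.csv", index=False)

    reports = {}
    for name, table in (("image_route", images), ("cohort_table", cohort)):
        rep = classify_cv(table, table.labels, folds=6, seed=0)
        reports[name] = rep.to_dict()
        print(f"{name}: mean AUC {rep.mean_auc:.3f}, AP {rep.average_precision:.3f}")
    subsets = feature_subset_experiment(cohort, cohort.labels, sizes=(10, 25, 50),
                                        repeats=5, seed=0)
    reports["subset_auc_by_size"] = subsets
    print("subset AUC by size:", {k: round(v, 3) for k, v in subsets.items()})
    (OUT / "classification.json").write_text(json.dumps(reports, indent=2))


if __name__ == "__main__":
    main()
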