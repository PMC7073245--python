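"""Generate every synthetic input the downstream analyses need.

Writes under results/data/:
  images/ + manifest.csv + survival_images.csv  — a small rendered H&E set
      (tumor slides carry many nuclei, normals few) for the image route;
  cohort_features.tsv + survival.csv + ipl.tsv + ground_truth.json — a
      desk-scale cohort feature table (150 tumor / 40 normal, ~4:1 as in the
      study cohort) with planted class, cluster, survival and pathway
      coupling structure for the statistical stages.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from histoprog.features import FeatureTable
from histoprog.pathways import write_ipl
from histoprog.synthetic_data import (
    CohortSimSpec,
    ImageSimSpec,
    simulate_cohort,
    simulate_he_image,
    simulate_ipl,
)

OUT = Path("results/data")
SEED = 20260928


def main() -> None:
    img_dir = OUT / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    # --- image route: 18 rendered slides over 18 subjects -------------------
    image_cohort = simulate_cohort(
        CohortSimSpec(n_tumor=12, n_normal=6, n_features=24, class_shift=4.0,
                      censor_fraction=0.25, seed=SEED)
    )
    rng = np.random.default_rng(SEED)
    rows = []
    for i, sid in enumerate(image_cohort.labels.index):
        tumor = image_cohort.labels[sid] == "tumor"
        sim = simulate_he_image(
            ImageSimSpec(width=128, height=128, nucleus_count=40 if tumor else 6,
                         nucleus_radius_range=(3, 7), seed=int(rng.integers(2**31)))
        )
        path = img_dir / f"im{i:02d}.png"
        Image.fromarray(sim.image.pixels).save(path)
        rows.append((sid, str(path), image_cohort.labels[sid]))
    pd.DataFrame(rows, columns=["subject_id", "path", "sample_type"]).to_csv(
        OUT / "manifest.csv", index=False
    )
    pd.DataFrame(
        [(r.subject_id, r.time, r.event, r.endpoint) for r in image_cohort.survival],
        columns=["subject_id", "time_days", "event", "endpoint"],
    ).to_csv(OUT / "survival_images.csv", index=False)

    # --- statistical route: cohort feature table + IPL -----------------------
    # Plant the survival signal on the cluster-shifted feature subspace so the
    # discovered subgroups genuinely differ in survival, as in the real
    # cohort; a scouting pass with zero coefficients reveals which columns
    # carry the planted cluster (same seed -> same layout).
    spec_kwargs = dict(n_tumor=150, n_normal=40, n_features=60, class_shift=3.0,
                       n_clusters=2, cluster_shift=3.0, censor_fraction=0.3,
                       seed=SEED + 2)
    scout = simulate_cohort(CohortSimSpec(survival_beta=np.zeros(60), **spec_kwargs))
    beta = np.zeros(60)
    beta[scout.cluster_feature_idx[1][:5]] = 0.3
    cohort = simulate_cohort(CohortSimSpec(survival_beta=beta, **spec_kwargs))
    FeatureTable(values=cohort.features, labels=cohort.labels,
                 extractor_name="simulated-cohort").to_tsv(OUT / "cohort_features.tsv")
    pd.DataFrame(
        [(r.subject_id, r.time, r.event, r.endpoint) for r in cohort.survival],
        columns=["subject_id", "time_days", "event", "endpoint"],
    ).to_csv(OUT / "survival.csv", index=False)
    # couple two entities to subgroup-carrying features (their activity will
    # differ between the discovered subgroups) and one to an arbitrary feature
    cluster_feats = [f"f{j}" for j in scout.cluster_feature_idx[1][:2]]
    coupled = [(cluster_feats[0], 0, 0.6), ("f1", 1, -0.5), (cluster_feats[1], 2, 0.7)]
    ipl, truth = simulate_ipl(cohort.features, n_entities=120,
                              coupled_pairs=coupled, seed=SEED + 3)
    write_ipl(ipl, OUT / "ipl.tsv")
    (OUT / "ground_truth.json").write_text(json.dumps({
        "survival_beta_nonzero": np.flatnonzero(beta).tolist(),
        "class_feature_idx": cohort.class_feature_idx.tolist(),
        "planted_clusters": int(cohort.cluster_assignments.nunique()),
        "ipl_coupling": truth,
    }, indent=2))
    print(f"wrote 18 images, cohort table (190 x 60), IPL (120 entities) under {OUT}")


if __name__ == "__main__":
    main()
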