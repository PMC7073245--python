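"""Subgroup discovery on doubly survival-significant features.

Clusters tumor samples (K-means, K = 2..12, silhouette + Davies-Bouldin)
on the features selected for both OS and DFS, compares subgroup survival
(log-rank, C-index, KM), and builds an overlap table between the subgroup
labelings obtained from two feature views (all features vs the significant
subset) as a stand-in for the cross-backbone comparison.
"""

import json
from pathlib import Path

import pandas as pd

from histoprog.features import FeatureTable
from histoprog.subgroups import cluster_scan, overlap_table, subgroup_survival
from histoprog.survival import read_survival_csv, records_to_frame

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    cohort = FeatureTable.from_tsv(DATA / "cohort_features.tsv")
    tumors = cohort.values.loc[cohort.labels == "tumor"]
    records = read_survival_csv(DATA / "survival.csv")
    both = json.loads((OUT / "survival_summary.json").read_text())["significant_both"]
    Xsig = tumors.iloc[:, both]
    print(f"clustering {Xsig.shape[0]} tumors on {Xsig.shape[1]} doubly-significant features")

    scan = cluster_scan(Xsig, seed=0)
    print(f"chosen K = {scan.chosen_k} "
          f"(silhouette {scan.silhouette_per_k[scan.chosen_k]:.3f}, "
          f"Davies-Bouldin {scan.davies_bouldin_per_k[scan.chosen_k]:.3f})")
    pd.DataFrame(
        {"k": scan.k_values,
         "silhouette": [scan.silhouette_per_k[k] for k in scan.k_values],
         "davies_bouldin": [scan.davies_bouldin_per_k[k] for k in scan.k_values]}
    ).to_csv(OUT / "cluster_scan.tsv", sep="\t", index=False)

    labels = scan.chosen_labels
    if scan.chosen_k != 2:
        print("note: comparing the two-subgroup solution for survival contrast")
        labels = scan.labels_per_k[2]

    results = {"chosen_k": int(scan.chosen_k)}
    for endpoint in ("OS", "DFS"):
        frame = records_to_frame(records, endpoint=endpoint)
        shared = [s for s in Xsig.index if s in frame.index]
        lab = labels[[list(Xsig.index).index(s) for s in shared]]
        res = subgroup_survival(lab, frame.loc[shared, "time"].to_numpy(),
                                frame.loc[shared, "event"].to_numpy())
        print(f"{endpoint}: log-rank p {res.logrank_p:.2e}, C-index {res.c_index:.3f} "
              f"(group 2 = better prognosis)")
        results[endpoint] = {"logrank_p": res.logrank_p, "c_index": res.c_index}
        if endpoint == "OS":
            pd.DataFrame({"subject_id": shared, "group": res.labels}).to_csv(
                OUT / "subgroups.csv", index=False
            )

    alt = cluster_scan(tumors, seed=0)
    counts = overlap_table({
        "significant_view": labels,
        "all_features_view": alt.labels_per_k[2],
    })
    counts.to_csv(OUT / "subgroup_overlap.tsv", sep="\t", index=False)
    print(f"overlap table cells sum to {counts['count'].sum()} tumor samples")
    (OUT / "subgroup_summary.json").write_text(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
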