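"""K-means subgroup discovery on survival-associated features.

The cluster count K is scanned (default 2..12) and chosen by the mean
silhouette coefficient, with the Davies-Bouldin index (lower is better) as
tie-breaker. Features are standardized before clustering because raw
activations have heterogeneous scales. Subgroup survival differences are
assessed with a Cox model on group indicators, a log-rank test and
Kaplan-Meier curves; groups are relabeled so that higher group numbers have
better survival (larger area under the KM curve), making "group 2 is the
good-prognosis group" a stable convention for K = 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.preprocessing import StandardScaler

from .errors import AlignmentError, DegenerateClusteringError, GroupSizeError
from .survival import concordance_index, kaplan_meier

__all__ = ["ClusteringScan", "SubgroupSurvival", "cluster_scan", "subgroup_survival", "overlap_table"]


@dataclass
class ClusteringScan:
    k_values: list
    labels_per_k: dict
    silhouette_per_k: dict
    davies_bouldin_per_k: dict
    chosen_k: int

    @property
    def chosen_labels(self) -> np.ndarray:
        return self.labels_per_k[self.chosen_k]


@dataclass
class SubgroupSurvival:
    labels: np.ndarray
    logrank_p: float
    c_index: float
    km_curves: dict = field(default_factory=dict)


def cluster_scan(
    features,
    k_min: int = 2,
    k_max: int = 12,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = True,
) -> ClusteringScan:
    """K-means over K = k_min..k_max with silhouette/Davies-Bouldin selection."""
    X = features.to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    n = X.shape[0]
    if np.allclose(X, X[0]):
        raise DegenerateClusteringError("all points identical; clustering undefined")
    if n <= k_max:
        warnings.warn(f"only {n} samples; clipping k_max from {k_max} to {n - 1}", stacklevel=2)
        k_max = n - 1
    if standardize:
        X = StandardScaler().fit_transform(X)
    ks = list(range(k_min, k_max + 1))
    labels_per_k, sil, dbi = {}, {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        labels_per_k[k] = lab
        if len(np.unique(lab)) < 2:
            sil[k], dbi[k] = -1.0, np.inf
        else:
            sil[k] = float(silhouette_score(X, lab))
            dbi[k] = float(davies_bouldin_score(X, lab))
    # Max silhouette; Davies-Bouldin (lower) breaks ties, then smaller K.
    chosen = min(ks, key=lambda k: (-sil[k], dbi[k], k))
    return ClusteringScan(
        k_values=ks,
        labels_per_k=labels_per_k,
        silhouette_per_k=sil,
        davies_bouldin_per_k=dbi,
        chosen_k=chosen,
    )


def _km_area(time, event) -> float:
    """Area under the KM curve up to the last observed time (restricted mean)."""
    curves, _ = kaplan_meier(time, event, np.zeros(len(time), int))
    df = next(iter(curves.values()))
    t = df["timeline"].to_numpy()
    s = df["survival"].to_numpy()
    horizon = float(np.max(time))
    # Step function: survival is right-continuous, constant between drops.
    t_ext = np.append(t, horizon)
    return float(np.sum(s * np.diff(t_ext))) if len(t) else horizon


def subgroup_survival(labels, time, event) -> SubgroupSurvival:
    """Survival comparison across discovered subgroups.

    Groups are renumbered 1..G by increasing KM area, so the highest-numbered
    group has the best prognosis. The concordance index uses the Cox linear
    predictor of the group indicators as the risk score.
    """
    labels = np.asarray(labels)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise GroupSizeError("need >= 2 subgroups for a survival comparison")
    areas = {g: _km_area(time[labels == g], event[labels == g]) for g in uniq}
    order = sorted(uniq, key=lambda g: areas[g])  # worst survival first
    relabel = {g: i + 1 for i, g in enumerate(order)}
    new_labels = np.array([relabel[g] for g in labels])

    df = pd.DataFrame({"time": time, "event": event})
    for g in range(2, len(uniq) + 1):  # group 1 is baseline
        df[f"g{g}"] = (new_labels == g).astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    risk = cph.predict_partial_hazard(df).to_numpy(float)
    curves, p = kaplan_meier(time, event, new_labels)
    return SubgroupSurvival(
        labels=new_labels,
        logrank_p=float(p),
        c_index=concordance_index(risk, time, event),
        km_curves=curves,
    )


def overlap_table(label_sets: dict) -> pd.DataFrame:
    """Contingency counts over label combinations from several models.

    ``label_sets`` maps model name to an equal-length label sequence over the
    same samples. Returns one row per observed combination with a ``count``
    column; counts sum to the number of samples.
    """
    names = list(label_sets)
    lengths = {len(np.asarray(v)) for v in label_sets.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"label sets have different lengths: {lengths}")
    df = pd.DataFrame({name: np.asarray(label_sets[name]) for name in names})
    counts = df.groupby(names, sort=True).size().reset_index(name="count")
    return counts
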