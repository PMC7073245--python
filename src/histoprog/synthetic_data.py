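"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline end to end without any downloads:

* :func:`simulate_he_image` — two-stain Beer-Lambert H&E-like rasters with a
  known 3x2 stain matrix: hematoxylin-rich nucleus disks, eosin-rich
  cytoplasm, Gaussian concentration noise and a pure-white background strip.
* :func:`simulate_cohort` — a samples x features table with a planted
  tumor/normal mean shift, planted K-cluster structure among tumors, and
  exponential-baseline Cox survival (OS and DFS) with known coefficients and
  uniform censoring calibrated to a target fraction.
* :func:`simulate_ipl` — a pathway-entity matrix in which chosen entities
  are linear transforms of chosen features achieving a target correlation in
  expectation, the rest independent noise.

All generators are fully determined by their seed. Cohort defaults mirror a
scaled-down version of the study conditions: a ~4:1 tumor:normal ratio, ~30%
censoring, and mean shifts large enough that class and cluster structure are
clean (the regime the pipeline is reported to operate in on real slides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import SimulationSpecError
from .image_io import SlideImage
from .pathways import ipl_from_frame
from .stain import StainModel, default_reference, render_concentrations
from .survival import SurvivalRecord

__all__ = [
    "ImageSimSpec",
    "CohortSimSpec",
    "SimulatedImage",
    "SimulatedCohort",
    "simulate_he_image",
    "simulate_cohort",
    "simulate_ipl",
]


@dataclass
class ImageSimSpec:
    width: int = 256
    height: int = 256
    stain_model: Optional[StainModel] = None
    nucleus_count: int = 40
    nucleus_radius_range: tuple = (4, 10)
    background_fraction: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise SimulationSpecError("image dimensions must be positive")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise SimulationSpecError("background_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise SimulationSpecError("noise_sd must be >= 0")
        r_lo, r_hi = self.nucleus_radius_range
        if r_lo > r_hi or r_hi >= min(self.width, self.height):
            raise SimulationSpecError("nucleus radii must fit inside the image")


@dataclass
class SimulatedImage:
    image: SlideImage
    stain_model: StainModel  # ground truth, max_density from rendered tissue
    concentrations: np.ndarray  # (H, W, 2) ground-truth H/E densities


def simulate_he_image(spec: ImageSimSpec) -> SimulatedImage:
    """Render an H&E-like image from known stain vectors and concentrations."""
    rng = np.random.default_rng(spec.seed)
    model = spec.stain_model if spec.stain_model is not None else default_reference()
    h, w = spec.height, spec.width
    conc = np.zeros((h, w, 2))
    # Background occupies the rightmost columns; tissue fills the rest.
    n_tissue_cols = int(round(w * (1.0 - spec.background_fraction)))
    tissue = np.zeros((h, w), bool)
    tissue[:, :n_tissue_cols] = True
    if tissue.any():
        # Cytoplasm: eosin only (plus noise), near-pure E pixels anchor the
        # extreme-angle estimator on one side.
        conc[:, :, 1][tissue] = rng.uniform(0.2, 1.0, size=int(tissue.sum()))
        # Nuclei: strong hematoxylin, eosin suppressed to near zero so the
        # other extreme angle is anchored too.
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        for _ in range(spec.nucleus_count):
            if n_tissue_cols == 0:
                break
            r = rng.uniform(*spec.nucleus_radius_range)
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, n_tissue_cols)
            disk = ((rows - cy) ** 2 + (cols - cx) ** 2 <= r * r) & tissue
            if not disk.any():
                continue
            conc[:, :, 0][disk] = rng.uniform(0.6, 1.2, size=int(disk.sum()))
            conc[:, :, 1][disk] *= 0.05
        if spec.noise_sd > 0:
            noise = rng.normal(0.0, spec.noise_sd, size=(int(tissue.sum()), 2))
            conc[tissue] = np.clip(conc[tissue] + noise, 0.0, None)
    pixels = render_concentrations(conc, model)
    truth = StainModel(matrix=model.matrix.copy())
    flat = conc[tissue] if tissue.any() else np.zeros((0, 2))
    if flat.shape[0]:
        truth.max_density = np.maximum(np.percentile(flat, 99, axis=0), 1e-6)
    return SimulatedImage(
        image=SlideImage(pixels=pixels, subject_id=f"sim{spec.seed}"),
        stain_model=truth,
        concentrations=conc,
    )


@dataclass
class CohortSimSpec:
    n_tumor: int = 120
    n_normal: int = 30
    n_features: int = 50
    class_shift: float = 3.0
    n_clusters: int = 2
    cluster_shift: float = 3.0
    survival_beta: Optional[np.ndarray] = None  # default: 5 entries of 1.0
    censor_fraction: float = 0.3
    baseline_hazard: float = 1.0 / 365.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 0 or self.n_features < 1:
            raise SimulationSpecError("counts must be positive")
        if not (0.0 <= self.censor_fraction < 1.0):
            raise SimulationSpecError("censor_fraction must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise SimulationSpecError("baseline_hazard must be positive")


@dataclass
class SimulatedCohort:
    features: pd.DataFrame  # all samples x features
    labels: pd.Series  # tumor / normal
    survival: list  # SurvivalRecords, OS and DFS, tumor subjects
    cluster_assignments: pd.Series  # planted cluster per tumor sample
    class_feature_idx: np.ndarray
    cluster_feature_idx: dict
    survival_beta: np.ndarray
    dfs_beta: np.ndarray

    @property
    def tumor_features(self) -> pd.DataFrame:
        return self.features.loc[self.labels == "tumor"]


def _calibrate_censoring(t_event: np.ndarray, u: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target fraction.

    The empirical censored fraction ``mean(c*u < t)`` decreases monotonically
    in c; solve for c by bisection on fixed uniforms so the draw stays
    deterministic.
    """

    def frac(c):
        return float(np.mean(c * u < t_event)) - target

    lo, hi = 1e-9, float(t_event.max()) * 1e6
    if frac(hi) > 0:  # even huge c censors too much (cannot happen for target>0)
        return hi
    return brentq(frac, lo, hi, xtol=1e-12, rtol=1e-10)


def _simulate_survival(X, beta, baseline_hazard, censor_fraction, rng, endpoint, ids):
    lp = X @ beta
    lp = lp - lp.mean()
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0, size=len(rate)) / rate  # Exp(rate)
    if censor_fraction > 0:
        u = rng.uniform(size=len(rate))
        c = _calibrate_censoring(t_event, u, censor_fraction)
        t_cens = c * u
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(len(rate), int)
        time = t_event
    time = np.maximum(time, 1e-6)
    return [
        SurvivalRecord(sid, float(t), int(e), endpoint)
        for sid, t, e in zip(ids, time, event)
    ]


def simulate_cohort(spec: CohortSimSpec) -> SimulatedCohort:
    """Generate a cohort feature table with planted class/cluster/survival."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tumor + spec.n_normal
    p = spec.n_features
    X = rng.standard_normal((n, p))
    ids = [f"S{i:04d}" for i in range(n)]
    labels = np.array(["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal)

    # Disjoint feature subspaces for the class shift and each planted cluster.
    block = max(1, p // 10)
    perm = rng.permutation(p)
    class_idx = perm[:block]
    X[: spec.n_tumor][:, class_idx] += spec.class_shift

    cluster_idx = {}
    clusters = np.zeros(spec.n_tumor, int)
    if spec.n_clusters > 1:
        clusters = rng.integers(0, spec.n_clusters, size=spec.n_tumor)
        for c in range(1, spec.n_clusters):
            lo = block * c
            idx = perm[lo : lo + block]
            if len(idx) == 0:
                raise SimulationSpecError("too few features for the planted clusters")
            cluster_idx[c] = idx
            X[np.flatnonzero(clusters == c)[:, None], idx[None, :]] += spec.cluster_shift

    beta = spec.survival_beta
    if beta is None:
        beta = np.zeros(p)
        k = min(5, p)
        beta[rng.choice(p, size=k, replace=False)] = 1.0
    beta = np.asarray(beta, float)
    if beta.shape != (p,):
        raise SimulationSpecError(f"survival_beta must have length {p}")
    # DFS keeps the OS support (prognostic features tend to matter for both
    # endpoints) but with damped, jittered coefficients and its own draws.
    dfs_rng = np.random.default_rng(spec.seed + 1)
    dfs_beta = 0.8 * beta * dfs_rng.uniform(0.8, 1.2, size=p)

    tumor_ids = ids[: spec.n_tumor]
    Xt = X[: spec.n_tumor]
    survival = _simulate_survival(
        Xt, beta, spec.baseline_hazard, spec.censor_fraction, rng, "OS", tumor_ids
    )
    survival += _simulate_survival(
        Xt, dfs_beta, spec.baseline_hazard, spec.censor_fraction, dfs_rng, "DFS", tumor_ids
    )
    features = pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(p)])
    return SimulatedCohort(
        features=features,
        labels=pd.Series(labels, index=ids, name="label"),
        survival=survival,
        cluster_assignments=pd.Series(clusters, index=tumor_ids, name="cluster"),
        class_feature_idx=class_idx,
        cluster_feature_idx=cluster_idx,
        survival_beta=beta,
        dfs_beta=dfs_beta,
    )


def simulate_ipl(
    features: pd.DataFrame,
    n_entities: int = 100,
    coupled_pairs=(),
    noise_sd: float = 1.0,
    seed: int = 0,
    n_pathways: int = 135,
) -> tuple:
    """Entity x sample matrix with chosen entities coupled to chosen features.

    ``coupled_pairs`` is a list of ``(feature, entity_index, rho)``: entity
    row ``entity_index`` becomes ``rho * z_feature + sqrt(1 - rho^2) * eps``
    with standard-normal noise, so its correlation with the feature is
    ``rho`` in expectation. Returns ``(IPLMatrix, ground_truth_list)``.
    """
    rng = np.random.default_rng(seed)
    n = features.shape[0]
    E = rng.normal(0.0, noise_sd, size=(n_entities, n))
    truth = []
    for feat, eidx, rho in coupled_pairs:
        if not (-1.0 < rho < 1.0):
            raise SimulationSpecError(f"target correlation {rho} must be in (-1, 1)")
        if not (0 <= eidx < n_entities):
            raise SimulationSpecError(f"entity index {eidx} out of range")
        x = features[feat].to_numpy(float)
        z = (x - x.mean()) / max(x.std(), 1e-12)
        E[eidx] = rho * z + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
        truth.append({"feature": feat, "entity_index": int(eidx), "rho": float(rho)})
    ids = [f"{i % n_pathways}_G{i:04d}" for i in range(n_entities)]
    df = pd.DataFrame(E, index=ids, columns=features.index)
    ipl = ipl_from_frame(df)
    for t in truth:
        t["entity_id"] = ids[t["entity_index"]]
    return ipl, truth
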