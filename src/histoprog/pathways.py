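"""Pathway-entity (IPL) parsing, feature-pathway correlation, differential tests.

Integrated Pathway Levels (IPLs) are per-sample activities of pathway
entities inferred from expression and copy number; entity ids follow the
Firehose PARADIGM dialect ``<pathwayIndex>_<concept>`` (e.g. ``19_EPHB3``).
Image features are related to entities by Pearson correlation with global
Benjamini-Hochberg control over all feature x entity pairs, and entities are
tested for differential activity between subgroups with a moderated
(empirical-Bayes) t-statistic: per-entity variances are shrunk toward a
pooled prior whose scale and degrees of freedom are estimated from all
entities by moment matching on log-variances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, GroupSizeError, IPLParseError, ParameterError

__all__ = [
    "IPLMatrix",
    "parse_ipl",
    "write_ipl",
    "bh_adjust",
    "correlate",
    "moderated_t",
    "differential_ipl",
    "fit_variance_prior",
]

_ID_RE = re.compile(r"^(\d+)_(.+)$")


@dataclass
class IPLMatrix:
    """Entities x samples activity matrix with parsed entity annotation."""

    values: pd.DataFrame  # index entity_id, columns sample ids
    pathway_index: pd.Series
    concept: pd.Series

    @property
    def entity_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def _parse_ids(ids) -> tuple:
    pathway, concept = [], []
    for eid in ids:
        m = _ID_RE.match(str(eid))
        if not m:
            raise IPLParseError(
                f"entity id {eid!r} lacks the '<integer>_<concept>' form"
            )
        pathway.append(int(m.group(1)))
        concept.append(m.group(2))
    return pathway, concept


def ipl_from_frame(df: pd.DataFrame) -> IPLMatrix:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise IPLParseError(f"duplicate entity id {dup!r}")
    pathway, concept = _parse_ids(df.index)
    return IPLMatrix(
        values=df.astype(float),
        pathway_index=pd.Series(pathway, index=df.index),
        concept=pd.Series(concept, index=df.index),
    )


def parse_ipl(path) -> IPLMatrix:
    """Read a tab-delimited entity x sample matrix (first column entity id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ipl_from_frame(df)


def write_ipl(ipl: IPLMatrix, path) -> None:
    df = ipl.values.copy()
    df.index.name = "entity_id"
    df.to_csv(path, sep="\t")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate(features, ipl: IPLMatrix, threshold: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of every feature with every pathway entity.

    ``features`` is a samples x features DataFrame. Correlations are computed
    on the shared samples; p-values are two-sided and BH-adjusted globally
    over all pairs. Constant columns get r = 0, p = 1. Returns a tidy frame
    (feature, entity_id, r, p, p_adjusted, significant) with a
    ``fraction_features_significant`` attribute: the share of features having
    at least one significant entity.
    """
    if not isinstance(features, pd.DataFrame):
        raise ParameterError("features must be a samples x features DataFrame")
    shared = features.index.intersection(ipl.values.columns)
    if len(shared) < 3:
        raise AlignmentError(f"only {len(shared)} shared samples; need >= 3")
    F = features.loc[shared].to_numpy(float)  # (n, f)
    E = ipl.values[shared].to_numpy(float).T  # (n, e)
    n = len(shared)
    Fz = F - F.mean(axis=0)
    Ez = E - E.mean(axis=0)
    fs = np.sqrt((Fz**2).sum(axis=0))
    es = np.sqrt((Ez**2).sum(axis=0))
    fs_safe = np.where(fs > 0, fs, 1.0)
    es_safe = np.where(es > 0, es, 1.0)
    R = (Fz / fs_safe).T @ (Ez / es_safe)
    R[fs == 0, :] = 0.0
    R[:, es == 0] = 0.0
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / np.maximum(1 - R**2, 1e-300))
    P = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    P[fs == 0, :] = 1.0
    P[:, es == 0] = 1.0
    padj = bh_adjust(P.ravel()).reshape(P.shape)
    feat_names = np.repeat(features.columns.to_numpy(), E.shape[1])
    ent_names = np.tile(np.asarray(ipl.entity_ids), F.shape[1])
    out = pd.DataFrame(
        {
            "feature": feat_names,
            "entity_id": ent_names,
            "r": R.ravel(),
            "p": P.ravel(),
            "p_adjusted": padj.ravel(),
        }
    )
    out["significant"] = out["p_adjusted"] <= threshold
    sig_by_feature = out.groupby("feature")["significant"].any()
    out.attrs["fraction_features_significant"] = float(sig_by_feature.mean())
    out.attrs["n_shared_samples"] = n
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the log scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple:
    """Moment-match a scaled-F marginal to observed variances.

    Under the hierarchical model ``s2 ~ s0^2 * F(df, d0)``, log-variances
    have mean ``log s0^2 + psi(df/2) - psi(d0/2) + log(d0/df)`` and variance
    ``psi'(df/2) + psi'(d0/2)``. Returns ``(s0_squared, d0)``; ``d0`` may be
    ``inf`` when observed variances are no more dispersed than sampling
    noise alone.
    """
    s2 = np.asarray(s2, float)
    s2 = np.clip(s2, 1e-300, None)
    e = np.log(s2)
    excess = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        log_s0 = e.mean() - special.digamma(df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            e.mean()
            - special.digamma(df / 2.0)
            + special.digamma(d0 / 2.0)
            - np.log(d0 / df)
        )
    return float(np.exp(log_s0)), float(d0)


def moderated_t(values, group_mask, prior_df: float | None = None) -> pd.DataFrame:
    """Two-group moderated t per row of an entities x samples matrix.

    ``group_mask`` is a boolean per-sample vector (True = group A). Pooled
    per-row variances are shrunk toward the moment-matched prior:
    ``s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)``, and the t statistic is
    referred to a t distribution with ``d + d0`` degrees of freedom. Passing
    ``prior_df=0`` recovers the ordinary pooled-variance t-test.
    """
    V = values.to_numpy(float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    idx = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(V.shape[0])
    mask = np.asarray(group_mask, bool)
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise GroupSizeError(f"both groups need >= 2 samples, got {n1} and {n2}")
    d = n1 + n2 - 2
    m1 = V[:, mask].mean(axis=1)
    m2 = V[:, ~mask].mean(axis=1)
    ss1 = ((V[:, mask] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((V[:, ~mask] - m2[:, None]) ** 2).sum(axis=1)
    s2 = (ss1 + ss2) / d
    if prior_df is None:
        s0_sq, d0 = fit_variance_prior(s2, d)
    elif prior_df == 0:
        s0_sq, d0 = 1.0, 0.0
    else:
        d0 = float(prior_df)
        s0_sq, _ = fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d + d0
    effect = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return pd.DataFrame(
        {"effect": effect, "t": t, "df": df_total, "p": p}, index=idx
    )


def differential_ipl(
    ipl: IPLMatrix,
    groups,
    threshold: float = 0.1,
    method: str = "moderated",
) -> pd.DataFrame:
    """Test every entity for differential activity between two subgroups.

    ``groups`` is a per-sample label vector aligned with ``ipl.sample_ids``
    (exactly two distinct labels). ``method`` is "moderated"
    (empirical-Bayes, default) or "welch".
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise GroupSizeError(f"need exactly 2 groups, got {list(uniq)}")
    mask = groups == uniq[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise GroupSizeError("both groups need >= 2 samples")
    V = ipl.values
    if method == "moderated":
        res = moderated_t(V, mask)
    elif method == "welch":
        a = V.to_numpy(float)[:, mask]
        b = V.to_numpy(float)[:, ~mask]
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        res = pd.DataFrame(
            {"effect": a.mean(axis=1) - b.mean(axis=1), "t": t, "df": np.nan, "p": p},
            index=V.index,
        )
    else:
        raise ParameterError(f"unknown method {method!r}")
    res["p_adjusted"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["p_adjusted"] <= threshold
    res["pathway_index"] = ipl.pathway_index
    res["concept"] = ipl.concept
    return res
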