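"""Handcrafted-radiomics evaluation: feature filtering, drift, and ROC.

The pipeline mirrors the standard radiomics modeling recipe: remove highly
correlated features (greedy, threshold on |Pearson r|), screen the
remainder by rank association with the outcome (Kendall tau-b), fit any
scorer on the surviving features, and compare validation ROC curves between
datasets with a paired bootstrap.  Feature drift induced by generative
translation is quantified per subject and feature as the absolute
percentage difference between the pre- and post-translation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

__all__ = [
    "drop_correlated",
    "kendall_select",
    "abs_pct_diff",
    "DriftResult",
    "roc_auc",
    "bootstrap_auc_compare",
    "PenalizedLinearScorer",
    "first_order_features",
]


def first_order_features(values: np.ndarray, masks: dict[str, np.ndarray]) -> dict[str, float]:
    """First-order intensity statistics per region mask.

    A lightweight stand-in radiomics panel (mean, SD, percentiles, energy)
    sufficient to exercise feature selection, drift and ROC machinery on
    phantom data; full texture/wavelet panels plug in as external tables.
    """
    values = np.asarray(values, dtype=float)
    out: dict[str, float] = {}
    for region, mask in masks.items():
        v = values[np.asarray(mask, dtype=bool)]
        if v.size == 0:
            raise ValueError(f"region {region!r} mask is empty")
        out[f"{region}_mean"] = float(v.mean())
        out[f"{region}_sd"] = float(v.std())
        out[f"{region}_p10"] = float(np.percentile(v, 10))
        out[f"{region}_median"] = float(np.median(v))
        out[f"{region}_p90"] = float(np.percentile(v, 90))
        out[f"{region}_energy"] = float(np.mean(v**2))
    return out


def drop_correlated(table: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Remove features until no pair exceeds ``threshold`` absolute correlation.

    Greedy: repeatedly take the worst-correlated pair and drop the member
    with the larger mean absolute correlation to all remaining features
    (lexicographic tie-break on feature name).  Zero-variance columns are
    removed first with a warning.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two features")
    work = table.copy()
    constant = [c for c in work.columns if work[c].nunique() <= 1]
    if constant:
        warnings.warn(f"removing zero-variance features: {constant}")
        work = work.drop(columns=constant)
    if work.shape[1] < 2 or threshold >= 1.0:
        return work
    corr = work.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    while True:
        max_val = corr.values.max()
        if max_val <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # lexicographic tie-break: keep the earlier name
        corr = corr.drop(index=drop, columns=drop)
        work = work.drop(columns=drop)
    return work


def kendall_select(
    table: pd.DataFrame, labels, threshold: float = 0.2
) -> pd.DataFrame:
    """Keep features whose |Kendall tau-b| with the binary label >= threshold."""
    y = np.asarray(labels, dtype=float).ravel()
    if len(y) != len(table):
        raise ValueError("labels must align with the feature table rows")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; rank association is undefined")
    keep = []
    for col in table.columns:
        tau = sstats.kendalltau(table[col].to_numpy(), y, variant="b").statistic
        if np.isfinite(tau) and abs(tau) >= threshold:
            keep.append(col)
    return table[keep]


@dataclass
class DriftResult:
    """Per-subject/feature drift plus zero-denominator bookkeeping."""

    drift: pd.DataFrame  # percent values; NaN where the pre value was 0
    excluded: pd.Series  # per feature: subjects excluded for pre == 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "median_pct": self.drift.median(),
                "mean_pct": self.drift.mean(),
                "max_pct": self.drift.max(),
                "n_excluded": self.excluded,
            }
        )


def abs_pct_diff(pre: pd.DataFrame, post: pd.DataFrame) -> DriftResult:
    """Absolute percentage difference ``100 |post - pre| / |pre|``.

    Cells with ``pre == 0`` are excluded from that feature's distribution
    and counted in the excluded tally instead of being substituted.
    """
    if list(pre.index) != list(post.index) or list(pre.columns) != list(post.columns):
        missing_rows = set(pre.index).symmetric_difference(post.index)
        missing_cols = set(pre.columns).symmetric_difference(post.columns)
        raise ValueError(
            "pre/post tables misaligned; differing subjects "
            f"{sorted(missing_rows)} and features {sorted(missing_cols)}"
        )
    pre_v = pre.to_numpy(dtype=float)
    post_v = post.to_numpy(dtype=float)
    zero = pre_v == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(post_v - pre_v) / np.abs(pre_v)
    pct[zero] = np.nan
    drift = pd.DataFrame(pct, index=pre.index, columns=pre.columns)
    excluded = pd.Series(zero.sum(axis=0), index=pre.columns, name="n_excluded")
    return DriftResult(drift=drift, excluded=excluded)


def roc_auc(scores, labels) -> float:
    """Rank-statistic AUC (Mann-Whitney; ties count one half)."""
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, s))


def bootstrap_auc_compare(
    scores1,
    scores2,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Paired stratified bootstrap comparison of two ROC curves.

    Both score vectors refer to the same subjects.  Positives and negatives
    are resampled separately (both classes always present), the AUC
    difference recomputed per resample, and a two-sided p-value taken from
    the normal approximation to the resampled difference distribution, as
    in the common ROC-comparison bootstrap.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} is small; p-value will be unstable")
    y = np.asarray(labels, dtype=float).ravel()
    s1 = np.asarray(scores1, dtype=float).ravel()
    s2 = np.asarray(scores2, dtype=float).ravel()
    if not (len(s1) == len(s2) == len(y)):
        raise ValueError("scores and labels must be paired on the same subjects")
    delta = roc_auc(s1, y) - roc_auc(s2, y)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == np.max(y))
    neg = np.flatnonzero(y != np.max(y))
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        diffs[i] = roc_auc(s1[idx], y[idx]) - roc_auc(s2[idx], y[idx])
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2.0 * sstats.norm.sf(abs(delta) / sd))
    return {"delta_auc": float(delta), "p_value": p, "n_boot": n_boot}


class PenalizedLinearScorer:
    """Built-in scorer: L2-penalized logistic regression.

    Any object with ``fit(X, y)`` and ``decision_function(X)`` (or
    ``predict_proba``) satisfies the scorer contract used by the drift and
    ROC comparisons; external model families plug in the same way.
    """

    def __init__(self, c: float = 1.0, seed: int = 0) -> None:
        from sklearn.linear_model import LogisticRegression

        self.model = LogisticRegression(C=c, max_iter=2000, random_state=seed)

    def fit(self, x: pd.DataFrame, y) -> "PenalizedLinearScorer":
        self.model.fit(np.asarray(x, dtype=float), np.asarray(y).ravel())
        return self

    def scores(self, x: pd.DataFrame) -> np.ndarray:
        return self.model.decision_function(np.asarray(x, dtype=float))
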