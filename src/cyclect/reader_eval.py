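"""Modified-Turing-test statistics for expert reader studies.

Readers blindly classify a mix of acquired and synthetic CT slices.  The
positive class is fixed as "acquired/real", so a reader's sensitivity is
their hit rate on acquired slices and their specificity is their accuracy
on synthetic ones; the rate at which synthetic images are mistaken for real
is ``1 - specificity``.  Inter-rater agreement is summarized with Fleiss'
kappa computed from the item-by-category rating-count matrix:

    kappa = (P_bar - P_bar_e) / (1 - P_bar_e)

where ``P_bar`` is the mean observed pairwise agreement per item and
``P_bar_e`` the chance agreement implied by the marginal category
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReaderConfusion",
    "RatingMatrix",
    "confusion_from_rates",
    "reader_metrics",
    "panel_summary",
    "fleiss_kappa",
    "fleiss_kappa_z",
    "ratings_from_long",
    "simulate_ratings",
]

_INT_TOL = 1e-9


@dataclass(frozen=True)
class ReaderConfusion:
    """Counts for one reader; positive class = acquired (real) image."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


def confusion_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ReaderConfusion:
    """Reconstruct a confusion table from published rates and class sizes."""
    for name, r in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    tp_f = sensitivity * n_pos
    tn_f = specificity * n_neg
    for name, v in (("sensitivity * n_pos", tp_f), ("specificity * n_neg", tn_f)):
        if abs(v - round(v)) > _INT_TOL:
            raise ValueError(
                f"{name} = {v} is not an integer count; rates inconsistent with class sizes"
            )
    tp, tn = int(round(tp_f)), int(round(tn_f))
    return ReaderConfusion(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


def reader_metrics(c: ReaderConfusion) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, single-operating-point AUC, FPR.

    A binary rater defines one point on the ROC plane, so the AUC of the
    implied two-segment curve is ``(sensitivity + specificity) / 2``.
    """
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("confusion must contain both classes")
    sens = c.tp / c.n_pos
    spec = c.tn / c.n_neg
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "sensitivity": sens,
        "specificity": spec,
        "auc": (sens + spec) / 2.0,
        "fpr": c.fp / c.n_neg,
    }


def panel_summary(confusions: list[ReaderConfusion]) -> dict[str, float]:
    """Unweighted panel means: accuracy, its range, and the rate at which
    synthetic images were called real (mean of ``1 - specificity``)."""
    if not confusions:
        raise ValueError("need at least one reader")
    metrics = [reader_metrics(c) for c in confusions]
    accs = np.array([m["accuracy"] for m in metrics])
    fprs = np.array([m["fpr"] for m in metrics])
    return {
        "mean_accuracy": float(accs.mean()),
        "accuracy_min": float(accs.min()),
        "accuracy_max": float(accs.max()),
        "mean_fpr_on_synthetic": float(fprs.mean()),
    }


@dataclass(frozen=True)
class RatingMatrix:
    """Item-by-category rating counts: ``counts[i, j]`` raters chose j."""

    counts: np.ndarray
    n_raters: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("rating matrix must be N x k with N >= 2, k >= 2")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("rating counts must be non-negative integers")
        if np.any(counts.sum(axis=1) != self.n_raters):
            raise ValueError(f"every row must sum to the rater count {self.n_raters}")


def ratings_from_long(table: pd.DataFrame) -> RatingMatrix:
    """Pivot a long table (item_id, reader_id, category) into a RatingMatrix."""
    required = {"item_id", "reader_id", "category"}
    if not required.issubset(table.columns):
        raise ValueError(f"rating table needs columns {sorted(required)}")
    pivot = pd.crosstab(table["item_id"], table["category"])
    n_raters = table.groupby("item_id")["reader_id"].nunique()
    if n_raters.nunique() != 1:
        raise ValueError("all items must be rated by the same number of readers")
    return RatingMatrix(pivot.to_numpy(dtype=int), int(n_raters.iloc[0]))


def fleiss_kappa(r: RatingMatrix) -> dict[str, float]:
    """Fleiss' kappa with its observed and chance agreement components."""
    counts = np.asarray(r.counts, dtype=float)
    big_n, _ = counts.shape
    n = r.n_raters
    if n < 2:
        raise ValueError("Fleiss' kappa needs at least two raters per item")
    p_bar = float(np.sum(counts * (counts - 1)) / (big_n * n * (n - 1)))
    p_j = counts.sum(axis=0) / (big_n * n)
    p_bar_e = float(np.sum(p_j**2))
    if p_bar_e >= 1.0 - 1e-12:
        raise ZeroDivisionError(
            "all ratings fall in a single category: chance agreement is 1 and kappa is undefined"
        )
    return {
        "kappa": (p_bar - p_bar_e) / (1.0 - p_bar_e),
        "p_bar": p_bar,
        "p_bar_e": p_bar_e,
    }


def simulate_ratings(
    reader_rates: list[tuple[float, float]],
    n_pos: int,
    n_neg: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[ReaderConfusion]]:
    """Simulate a blinded rating table for a panel of readers.

    Each reader independently calls an acquired item "real" with their
    sensitivity and a synthetic item "synthetic" with their specificity.
    Returns the long table (item_id, reader_id, category) and the realized
    per-reader confusions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    realized = []
    truth = ["real"] * n_pos + ["synthetic"] * n_neg
    for r, (sens, spec) in enumerate(reader_rates):
        tp = fp = tn = fn = 0
        for i, t in enumerate(truth):
            if t == "real":
                call = "real" if rng.random() < sens else "synthetic"
                tp += call == "real"
                fn += call == "synthetic"
            else:
                call = "synthetic" if rng.random() < spec else "real"
                tn += call == "synthetic"
                fp += call == "real"
            rows.append({"item_id": f"item{i:04d}", "reader_id": f"reader{r}", "category": call})
        realized.append(ReaderConfusion(tp=tp, fn=fn, tn=tn, fp=fp))
    return pd.DataFrame(rows), realized


def fleiss_kappa_z(r: RatingMatrix) -> dict[str, float]:
    """Large-sample z statistic for kappa under the null of chance agreement.

    Uses the standard Fleiss variance.  Provided for convenience; reported
    reader studies rarely publish the raw rating matrix needed to check it.
    """
    counts = np.asarray(r.counts, dtype=float)
    big_n, _ = counts.shape
    n = r.n_raters
    stats = fleiss_kappa(r)
    p_j = counts.sum(axis=0) / (big_n * n)
    pe = float(np.sum(p_j**2))
    var = (2.0 / (big_n * n * (n - 1))) * (
        (pe - (2 * n - 3) * pe**2 + 2 * (n - 2) * np.sum(p_j**3)) / (1 - pe) ** 2
    )
    z = stats["kappa"] / np.sqrt(var)
    return {**stats, "z": float(z), "var": float(var)}
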