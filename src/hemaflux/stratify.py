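"""Feature matrices, clustering and the chimerism-ratio ROC scan.

Influx feature matrices are first max-scaled per quantity to [0, 1] and then
z-scored within each individual; chimerism matrices are z-scored within each
individual directly.  Individuals are grouped by complete-linkage
hierarchical clustering (Euclidean distance) or k-means (k = 3 by default).

The ROC scan sweeps every ordered lineage pair and observation week, scoring
each mouse by the ratio of the two lineages' chimerism at that week
(censored values entering at the detection limit) against the stable/dropped
bypass classes, and ranks the features by area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

__all__ = [
    "FeatureMatrix",
    "RocResult",
    "WithinIndividualScaler",
    "normalize_influx_matrix",
    "normalize_chimerism_matrix",
    "hclust_complete",
    "kmeans_groups",
    "auc_threshold_sweep",
    "ratio_feature_scan",
    "DEFAULT_SCAN_WEEKS",
]

DEFAULT_SCAN_WEEKS: Tuple[float, ...] = (2.0, 3.0, 4.0, 8.0, 12.0, 16.0, 24.0)


@dataclass
class FeatureMatrix:
    """Individuals x (quantity, week) matrix with labels."""

    values: np.ndarray
    row_labels: List[str]
    col_labels: List[Tuple[str, float]]  # (quantity, week)
    excluded: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{q}@{w:g}" for q, w in self.col_labels]
        return pd.DataFrame(self.values, index=self.row_labels, columns=cols)


class WithinIndividualScaler(BaseEstimator, TransformerMixin):
    """Z-score each row (individual) to mean 0, variance 1.

    Rows with zero variance map to all zeros.  Stateless (each row is
    standardized against itself), so ``fit`` only validates input.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return out


def _pivot(records: pd.DataFrame, value_col: str, quantity_col: str) -> pd.DataFrame:
    return records.pivot_table(
        index="individual_id", columns=[quantity_col, "week"], values=value_col, aggfunc="first"
    )


def normalize_influx_matrix(influx_records: pd.DataFrame) -> FeatureMatrix:
    """Influx feature matrix: per-quantity max-scaling then row z-scoring.

    ``influx_records`` is the long table written by
    :meth:`hemaflux.bypass.InfluxSeries.to_frame` for a set of individuals
    (columns individual_id, week, quantity, value).  Quantities that are zero
    everywhere are dropped with a warning attached to ``excluded``.
    """
    wide = _pivot(influx_records, "value", "quantity")
    dropped: List[str] = []
    for quantity in wide.columns.get_level_values(0).unique():
        block = wide[quantity]
        mx = np.nanmax(block.to_numpy()) if block.size else 0.0
        if not np.isfinite(mx) or mx <= 0:
            wide = wide.drop(columns=quantity, level=0)
            dropped.append(str(quantity))
        else:
            wide[quantity] = block / mx
    values = WithinIndividualScaler().fit_transform(wide.to_numpy())
    return FeatureMatrix(
        values=values,
        row_labels=[str(i) for i in wide.index],
        col_labels=[(str(q), float(w)) for q, w in wide.columns],
        excluded=dropped,
    )


def normalize_chimerism_matrix(
    obs: pd.DataFrame, weeks: Sequence[float] = DEFAULT_SCAN_WEEKS
) -> FeatureMatrix:
    """Chimerism feature matrix z-scored within individuals.

    Censored values enter at the detection limit (they are stored that way).
    Individuals missing any requested (lineage, week) entry are excluded and
    reported in ``excluded``.
    """
    chim = obs[obs["kind"] == "chimerism"]
    chim = chim[chim["week"].isin([float(w) for w in weeks])]
    wide = _pivot(chim, "value", "lineage")
    complete = wide.dropna()
    excluded = sorted(set(map(str, wide.index)) - set(map(str, complete.index)))
    values = WithinIndividualScaler().fit_transform(complete.to_numpy())
    return FeatureMatrix(
        values=values,
        row_labels=[str(i) for i in complete.index],
        col_labels=[(str(q), float(w)) for q, w in complete.columns],
        excluded=excluded,
    )


def hclust_complete(
    matrix: FeatureMatrix, k: Optional[int] = None, height: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Complete-linkage hierarchical clustering with Euclidean distance.

    Returns ``(labels, merge_tree)`` where the merge tree is the scipy
    linkage matrix.  Provide ``k`` (number of clusters) or ``height`` (cut
    distance); with neither, every row is its own cluster label.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    if X.shape[0] < 1:
        raise ValueError("need at least one row")
    if X.shape[0] == 1:
        return np.array([1]), np.empty((0, 4))
    Z = linkage(X, method="complete", metric="euclidean")
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        labels = np.arange(1, X.shape[0] + 1)
    return labels, Z


def kmeans_groups(matrix: FeatureMatrix, k: int = 3, seed: int = 0, n_restarts: int = 50) -> np.ndarray:
    """K-means labels (default k = 3), best inertia over seeded restarts."""
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(X)


@dataclass
class RocResult:
    """ROC curve and AUC of one candidate feature."""

    feature: Tuple[str, str, float]  # (numerator lineage, denominator lineage, week)
    auc: float
    curve: np.ndarray  # ordered (FPR, TPR) points
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


def auc_threshold_sweep(scores: Sequence[float], labels: Sequence[bool], feature=("", "", 0.0)) -> RocResult:
    """ROC by sweeping every score threshold; AUC by the trapezoid rule.

    ``labels`` are True for the positive class; higher scores vote positive.
    Tied scores enter the curve simultaneously, which makes the AUC equal to
    the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group ties: advance over blocks of equal score
    boundaries = np.flatnonzero(np.diff(s)) + 1
    blocks = np.split(np.arange(len(s)), boundaries)
    tps = [0]
    fps = [0]
    thresholds = [np.inf]
    tp = fp = 0
    for block in blocks:
        tp += int(y[block].sum())
        fp += int(len(block) - y[block].sum())
        tps.append(tp)
        fps.append(fp)
        thresholds.append(s[block[-1]])
    tpr = np.array(tps) / n_pos
    fpr = np.array(fps) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    curve = np.column_stack([fpr, tpr])
    return RocResult(
        feature=feature, auc=auc, curve=curve, thresholds=np.array(thresholds), n_pos=n_pos, n_neg=n_neg
    )


def ratio_feature_scan(
    obs: pd.DataFrame,
    classes: Dict[str, str],
    weeks: Sequence[float] = DEFAULT_SCAN_WEEKS,
    lineages: Optional[Sequence[str]] = None,
    detection_floor: float = 0.001,
    positive_class: str = "stable",
) -> List[RocResult]:
    """Exhaustive scan of chimerism-ratio features against bypass classes.

    For every ordered lineage pair (numerator, denominator) and week, each
    mouse is scored by numerator/denominator chimerism (floored at the
    detection limit) and the score's ROC against ``classes`` (mapping
    individual_id to "stable"/"dropped", or any two labels with
    ``positive_class`` naming the positive one) is computed.  Results are
    ranked by AUC, ties broken by feature name for reproducibility.  Both
    ratio directions are scanned with the fixed orientation "higher score
    means positive class".
    """
    chim = obs[obs["kind"] == "chimerism"].copy()
    chim = chim[chim["individual_id"].isin(classes.keys())]
    if lineages is None:
        lineages = sorted(chim["lineage"].unique())
    chim["value"] = chim["value"].clip(lower=detection_floor)
    wide = chim.pivot_table(index="individual_id", columns=["lineage", "week"], values="value", aggfunc="first")
    results: List[RocResult] = []
    for num in lineages:
        for den in lineages:
            if num == den:
                continue
            for w in weeks:
                w = float(w)
                if (num, w) not in wide.columns or (den, w) not in wide.columns:
                    continue
                sub = wide[[(num, w), (den, w)]].dropna()
                ids = [str(i) for i in sub.index]
                y = np.array([classes[i] == positive_class for i in ids])
                if y.all() or not y.any():
                    continue
                scores = sub[(num, w)].to_numpy() / sub[(den, w)].to_numpy()
                results.append(auc_threshold_sweep(scores, y, feature=(str(num), str(den), w)))
    results.sort(key=lambda r: (-r.auc, r.feature))
    return results


def roc_results_to_frame(results: Sequence[RocResult]) -> pd.DataFrame:
    rows = [
        (r.feature[0], r.feature[1], r.feature[2], r.auc, r.n_pos, r.n_neg)
        for r in results
    ]
    return pd.DataFrame(rows, columns=["numerator", "denominator", "week", "auc", "n_pos", "n_neg"])
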