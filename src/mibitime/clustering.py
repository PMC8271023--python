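"""Patient stratification: feature scaling, hierarchical clustering, and
silhouette-guided choice of the number of clusters.

Features (flattened pair-count matrices, composition vectors, ...) are
z-scored across patients, clustered agglomeratively (Ward linkage on
Euclidean distance by default), and the tree is cut at the k maximising
the mean silhouette — parsimony breaks ties toward smaller k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)


@dataclass
class CohortFeatures:
    """Patients × features matrix with scaling bookkeeping."""

    values: pd.DataFrame
    standardized: bool = False
    dropped_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("missing values in cohort features")


@dataclass
class ClusterAssignment:
    """Deterministic cluster labels (1..k) plus selection diagnostics."""

    labels: pd.Series  # patient_id -> label in 1..k
    k: int
    linkage_tree: np.ndarray
    silhouettes: dict[int, float] = field(default_factory=dict)

    def groups(self) -> dict[int, list[str]]:
        return {
            int(lbl): list(self.labels.index[self.labels == lbl])
            for lbl in sorted(self.labels.unique())
        }


def standard_scale(features: pd.DataFrame) -> CohortFeatures:
    """Column z-scores with the population standard deviation.

    Zero-variance columns carry no between-patient information and are
    dropped (logged).
    """
    if len(features) < 2:
        raise ValueError("standard scaling needs at least 2 patients")
    mu = features.mean(axis=0)
    sd = features.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = tuple(features.columns[~keep])
    if dropped:
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped[:5])
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    scaled = (features.loc[:, keep] - mu[keep]) / sd[keep]
    return CohortFeatures(values=scaled, standardized=True, dropped_columns=dropped)


def hierarchical_cluster(
    features: CohortFeatures | pd.DataFrame,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> np.ndarray:
    """Agglomerative linkage tree (scipy linkage matrix)."""
    X = features.values if isinstance(features, CohortFeatures) else features
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        raise ValueError("clustering needs at least 2 patients")
    return hierarchy.linkage(X, method=linkage, metric=metric)


def mean_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over samples; singleton clusters score 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2 or len(uniq) >= len(labels):
        # all-singleton or single-cluster cuts are defined as 0
        return 0.0
    return float(np.mean(silhouette_samples(X, labels)))


def cut_tree(
    tree: np.ndarray, k: int, patient_ids: Sequence[str]
) -> pd.Series:
    """Cut the linkage tree into exactly k clusters.

    Labels are renumbered 1..k by order of first patient appearance so the
    assignment is stable under any internal labelling scipy chooses.
    """
    n = len(patient_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # maxclust may undershoot on ties; fall back to cutting by height rank
        raw = hierarchy.cut_tree(tree, n_clusters=k).ravel() + 1
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        out[i] = remap[r]
    return pd.Series(out, index=list(patient_ids), name="cluster")


def silhouette_select_k(
    tree: np.ndarray,
    features: CohortFeatures | pd.DataFrame,
    k_range: Iterable[int] = range(2, 7),
) -> tuple[int, dict[int, float]]:
    """Mean silhouette for each candidate k; argmax wins, ties → smallest k."""
    df = features.values if isinstance(features, CohortFeatures) else features
    X = np.asarray(df, dtype=float)
    n = len(X)
    scores: dict[int, float] = {}
    for k in sorted(set(k_range)):
        if not 2 <= k <= n - 1:
            continue
        labels = cut_tree(tree, k, list(range(n))).to_numpy()
        scores[k] = mean_silhouette(X, labels)
    if not scores:
        raise ValueError("no valid k in range")
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def cluster_cohort(
    features: pd.DataFrame,
    k: int | None = None,
    k_range: Iterable[int] = range(2, 7),
    linkage: str = "ward",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Scale → cluster → (optionally) silhouette-select k → cut.

    Convenience wrapper running the full stratification used for every
    feature family (co-expression, interactions, subsets).
    """
    scaled = standard_scale(features)
    tree = hierarchical_cluster(scaled, linkage=linkage, metric=metric)
    silhouettes: dict[int, float] = {}
    if k is None:
        k, silhouettes = silhouette_select_k(tree, scaled, k_range)
    labels = cut_tree(tree, k, list(features.index))
    return ClusterAssignment(labels=labels, k=k, linkage_tree=tree, silhouettes=silhouettes)
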