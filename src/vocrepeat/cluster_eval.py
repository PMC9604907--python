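"""Clustering concordance and the effect of removing erratic features.

Samples are clustered with K-means (Lloyd, k-means++ seeding, best of 10
restarts) and Ward hierarchical agglomeration on Euclidean distances, with k
fixed to the number of subjects.  Concordance between predicted clusters and
subject identity is scored by the Adjusted Rand Index and the
Fowlkes-Mallows score; cluster distinctness by the mean silhouette
coefficient of the *predicted* labels.  The comparison of interest is (all
features) vs (features not categorised Erratic): concordance should be
preserved while silhouettes sharpen.

Clustering operates on the fully normalised (log + min-max) matrix.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn import metrics
from sklearn.cluster import KMeans


def kmeans_cluster(values, k: int, seed: int = 0, n_init: int = 10, max_iter: int = 300):
    """K-means labels; deterministic given the seed."""
    X = np.asarray(values, float)
    if not 1 <= k <= X.shape[0]:
        raise ValueError("k must lie in [1, n_samples]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
                random_state=seed)
    return km.fit_predict(X)


def kmeans_inertia(values, k: int, seed: int = 0, n_init: int = 1, max_iter: int = 300) -> float:
    """Best inertia reached; exposed so Lloyd monotonicity can be probed."""
    X = np.asarray(values, float)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
                random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def ward_cluster(values, k: int):
    """Ward agglomeration on Euclidean distances, tree cut at k clusters."""
    X = np.asarray(values, float)
    if not 1 <= k <= X.shape[0]:
        raise ValueError("k must lie in [1, n_samples]")
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement in [-1, 1]."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(metrics.adjusted_rand_score(a, b))


def fowlkes_mallows(labels_a, labels_b) -> float:
    """Geometric mean of pairwise precision and recall, in [0, 1].

    Two all-singleton partitions agree perfectly and score 1 by convention.
    """
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if len(np.unique(a)) == n and len(np.unique(b)) == n:
        return 1.0
    return float(metrics.fowlkes_mallows_score(a, b))


def silhouette(values, labels) -> float:
    """Mean silhouette coefficient; singleton clusters contribute 0."""
    X = np.asarray(values, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(metrics.silhouette_samples(X, labels).mean())


@dataclass
class ClusterEvalResult:
    algorithm: str  # kmeans | ward
    feature_set: str  # all | non_erratic
    k: int
    n_features: int
    ari: float
    fowlkes_mallows: float
    silhouette: float
    seed: int


def compare_feature_sets(
    values: pd.DataFrame,
    profile: pd.DataFrame,
    subjects: pd.Series,
    seed: int = 0,
) -> list[ClusterEvalResult]:
    """Cluster on all vs non-Erratic features with both algorithms.

    ``values`` is the normalised samples x features matrix and ``profile``
    the variance profile covering all of its features.  k is the number of
    distinct subjects.  ARI and Fowlkes-Mallows are scored against subject
    identity; silhouette on the predicted labels.
    """
    missing = set(values.columns) - set(profile.index)
    if missing:
        raise ValueError(f"profile does not cover features: {sorted(missing)[:5]}...")
    non_erratic = [f for f in values.columns if profile.loc[f, "category"] != "Erratic"]
    if not non_erratic:
        raise ValueError("no non-Erratic features remain")
    subject_labels = subjects.loc[values.index].to_numpy()
    k = len(np.unique(subject_labels))

    results = []
    for set_name, cols in (("all", list(values.columns)), ("non_erratic", non_erratic)):
        X = values[cols]
        for algorithm in ("kmeans", "ward"):
            if algorithm == "kmeans":
                pred = kmeans_cluster(X, k, seed=seed)
            else:
                pred = ward_cluster(X, k)
            results.append(
                ClusterEvalResult(
                    algorithm=algorithm,
                    feature_set=set_name,
                    k=k,
                    n_features=len(cols),
                    ari=adjusted_rand_index(pred, subject_labels),
                    fowlkes_mallows=fowlkes_mallows(pred, subject_labels),
                    silhouette=silhouette(X, pred),
                    seed=seed,
                )
            )
    return results


def results_frame(results: list[ClusterEvalResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])
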