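"""Cluster-based undersampling of the majority class.

Binding screens are dominated by non-binders, so a classifier trained on the
raw grid collapses toward the negative class. Rather than discarding majority
samples at random, the majority class is clustered with k-means++ into as
many clusters as there are minority samples and each cluster contributes its
most central member. The result is an exactly balanced training set made
entirely of original samples (no synthetic points), chosen to preserve the
majority class's spread in feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .featureblock import FeatureBlock

logger = logging.getLogger(__name__)


@dataclass
class UndersampleResult:
    """Indices kept after undersampling, with bookkeeping for diagnostics."""

    kept_indices: np.ndarray
    n_majority_before: int
    n_majority_after: int
    cluster_assignments: dict[int, int]  # original majority index -> cluster


def cluster_undersample(
    features, labels, seed: int = 0
) -> UndersampleResult:
    """Balance a binary dataset by keeping k-means++ representatives of the majority.

    Parameters
    ----------
    features : FeatureBlock or ndarray
        Feature rows aligned with ``labels``. Rows are standardized to zero
        mean / unit variance (computed on the majority class) before
        clustering, since Euclidean k-means is scale-sensitive.
    labels : array-like of shape (n,)
        Binary labels (any two distinct values).
    seed : int
        Seeds k-means++ initialization; identical seeds give identical
        selections.

    Returns
    -------
    UndersampleResult
        ``kept_indices`` is sorted and contains every minority sample plus
        one majority sample per cluster — the one nearest its centroid,
        ties broken by smallest original index.
    """
    if isinstance(features, FeatureBlock):
        x = features.values
    else:
        x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"features ({x.shape[0]} rows) and labels ({y.shape[0]}) misaligned"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(
            f"need exactly two classes with samples, got {len(classes)}"
        )
    minority_cls = classes[np.argmin(counts)]
    majority_cls = classes[np.argmax(counts)]
    min_idx = np.flatnonzero(y == minority_cls)
    maj_idx = np.flatnonzero(y == majority_cls)
    n_min, n_maj = len(min_idx), len(maj_idx)

    if n_min >= n_maj:
        logger.warning(
            "minority (%d) >= majority (%d); nothing to undersample", n_min, n_maj
        )
        return UndersampleResult(
            kept_indices=np.arange(len(y)),
            n_majority_before=n_maj,
            n_majority_after=n_maj,
            cluster_assignments={},
        )

    xm = x[maj_idx]
    mu = xm.mean(axis=0)
    sd = xm.std(axis=0)
    sd[sd == 0] = 1.0
    # float32 halves the k-means memory traffic; selection is by argmin of
    # well-separated distances, so the precision drop does not change it
    xm = ((xm - mu) / sd).astype(np.float32)

    km = KMeans(
        n_clusters=n_min, init="k-means++", n_init=1, random_state=seed
    ).fit(xm)
    assignments = km.labels_
    kept_majority = []
    for c in range(n_min):
        in_c = np.flatnonzero(assignments == c)
        if len(in_c) == 0:  # pragma: no cover - k-means++ rarely empties a cluster
            continue
        d = np.linalg.norm(xm[in_c] - km.cluster_centers_[c], axis=1)
        kept_majority.append(maj_idx[in_c[np.argmin(d)]])  # argmin -> smallest index on ties

    kept = np.sort(np.concatenate([min_idx, np.array(kept_majority, dtype=int)]))
    return UndersampleResult(
        kept_indices=kept,
        n_majority_before=n_maj,
        n_majority_after=len(kept_majority),
        cluster_assignments={
            int(mi): int(c) for mi, c in zip(maj_idx, assignments)
        },
    )
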