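"""Mask redundancy reduction: two-round clustering and representative picks.

Round 1 clusters masks on their binary variant membership (which variants each
mask includes), after PCA keeps the fewest components explaining >= 90% of
variance and k is chosen where the k-means cost stops dropping (elbow).
Round 2 re-clusters each cluster on MAF features (the variant's MAF where the
mask includes it, 0 otherwise), splitting clusters that share membership but
differ in the frequency range they admit.  Each (sub)cluster is then
represented by its member mask with the most significant associations,
yielding compact strategies whose size equals the number of (sub)clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples, silhouette_score

from .config import PipelineConfig
from .strategies import Strategy

__all__ = [
    "ClusteringResult",
    "reduce_dimensions",
    "choose_k_elbow",
    "cluster_and_subcluster",
    "select_representatives",
]


def reduce_dimensions(features: np.ndarray, variance_target: float = 0.90,
                      ) -> tuple[np.ndarray, int, float]:
    """PCA scores keeping the smallest component count whose cumulative
    explained variance reaches the target.

    Sign convention: each component's largest-magnitude loading is positive,
    so scores are reproducible across runs.  Returns (scores, n_components,
    explained_fraction).
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("need at least two masks")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    centered = features - features.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("constant feature matrix")
    pca = PCA(n_components=min(features.shape)).fit(features)
    ratios = pca.explained_variance_ratio_
    # strip numerically null trailing components before applying the target
    nonnull = ratios > 1e-12
    ratios = ratios[nonnull]
    cum = np.cumsum(ratios)
    n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_keep = min(n_keep, ratios.size)
    components = pca.components_[:n_keep]
    signs = np.sign(components[np.arange(n_keep),
                               np.argmax(np.abs(components), axis=1)])
    signs[signs == 0] = 1.0
    components = components * signs[:, None]
    scores = centered @ components.T
    return scores, n_keep, float(cum[n_keep - 1])


def _kmeans(scores: np.ndarray, k: int, seed: int, restarts: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(scores)


def _safe_silhouette(scores: np.ndarray, labels: np.ndarray) -> float:
    n_labels = len(set(labels.tolist()))
    if not 1 < n_labels < scores.shape[0]:
        return float("nan")
    return float(silhouette_score(scores, labels))


def choose_k_elbow(scores: np.ndarray, k_range: range | None = None,
                   drop_threshold: float = 0.05, seed: int = 0,
                   restarts: int = 10) -> int:
    """Smallest k whose k-means cost decrease to k+1, as a fraction of the
    total cost at the smallest k, falls below the threshold (the elbow).

    Normalizing by the total cost (rather than the local cost) makes the rule
    terminate: past the elbow, each extra centroid shaves a large share of an
    already-small residual, but a negligible share of the total."""
    n = scores.shape[0]
    if n == 1:
        return 1
    if k_range is None:
        k_range = range(1, min(15, n) + 1)
    n_distinct = np.unique(scores, axis=0).shape[0]
    ks = [k for k in k_range if 1 <= k <= n_distinct]
    if not ks:
        return 1
    inertia = {k: _kmeans(scores, k, seed, restarts).inertia_ for k in ks}
    total = inertia[ks[0]]
    if total <= 0:
        return ks[0]
    for k in ks[:-1]:
        nxt = inertia.get(k + 1)
        if nxt is None:
            break
        if (inertia[k] - nxt) / total < drop_threshold:
            return k
    return ks[-1]


@dataclass
class ClusteringResult:
    labels: pd.Series                 # round-1 cluster per mask
    subcluster_labels: pd.Series      # "cluster.sub" per mask
    k: int
    n_components: int
    explained_variance: float
    silhouette: float                 # round 1 (NaN when k == 1)
    subcluster_silhouette: float      # mean over per-cluster round-2 scores
    n_subclusters: int
    silhouette_contributions: pd.Series | None = None  # per mask, round 1


def cluster_and_subcluster(mask_ids: list[str], membership: np.ndarray,
                           maf_features: np.ndarray,
                           config: PipelineConfig | None = None,
                           ) -> ClusteringResult:
    """Round 1 on binary membership; round 2 per cluster on MAF features.

    MAF features carry the variant's MAF where the mask includes it and 0
    elsewhere.  Singleton clusters, and clusters whose MAF features are
    constant, keep a single subcluster.
    """
    config = config or PipelineConfig()
    membership = np.asarray(membership, dtype=float)
    maf_features = np.asarray(maf_features, dtype=float)

    if np.allclose(membership - membership.mean(axis=0), 0):
        # identical masks: one cluster, nothing to subdivide
        labels = pd.Series(np.zeros(len(mask_ids), dtype=int), index=mask_ids,
                           name="cluster")
        subs = pd.Series(["0.0"] * len(mask_ids), index=mask_ids,
                         name="subcluster")
        return ClusteringResult(labels=labels, subcluster_labels=subs, k=1,
                                n_components=0, explained_variance=1.0,
                                silhouette=float("nan"),
                                subcluster_silhouette=float("nan"),
                                n_subclusters=1,
                                silhouette_contributions=pd.Series(
                                    np.nan, index=mask_ids))

    scores, n_comp, explained = reduce_dimensions(membership,
                                                  config.variance_target)
    k_range = range(1, min(config.k_max, len(mask_ids)) + 1)
    k = choose_k_elbow(scores, k_range, config.elbow_drop, config.seed,
                       config.kmeans_restarts)
    if k == 1:
        labels = np.zeros(len(mask_ids), dtype=int)
        sil = float("nan")
        contributions = np.full(len(mask_ids), np.nan)
    else:
        fit = _kmeans(scores, k, config.seed, config.kmeans_restarts)
        labels = fit.labels_
        sil = _safe_silhouette(scores, labels)
        contributions = (silhouette_samples(scores, labels)
                         if not np.isnan(sil)
                         else np.full(len(mask_ids), np.nan))

    sub_labels = np.empty(len(mask_ids), dtype=object)
    sub_sils = []
    n_subclusters = 0
    for cluster in sorted(set(labels)):
        idx = np.flatnonzero(labels == cluster)
        sub = np.zeros(idx.size, dtype=int)
        if idx.size > 1:
            feats = maf_features[idx]
            centered = feats - feats.mean(axis=0)
            if not np.allclose(centered, 0):
                sub_scores, _, _ = reduce_dimensions(feats,
                                                     config.variance_target)
                sub_k = choose_k_elbow(
                    sub_scores, range(1, min(config.k_max, idx.size) + 1),
                    config.elbow_drop, config.seed, config.kmeans_restarts)
                if sub_k > 1:
                    sub_fit = _kmeans(sub_scores, sub_k, config.seed,
                                      config.kmeans_restarts)
                    sub = sub_fit.labels_
                    sub_sil = _safe_silhouette(sub_scores, sub)
                    if not np.isnan(sub_sil):
                        sub_sils.append(sub_sil)
        for local, j in zip(sub, idx):
            sub_labels[j] = f"{cluster}.{local}"
        n_subclusters += len(set(sub.tolist()))

    return ClusteringResult(
        labels=pd.Series(labels, index=mask_ids, name="cluster"),
        subcluster_labels=pd.Series(sub_labels, index=mask_ids,
                                    name="subcluster"),
        k=int(k), n_components=n_comp, explained_variance=explained,
        silhouette=sil,
        subcluster_silhouette=float(np.mean(sub_sils)) if sub_sils
        else float("nan"),
        n_subclusters=n_subclusters,
        silhouette_contributions=pd.Series(contributions, index=mask_ids,
                                           name="silhouette"))


def select_representatives(labels: pd.Series, mask_counts: pd.Series,
                           strategy_id: str = "representatives") -> Strategy:
    """One mask per (sub)cluster: the member with the largest significant
    count; ties broken by lexicographically smallest mask id."""
    chosen = []
    for cluster in sorted(set(labels), key=str):
        members = sorted(labels.index[labels == cluster])
        missing = [m for m in members if m not in mask_counts.index]
        if len(missing) == len(members):
            raise ValueError(f"cluster {cluster!r} has no scored masks")
        scored = [m for m in members if m in mask_counts.index]
        top = max(mask_counts[m] for m in scored)
        best = min(m for m in scored if mask_counts[m] == top)
        chosen.append(best)
    return Strategy(strategy_id=strategy_id, mask_ids=tuple(chosen))
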