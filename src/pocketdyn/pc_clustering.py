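"""Hierarchical clustering of conformations in the PC1-PC2 plane.

Conformations are agglomeratively clustered on Euclidean distances in the
2-D principal-component score plane (Ward linkage by default), the tree is
cut at an explicit height or cluster count, and each cluster is summarised
by its centroid representative: the member conformation with the lowest
RMSD to the cluster-average conformation.  Clusters can further be binned
into population tiers (high/middle/low) by size thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .ensemble_pca import EnsembleMatrix, PCScores

__all__ = [
    "ClusterResult",
    "cluster_subspace",
    "representatives",
    "subgroup_by_population",
]

_LINKAGES = {"ward", "complete", "average", "single"}


@dataclass
class ClusterResult:
    labels: np.ndarray
    method: str
    metric: str
    cut: dict
    representative_indices: dict

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def to_jsonable(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "method": self.method,
            "metric": self.metric,
            "cut": self.cut,
            "representative_indices": {
                str(k): int(v) for k, v in self.representative_indices.items()
            },
        }


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (deterministic)."""
    mapping = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_subspace(
    scores,
    method: str = "ward",
    n_clusters: int | None = None,
    height: float | None = None,
) -> np.ndarray:
    """Agglomerative clustering on Euclidean distance in the PC1-PC2 plane.

    Exactly one of ``n_clusters`` (cut by cluster count) or ``height``
    (cut by cophenetic distance) must be given.  Labels are 1..k in order
    of first appearance, so identical inputs give identical labels.
    """
    if isinstance(scores, PCScores):
        pts = scores.scores[:, :2]
    else:
        pts = np.asarray(scores, dtype=float)[:, :2]
    if not np.all(np.isfinite(pts)):
        raise ValueError("scores must be finite")
    m = len(pts)
    if m < 2:
        raise ValueError("clustering needs at least 2 conformations")
    if method not in _LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {sorted(_LINKAGES)}")
    if (n_clusters is None) == (height is None):
        raise ValueError("give exactly one of n_clusters or height")
    if n_clusters is not None and not (1 <= n_clusters <= m):
        raise ValueError(f"n_clusters={n_clusters} outside [1, {m}]")
    Z = linkage(pts, method=method, metric="euclidean")
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        raw = fcluster(Z, t=height, criterion="distance")
    return _canonical_labels(raw)


def representatives(e: EnsembleMatrix, labels) -> dict:
    """Centroid representative per cluster.

    For each cluster, the average conformation is the mean of the member
    rows (the ensemble is already in one frame, so no re-fitting); the
    representative is the member with the lowest RMSD to that average,
    ties broken by lowest conformation index.
    """
    labels = np.asarray(labels)
    if len(labels) != e.n_conformations:
        raise ValueError("labels must align with ensemble rows")
    reps = {}
    n = e.n_atoms
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        member_rows = e.X[idx]
        avg = member_rows.mean(axis=0)
        # RMSD to average = ||row - avg|| / sqrt(N)
        d = np.linalg.norm(member_rows - avg, axis=1) / np.sqrt(n)
        reps[int(lab)] = int(idx[int(np.argmin(d))])
    return reps


def subgroup_by_population(labels, boundaries, tier_names=None) -> dict:
    """Partition clusters into population tiers by member count.

    ``boundaries`` are descending size thresholds; a cluster of size s
    lands in the first tier whose threshold satisfies s >= threshold,
    else in the last tier.  Two boundaries give the high/middle/low
    split.  Within a tier, clusters are ordered by descending size then
    ascending cluster id.
    """
    labels = np.asarray(labels)
    boundaries = list(boundaries)
    if boundaries != sorted(boundaries, reverse=True):
        raise ValueError("boundaries must be in descending order")
    n_tiers = len(boundaries) + 1
    if tier_names is None:
        tier_names = (
            ["high", "middle", "low"]
            if n_tiers == 3
            else [f"tier{i}" for i in range(n_tiers)]
        )
    if len(tier_names) != n_tiers:
        raise ValueError("need one tier name per tier")
    ids, sizes = np.unique(labels, return_counts=True)
    tiers = {name: [] for name in tier_names}
    for cid, size in zip(ids, sizes):
        tier = n_tiers - 1
        for i, b in enumerate(boundaries):
            if size >= b:
                tier = i
                break
        tiers[tier_names[tier]].append((int(cid), int(size)))
    return {
        name: [cid for cid, _ in sorted(members, key=lambda t: (-t[1], t[0]))]
        for name, members in tiers.items()
    }
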