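"""Case-sample stratification.

Samples are compared by correlation distance (1 - Pearson) on their
full preprocessed expression vectors and grouped by complete-linkage
agglomerative clustering.  Flat clusters are read off the dendrogram at
``fraction * dmax`` where ``dmax`` is the height of the final merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix


@dataclass
class ClusterAssignment:
    """Flat cluster labels plus the dendrogram they were cut from."""

    sample_ids: list[str]
    labels: dict[str, int]
    merge_tree: np.ndarray  # scipy linkage matrix, (n-1) x 4
    cut_height: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster: int) -> list[str]:
        return [s for s in self.sample_ids if self.labels[s] == cluster]


def sample_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Correlation distance 1 - Pearson(s1, s2), in [0, 2]."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1 or s1.size < 2:
        raise ValueError("expect two equal-length vectors of length >= 2")
    c1 = s1 - s1.mean()
    c2 = s2 - s2.mean()
    n1 = np.linalg.norm(c1)
    n2 = np.linalg.norm(c2)
    if n1 == 0 or n2 == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(1.0 - (c1 @ c2) / (n1 * n2))


def distance_matrix(case: ExpressionMatrix) -> np.ndarray:
    """Pairwise correlation distances between the case sample columns."""
    v = case.values.astype(float)
    if np.any(v.std(axis=0) == 0):
        bad = case.sample_ids[int(np.argmin(v.std(axis=0)))]
        raise ValueError(f"sample {bad!r} has zero variance across genes")
    r = np.corrcoef(v, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def complete_linkage(d: np.ndarray) -> np.ndarray:
    """Agglomerate with max-linkage; returns a scipy linkage matrix."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if d.shape[0] < 2:
        return np.empty((0, 4))
    return linkage(squareform(d, checks=False), method="complete")


def cut_tree(tree: np.ndarray, sample_ids: list[str], fraction: float = 0.7) -> ClusterAssignment:
    """Cut the dendrogram at ``fraction`` of its maximum merge height.

    Clusters are the maximal groups whose internal merges all have
    height <= the cut (boundary kept); cluster indices are renumbered
    1..l in order of first appearance along ``sample_ids``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    tree = np.asarray(tree, dtype=float)
    if len(sample_ids) == 1 or tree.size == 0:
        return ClusterAssignment(list(sample_ids), {sample_ids[0]: 1}, np.empty((0, 4)), 0.0)
    cut = float(fraction * tree[:, 2].max())
    flat = fcluster(tree, t=cut, criterion="distance")
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for sid, lab in zip(sample_ids, flat):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[sid] = remap[lab]
    return ClusterAssignment(list(sample_ids), labels, tree, cut)


def cluster_samples(case: ExpressionMatrix, fraction: float = 0.7) -> ClusterAssignment:
    """Distance matrix -> complete linkage -> dendrogram cut."""
    if case.n_samples == 1:
        return ClusterAssignment(case.sample_ids, {case.sample_ids[0]: 1}, np.empty((0, 4)), 0.0)
    d = distance_matrix(case)
    tree = complete_linkage(d)
    return cut_tree(tree, case.sample_ids, fraction)
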