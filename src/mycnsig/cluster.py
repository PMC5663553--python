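"""Hierarchical clustering of samples (Euclidean distance, complete linkage)
and a quantitative co-clustering score for the MYCN-amplified group.

The agglomeration is written out explicitly so that ties are broken
deterministically (merge the lexicographically smallest cluster pair among
equals) and the result is reproducible across platforms; the produced merge
table is in the standard linkage-matrix layout so the scientific Python
hierarchy utilities (tree cutting, dendrogram drawing) apply directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix

__all__ = ["Dendrogram", "hcluster", "coclustering_score", "to_newick"]

log = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Binary merge tree over samples.

    ``linkage`` is an (n-1) x 4 merge table: child ids, merge height, leaf
    count — heights are non-decreasing under complete linkage (ultrametric).
    ``labels`` are the sample ids in input order; ``leaf_order`` lists leaves
    with smaller subtrees first at every internal node.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list[str]:
        n = self.n_leaves

        def leaves(node: int) -> tuple[list[int], int]:
            if node < n:
                return [node], node
            i, j = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
            li, mi = leaves(i)
            lj, mj = leaves(j)
            # smaller subtree first; break size ties on smallest leaf index
            if (len(li), mi) <= (len(lj), mj):
                return li + lj, min(mi, mj)
            return lj + li, min(mi, mj)

        order, _ = leaves(2 * n - 2) if n > 1 else ([0], 0)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster assignment (1..k) per sample, in label order."""
        if k > self.n_leaves:
            raise ValueError(f"cannot cut {self.n_leaves} samples into {k} clusters")
        return fcluster(self.linkage, t=k, criterion="maxclust")


def hcluster(matrix: pd.DataFrame | ExpressionMatrix, axis: str = "samples") -> Dendrogram:
    """Agglomerative complete-linkage tree on Euclidean distances.

    ``axis='samples'`` clusters columns (the usual orientation for cohort
    heatmaps); ``axis='features'`` clusters rows.
    """
    frame = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    data = frame.to_numpy(dtype=float).T if axis == "samples" else frame.to_numpy(dtype=float)
    labels = list(frame.columns if axis == "samples" else frame.index)
    n = data.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 observations")
    if not np.isfinite(data).all():
        raise ValueError("matrix contains non-finite values")

    dist = squareform(pdist(data, metric="euclidean"))

    # active cluster id -> (lexicographic key = sorted leaf labels, leaf count)
    keys: dict[int, tuple] = {i: (tuple([labels[i]]), 1) for i in range(n)}
    active = set(range(n))
    # distances kept in a dict over active pairs
    d: dict[tuple[int, int], float] = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    linkage = np.zeros((n - 1, 4))
    next_id = n
    members: dict[int, list[int]] = {i: [i] for i in range(n)}

    for step in range(n - 1):
        best_d = min(d.values())
        tied = [(i, j) for (i, j), dij in d.items() if dij == best_d]
        if len(tied) > 1:
            # lexicographically smallest pair of cluster keys among equals
            def pair_key(pair):
                ki, kj = keys[pair[0]][0], keys[pair[1]][0]
                return (min(ki, kj), max(ki, kj))
            i, j = min(tied, key=pair_key)
        else:
            i, j = tied[0]
        height = best_d
        count = keys[i][1] + keys[j][1]
        linkage[step] = [i, j, height, count]

        active.discard(i)
        active.discard(j)
        # complete linkage: distance to the merged cluster is the max
        for m in active:
            dmi = d.pop((min(i, m), max(i, m)))
            dmj = d.pop((min(j, m), max(j, m)))
            d[(m, next_id)] = max(dmi, dmj)
        d.pop((i, j), None)
        keys[next_id] = (tuple(sorted(keys[i][0] + keys[j][0])), count)
        members[next_id] = members[i] + members[j]
        active.add(next_id)
        next_id += 1

    return Dendrogram(linkage=linkage, labels=labels)


def coclustering_score(dendrogram: Dendrogram, labels, k: int = 2) -> float:
    """Max over the k tree-cut clusters of the F1 between cluster membership
    and the positive (amplified) label.

    Quantifies whether the amplified samples co-clusterize: 1.0 means some
    cluster is exactly the amplified group. Degenerate single-class labels
    return 1.0 with a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    y = np.asarray(labels, dtype=bool)
    if len(y) != dendrogram.n_leaves:
        raise ValueError("labels must align with the clustered samples")
    if y.all() or not y.any():
        warnings.warn("single-class labels: co-clustering score is degenerate")
        return 1.0
    assignment = dendrogram.cut(k)
    best = 0.0
    for c in np.unique(assignment):
        in_c = assignment == c
        tp = float((in_c & y).sum())
        if tp == 0:
            continue
        precision = tp / in_c.sum()
        recall = tp / y.sum()
        best = max(best, 2 * precision * recall / (precision + recall))
    return best


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick serialization with branch lengths = merge-height differences."""
    n = dendrogram.n_leaves
    Z = dendrogram.linkage

    def node_height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - node_height(node)
        if node < n:
            return f"{dendrogram.labels[node]}:{length:g}"
        i, j = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = node_height(node)
        return f"({render(i, h)},{render(j, h)}):{length:g}"

    root = 2 * n - 2
    return f"({render(int(Z[-1, 0]), node_height(root))},{render(int(Z[-1, 1]), node_height(root))});"
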