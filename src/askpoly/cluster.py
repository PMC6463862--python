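"""Hierarchical clustering of per-gene statistic profiles.

Distances are Manhattan (city-block) over the feature columns and linkage
is the classical Ward criterion applied directly to the given,
unsquared dissimilarities — R's hclust "ward.D" — via the Lance-Williams
update d(k, i+j) = ((n_i+n_k) d(ki) + (n_j+n_k) d(kj) - n_k d(ij)) /
(n_i+n_j+n_k).  Merge ties are broken on the smallest (id_a, id_b) pair,
making the dendrogram deterministic and row-order invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass
class Dendrogram:
    """Merge history in scipy linkage form plus leaf labels.

    ``linkage`` rows are (id_a, id_b, height, size) with leaves 0..n-1 and
    merge k creating node n+k.  Ward heights are non-decreasing.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left},{right}):{node.dist:.6g}"

        return walk(tree).rsplit(":", 1)[0] + ";"


def drop_undefined_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop rows containing undefined cells (NaN), with a warning."""
    bad = matrix.index[matrix.isna().any(axis=1)]
    if len(bad):
        warnings.warn(f"dropping rows with undefined values: {list(bad)}")
    return matrix.drop(index=bad)


def manhattan_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Manhattan distances d(i,j) = sum_k |m_ik - m_jk|."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to compute distances")
    if matrix.isna().any().any():
        raise ValueError("undefined cells present; drop or impute first")
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="cityblock"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def hierarchical_ward(distances: pd.DataFrame | np.ndarray,
                      labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative ward.D clustering of a distance matrix."""
    if isinstance(distances, pd.DataFrame):
        labels = labels or [str(i) for i in distances.index]
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = labels or [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 2:
        raise ValueError("need at least two observations")

    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    active = {i: (i, 1) for i in range(n)}     # slot -> (node id, size)
    Z = np.zeros((n - 1, 4))
    next_id = n
    slots = list(range(n))
    for step in range(n - 1):
        best = None
        for ai in range(len(slots)):
            for bi in range(ai + 1, len(slots)):
                i, j = slots[ai], slots[bi]
                key = (min(i, j), max(i, j))
                ids = tuple(sorted((active[i][0], active[j][0])))
                cand = (dist[key], ids, key)
                if best is None or cand < best:
                    best = cand
        height, (id_a, id_b), (i, j) = best
        size = active[i][1] + active[j][1]
        Z[step] = (id_a, id_b, height, size)
        # Lance-Williams ward.D update against every other active slot
        ni, nj = active[i][1], active[j][1]
        for k in slots:
            if k in (i, j):
                continue
            nk = active[k][1]
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dij = dist[(min(i, j), max(i, j))]
            dist[(min(i, k), max(i, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        slots.remove(j)
        active[i] = (next_id, size)
        del active[j]
        next_id += 1
    return Dendrogram(Z, labels)


def cut_tree(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into exactly k groups (height-threshold cut)."""
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    flat = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    if len(set(flat)) != k:
        raise RuntimeError(f"tied merge heights prevent a cut into exactly {k} groups")
    return {label: int(c) for label, c in zip(dendrogram.labels, flat)}


def cluster_statistic_matrix(matrix: pd.DataFrame, k: int = 3,
                             zscale: bool = False) -> tuple[Dendrogram, dict[str, int]]:
    """Convenience pipeline: drop undefined rows, optionally z-scale
    columns, Manhattan distances, ward.D linkage, cut into k groups."""
    m = drop_undefined_rows(matrix)
    if zscale:
        m = (m - m.mean()) / m.std(ddof=0)
    dendro = hierarchical_ward(manhattan_distances(m))
    return dendro, cut_tree(dendro, k)
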