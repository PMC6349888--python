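"""From a distance matrix to a labelled state sequence.

Snapshots are grouped by single-linkage (shortest-distance)
agglomerative clustering of the pairwise distance matrix; every
cluster is a *system state*.  The number of states C is chosen by
maximising Dunn's index

    min inter-state distance / max intra-state diameter

over the dendrogram cuts with 2 <= C <= t_max.  Cuts whose largest
diameter is zero leave the index undefined and are excluded from the
argmax (otherwise the all-singleton cut would always win); ties are
broken toward the smallest C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .graphdist import DistanceMatrix

__all__ = [
    "Dendrogram",
    "StateAssignment",
    "SimilarityMatrix",
    "single_linkage",
    "cut_dendrogram",
    "dunn_index",
    "select_states",
    "to_similarity",
]


@dataclass
class Dendrogram:
    """Single-linkage merge table in scipy linkage format.

    Each of the t_max - 1 rows holds (cluster_a, cluster_b, height,
    new_size); clusters >= t_max refer to earlier merges.  Single
    linkage is monotone, so heights are non-decreasing.
    """

    Z: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.Z.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


@dataclass
class StateAssignment:
    """Per-window state labels and the Dunn trace behind the choice of C.

    ``labels[t]`` is the state of window t (1-based states, numbered by
    first appearance in time); ``dunn_by_C[c]`` is Dunn's index of the
    dendrogram cut into c clusters (NaN where undefined).
    """

    labels: np.ndarray
    C: int
    dunn_by_C: dict[int, float]
    measure: str = ""

    @property
    def t_max(self) -> int:
        return self.labels.size


@dataclass
class SimilarityMatrix:
    """sim(i, j) = 1 - d(i, j) / max d, entries in [0, 1], unit diagonal."""

    sim: np.ndarray
    measure: str = ""


def _as_array(D) -> np.ndarray:
    d = D.d if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    return d


def single_linkage(D: DistanceMatrix | np.ndarray) -> Dendrogram:
    """Single-linkage dendrogram of a snapshot distance matrix.

    Inter-cluster distance is the minimum pairwise distance between
    members.  The merge order under tied heights follows the (fully
    deterministic) minimum-spanning-tree order of the linkage
    implementation; merge heights are the sorted MST edge weights and
    therefore independent of tie-breaking.
    """
    d = _as_array(D)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 snapshots")
    Z = sch.linkage(squareform(d, checks=False), method="single")
    return Dendrogram(Z=Z)


def cut_dendrogram(dend: Dendrogram, C: int) -> np.ndarray:
    """Partition into C clusters by stopping after t_max - C merges.

    Labels are renumbered by first appearance in time (window order),
    so label 1 is always the state of the first window.
    """
    n = dend.n_leaves
    if not 1 <= C <= n:
        raise ValueError(f"C must be in [1, {n}], got {C}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in range(n - C):
        a, b = int(dend.Z[k, 0]), int(dend.Z[k, 1])
        new = n + k
        parent[find(a)] = new
        parent[find(b)] = new

    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return labels


def dunn_index(D: DistanceMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Dunn's index of a labelling; NaN where undefined.

    Numerator: smallest distance between two windows in different
    states.  Denominator: largest within-state diameter (singletons
    have diameter 0).  A zero maximum diameter leaves the ratio
    undefined; NaN is returned and such cuts are excluded from model
    selection.
    """
    d = _as_array(D)
    labels = np.asarray(labels)
    if labels.size != d.shape[0]:
        raise ValueError("labels length must match distance matrix size")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn's index requires at least 2 states")

    same = labels[:, None] == labels[None, :]
    off = ~np.eye(labels.size, dtype=bool)
    inter = d[~same]
    intra = d[same & off]
    max_diam = intra.max() if intra.size else 0.0
    if max_diam == 0.0:
        return float("nan")
    return float(inter.min() / max_diam)


def select_states(
    D: DistanceMatrix | np.ndarray,
    dend: Dendrogram | None = None,
) -> StateAssignment:
    """Choose the number of states C by maximising Dunn's index.

    Evaluates every dendrogram cut with C in 2..t_max and returns the
    smallest C attaining the maximum over the defined values, together
    with the full Dunn trace.
    """
    d = _as_array(D)
    n = d.shape[0]
    if n < 3:
        raise ValueError("too few windows: need t_max >= 3 to select states")
    if dend is None:
        dend = single_linkage(d)

    dunn_by_C: dict[int, float] = {}
    labels_by_C: dict[int, np.ndarray] = {}
    for C in range(2, n + 1):
        labels = cut_dendrogram(dend, C)
        if np.unique(labels).size < 2:
            dunn_by_C[C] = float("nan")
            continue
        labels_by_C[C] = labels
        dunn_by_C[C] = dunn_index(d, labels)

    defined = {C: v for C, v in dunn_by_C.items() if np.isfinite(v)}
    if not defined:
        raise ValueError("degenerate distance matrix: Dunn's index undefined for every C")
    best = max(defined.values())
    C = min(C for C, v in defined.items() if v == best)
    measure = D.measure if isinstance(D, DistanceMatrix) else ""
    return StateAssignment(
        labels=labels_by_C[C], C=C, dunn_by_C=dunn_by_C, measure=measure
    )


def to_similarity(D: DistanceMatrix | np.ndarray) -> SimilarityMatrix:
    """Transform distances to similarities: sim = 1 - d / max d.

    Zero distance maps to similarity one; the largest distance maps to
    zero.  Invariant under positive rescaling of the distances.
    """
    d = _as_array(D)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("all-zero distance matrix has no similarity transform")
    measure = D.measure if isinstance(D, DistanceMatrix) else ""
    return SimilarityMatrix(sim=1.0 - d / dmax, measure=measure)
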