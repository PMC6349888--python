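"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths: naive O(n^3)
agglomeration, direct double-loop Dunn evaluation, straight-line
DELTACON with explicit matrix inverses, and dense eigendecompositions
via numpy.  They trade speed for obviousness.
"""

from __future__ import annotations

import numpy as np


def naive_single_linkage_heights(d: np.ndarray) -> list[float]:
    """Merge heights of single-linkage agglomeration, naive O(n^3)."""
    n = d.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, 0, 1)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = min(d[i, j] for i in clusters[a] for j in clusters[b])
                if dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return heights


def naive_single_linkage_partitions(d: np.ndarray) -> dict[int, np.ndarray]:
    """Partition at every cluster count C, by naive agglomeration."""
    n = d.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]

    def labels() -> np.ndarray:
        out = np.empty(n, dtype=int)
        for k, cl in enumerate(clusters):
            for i in cl:
                out[i] = k
        return out

    parts = {n: labels()}
    while len(clusters) > 1:
        best = (np.inf, 0, 1)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = min(d[i, j] for i in clusters[a] for j in clusters[b])
                if dist < best[0]:
                    best = (dist, a, b)
        _, a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
        parts[len(clusters)] = labels()
    return parts


def brute_dunn(d: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation of Dunn's index; NaN if the max diameter is 0."""
    labels = np.asarray(labels)
    states = np.unique(labels)
    numer = np.inf
    for a in range(len(states)):
        for b in range(a + 1, len(states)):
            for i in np.flatnonzero(labels == states[a]):
                for j in np.flatnonzero(labels == states[b]):
                    numer = min(numer, d[i, j])
    denom = 0.0
    for s in states:
        members = np.flatnonzero(labels == s)
        for x, i in enumerate(members):
            for j in members[x + 1:]:
                denom = max(denom, d[i, j])
    if denom == 0.0:
        return float("nan")
    return numer / denom


def brute_select_C(d: np.ndarray) -> int:
    """Smallest C maximising Dunn over naive single-linkage cuts, 2..n."""
    parts = naive_single_linkage_partitions(d)
    n = d.shape[0]
    scores = {}
    for C in range(2, n + 1):
        labels = parts[C]
        if np.unique(labels).size < 2:
            continue
        v = brute_dunn(d, labels)
        if np.isfinite(v):
            scores[C] = v
    best = max(scores.values())
    return min(C for C, v in scores.items() if v == best)


def deltacon_reference(A1: np.ndarray, A2: np.ndarray) -> float:
    """Straight-line DELTACON: two matrix inverses and the Matusita sum."""
    n = A1.shape[0]
    D1 = np.diag(A1.sum(axis=1))
    D2 = np.diag(A2.sum(axis=1))
    eps = 1.0 / (1.0 + max(A1.sum(axis=1).max(), A2.sum(axis=1).max()))
    S1 = np.linalg.inv(np.eye(n) + eps**2 * D1 - eps * A1)
    S2 = np.linalg.inv(np.eye(n) + eps**2 * D2 - eps * A2)
    return float(
        np.sqrt(np.sum((np.sqrt(np.clip(S1, 0, None)) - np.sqrt(np.clip(S2, 0, None))) ** 2))
    )


def dense_laplacian_eigs(A: np.ndarray, normalised: bool = False) -> np.ndarray:
    """Eigenvalues via an explicit dense build and numpy's solver."""
    deg = A.sum(axis=1)
    L = np.diag(deg) - A
    if normalised:
        with np.errstate(divide="ignore"):
            inv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        L = np.diag(inv) @ L @ np.diag(inv)
    return np.sort(np.linalg.eigvalsh(L))
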