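"""Graph distance measures between snapshot networks.

Seven measures are provided, all operating on undirected graphs over a
shared node label space:

* ``edit`` — labelled graph edit distance: the number of node/edge
  insertions and deletions transforming one graph into the other,
  without any vertex matching (node identities are shared).
* ``deltacon`` — the exact DELTACON distance: node-pair affinities from
  the fast-belief-propagation linear system, compared with the Matusita
  (root-Euclidean) distance.
* ``jsd`` — quantum spectral Jensen–Shannon divergence between the
  graphs' density matrices ``rho = exp(-beta*L) / tr(exp(-beta*L))``;
  ``beta`` is the diffusion-time scale.
* ``lap_unnormalized`` / ``lap_normalized`` — Euclidean distance
  between sorted spectra of the combinatorial Laplacian ``L = D - A``,
  either raw or normalised by the larger spectral energy.
* ``nlap_unnormalized`` / ``nlap_normalized`` — the same two variants
  on the normalised Laplacian ``L' = I - D^{-1/2} A D^{-1/2}``.

The normalised spectrum distance is bounded above by sqrt(2) (the
normaliser is the *maximum* of the two spectral energies), and the
normalised Laplacian's eigenvalues lie in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.linalg

from .snapshots import SnapshotSequence

__all__ = [
    "GraphMatrixBundle",
    "DistanceMatrix",
    "MEASURES",
    "edit_distance",
    "deltacon_distance",
    "laplacian_spectrum",
    "spectral_distance",
    "spectral_distance_from_spectra",
    "jsd_distance",
    "density_matrix",
    "von_neumann_entropy",
    "pairwise_distance_matrix",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class GraphMatrixBundle:
    """Adjacency, degree and Laplacian matrices of one graph.

    ``lnorm`` follows the isolated-node convention: rows and columns of
    the normalised Laplacian belonging to degree-zero nodes are zero,
    so each isolate contributes one zero eigenvalue.  This keeps every
    snapshot at the full registry dimension N with the spectrum still
    confined to [0, 2].
    """

    A: np.ndarray
    degrees: np.ndarray

    @classmethod
    def from_graph(
        cls,
        G: nx.Graph,
        nodelist: Sequence | None = None,
        weighted: bool = False,
    ) -> "GraphMatrixBundle":
        if G.is_directed():
            raise ValueError("adjacency matrix is not symmetric (directed graph)")
        if nodelist is None:
            nodelist = sorted(G.nodes, key=str)
        idx = {n: i for i, n in enumerate(nodelist)}
        A = np.zeros((len(idx), len(idx)))
        for u, v, data in G.edges(data=True):
            if u == v:
                continue
            try:
                i, j = idx[u], idx[v]
            except KeyError as exc:
                raise ValueError(f"node {exc.args[0]!r} missing from nodelist") from None
            w = float(data.get("weight", 1.0)) if weighted else 1.0
            if w < 0:
                raise ValueError("edge weights must be nonnegative")
            A[i, j] = A[j, i] = w
        return cls(A=A, degrees=A.sum(axis=1))

    @property
    def L(self) -> np.ndarray:
        """Combinatorial Laplacian D - A."""
        return np.diag(self.degrees) - self.A

    @property
    def Lnorm(self) -> np.ndarray:
        """Normalised Laplacian with zeroed rows/columns for isolates."""
        d = self.degrees
        inv_sqrt = np.zeros_like(d, dtype=float)
        nz = d > 0
        inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
        # D^{-1/2} (D - A) D^{-1/2}; isolates end up with all-zero rows
        Ln = -self.A * np.outer(inv_sqrt, inv_sqrt)
        np.fill_diagonal(Ln, np.where(nz, 1.0, 0.0))
        return Ln

    def laplacian(self, kind: str) -> np.ndarray:
        if kind == "combinatorial":
            return self.L
        if kind in ("normalised", "normalized"):
            return self.Lnorm
        raise ValueError(f"unknown Laplacian kind {kind!r}")


@dataclass
class DistanceMatrix:
    """Symmetric t_max x t_max pairwise snapshot distance matrix."""

    d: np.ndarray
    measure: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")

    @property
    def t_max(self) -> int:
        return self.d.shape[0]

    def validate(self) -> None:
        d = self.d
        if np.isnan(d).any():
            raise ValueError("distance matrix contains NaN")
        if not np.array_equal(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("distance matrix has a nonzero diagonal")
        if (d < 0).any():
            raise ValueError("distance matrix has negative entries")


# ---------------------------------------------------------------------------
# individual measures


def edit_distance(G1: nx.Graph, G2: nx.Graph, node_mode: str = "active") -> float:
    """Labelled graph edit distance (no vertex matching).

    ``d = N(G1) + N(G2) - 2 N(G1 ^ G2) + M(G1) + M(G2) - 2 M(G1 ^ G2)``
    where the intersection keeps nodes and edges present in both
    graphs.  In ``active`` mode N(G) counts only non-isolated nodes —
    for snapshots on a global registry the node terms would otherwise
    always cancel.  In ``global`` mode the node terms vanish and the
    distance reduces to the edge symmetric-difference size.
    """
    if node_mode not in ("active", "global"):
        raise ValueError(f"unknown node_mode {node_mode!r}")
    for g in (G1, G2):
        if any("weight" in data for _, _, data in g.edges(data=True)):
            raise ValueError("edit distance is defined on unweighted graphs")
    e1 = {frozenset(e) for e in G1.edges}
    e2 = {frozenset(e) for e in G2.edges}
    d = float(len(e1) + len(e2) - 2 * len(e1 & e2))
    if node_mode == "active":
        n1 = {n for n, deg in G1.degree if deg > 0}
        n2 = {n for n, deg in G2.degree if deg > 0}
        d += len(n1) + len(n2) - 2 * len(n1 & n2)
    return d


def deltacon_distance(
    G1: nx.Graph,
    G2: nx.Graph,
    nodelist: Sequence | None = None,
    eps: float | None = None,
) -> float:
    """Exact DELTACON distance between two graphs on a common node set.

    Node-pair affinities are ``S_k = [I + eps^2 D_k - eps A_k]^{-1}``
    with a common ``eps = 1/(1 + max degree over both graphs)`` — a
    shared eps keeps the measure symmetric and the two affinity
    matrices comparable.  The result is the Matusita distance
    ``sqrt(sum_ij (sqrt(S1_ij) - sqrt(S2_ij))^2)``.
    """
    if nodelist is None:
        nodelist = sorted(set(G1.nodes) | set(G2.nodes), key=str)
    b1 = GraphMatrixBundle.from_graph(G1, nodelist)
    b2 = GraphMatrixBundle.from_graph(G2, nodelist)
    if eps is None:
        dmax = max(b1.degrees.max(initial=0.0), b2.degrees.max(initial=0.0))
        eps = 1.0 / (1.0 + dmax)
    s1 = _deltacon_affinity(b1, eps)
    s2 = _deltacon_affinity(b2, eps)
    return float(np.sqrt(np.sum((np.sqrt(s1) - np.sqrt(s2)) ** 2)))


def _deltacon_affinity(bundle: GraphMatrixBundle, eps: float) -> np.ndarray:
    n = bundle.A.shape[0]
    M = np.eye(n) + eps**2 * np.diag(bundle.degrees) - eps * bundle.A
    try:
        S = scipy.linalg.solve(M, np.eye(n), assume_a="pos")
    except scipy.linalg.LinAlgError as exc:  # eps below spectral bound: unreachable
        raise ValueError("DELTACON linear system is singular") from exc
    # affinities are nonnegative for eps within the convergence bound;
    # clip roundoff noise before the square root
    return np.clip(S, 0.0, None)


def laplacian_spectrum(
    G: nx.Graph,
    kind: str = "combinatorial",
    nodelist: Sequence | None = None,
    weighted: bool = False,
) -> np.ndarray:
    """Ascending eigenvalues of the chosen Laplacian.

    Tiny negative eigenvalues (roundoff) are clipped to zero.  Under
    the normalised kind each isolated node contributes one zero
    eigenvalue (see :class:`GraphMatrixBundle`).
    """
    bundle = GraphMatrixBundle.from_graph(G, nodelist, weighted=weighted)
    return _spectrum_of(bundle, kind)


def _spectrum_of(bundle: GraphMatrixBundle, kind: str) -> np.ndarray:
    vals = scipy.linalg.eigvalsh(bundle.laplacian(kind))
    if vals[0] < -_EIG_TOL * max(1.0, abs(vals[-1])):
        raise ValueError("Laplacian spectrum has a significantly negative eigenvalue")
    return np.clip(vals, 0.0, None)


def spectral_distance(
    G1: nx.Graph,
    G2: nx.Graph,
    kind: str = "normalised",
    variant: str = "normalised_distance",
    n_eig: int | None = None,
    nodelist: Sequence | None = None,
) -> float:
    """Laplacian spectrum distance between two equally sized graphs.

    The unnormalised variant is the Euclidean distance between the
    ``n_eig`` largest eigenvalues of the chosen Laplacian; the
    normalised variant divides the squared sum by the larger of the two
    spectral energies before taking the root, bounding the result by
    sqrt(2).
    """
    if G1.number_of_nodes() != G2.number_of_nodes():
        raise ValueError("graphs must have equal node counts")
    if nodelist is None:
        nodelist = sorted(set(G1.nodes) | set(G2.nodes), key=str)
    s1 = laplacian_spectrum(G1, kind, nodelist)
    s2 = laplacian_spectrum(G2, kind, nodelist)
    return spectral_distance_from_spectra(s1, s2, variant=variant, n_eig=n_eig)


def spectral_distance_from_spectra(
    s1: np.ndarray,
    s2: np.ndarray,
    variant: str = "normalised_distance",
    n_eig: int | None = None,
) -> float:
    """Spectrum distance from precomputed ascending eigenvalue arrays."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("spectra must have equal length")
    N = s1.size
    if n_eig is None:
        n_eig = N
    if not 1 <= n_eig <= N:
        raise ValueError(f"n_eig must be in [1, {N}], got {n_eig}")
    top1 = s1[N - n_eig:]
    top2 = s2[N - n_eig:]
    sq = float(np.sum((top1 - top2) ** 2))
    if variant in ("unnormalised", "unnormalized"):
        return float(np.sqrt(sq))
    if variant in ("normalised_distance", "normalized_distance"):
        denom = max(float(np.sum(top1**2)), float(np.sum(top2**2)))
        if denom == 0.0:
            # both spectra identically zero (empty graphs): distance 0
            return 0.0
        return float(np.sqrt(sq / denom))
    raise ValueError(f"unknown variant {variant!r}")


def density_matrix(
    G: nx.Graph,
    beta: float = 1.0,
    kind: str = "combinatorial",
    nodelist: Sequence | None = None,
) -> np.ndarray:
    """Graph density matrix ``rho = exp(-beta*L) / tr(exp(-beta*L))``.

    ``beta > 0`` is the time for which a diffusion process is run on
    the graph; large beta emphasises global structure.  The result is
    symmetric positive semidefinite with unit trace.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    bundle = GraphMatrixBundle.from_graph(G, nodelist)
    L = bundle.laplacian(kind)
    vals, vecs = scipy.linalg.eigh(L)
    # factor out the smallest eigenvalue for numerical stability
    w = np.exp(-beta * (vals - vals.min()))
    w /= w.sum()
    return (vecs * w) @ vecs.T


def von_neumann_entropy(rho: np.ndarray) -> float:
    """Entropy ``-sum lam_i log2 lam_i`` of a density matrix, in bits."""
    vals = scipy.linalg.eigvalsh(rho)
    if vals.min() < -1e-9:
        raise ValueError("density matrix has a negative eigenvalue")
    vals = np.clip(vals, 0.0, None)
    nz = vals > 0
    return float(-np.sum(vals[nz] * np.log2(vals[nz])))


def jsd_distance(
    G1: nx.Graph,
    G2: nx.Graph,
    beta: float = 1.0,
    kind: str = "combinatorial",
    nodelist: Sequence | None = None,
) -> float:
    """Quantum spectral Jensen–Shannon distance, in [0, 1].

    ``d = sqrt(S((rho1+rho2)/2) - [S(rho1)+S(rho2)]/2)`` with entropies
    in bits.  A tiny negative radicand (roundoff) is clamped to zero.
    """
    if nodelist is None:
        nodelist = sorted(set(G1.nodes) | set(G2.nodes), key=str)
    r1 = density_matrix(G1, beta=beta, kind=kind, nodelist=nodelist)
    r2 = density_matrix(G2, beta=beta, kind=kind, nodelist=nodelist)
    return _jsd_from_density(r1, r2)


def _jsd_from_density(r1: np.ndarray, r2: np.ndarray) -> float:
    jsd = von_neumann_entropy((r1 + r2) / 2.0) - 0.5 * (
        von_neumann_entropy(r1) + von_neumann_entropy(r2)
    )
    if jsd < 0:
        if jsd < -1e-10:
            raise ValueError(f"Jensen-Shannon radicand {jsd} below tolerance")
        jsd = 0.0
    return float(np.sqrt(jsd))


# ---------------------------------------------------------------------------
# measure registry and the pairwise matrix

_SPECTRAL_MEASURES: Mapping[str, tuple[str, str]] = {
    "lap_unnormalized": ("combinatorial", "unnormalised"),
    "lap_normalized": ("combinatorial", "normalised_distance"),
    "nlap_unnormalized": ("normalised", "unnormalised"),
    "nlap_normalized": ("normalised", "normalised_distance"),
}


def _pair_measure(name: str, params: Mapping) -> Callable[[nx.Graph, nx.Graph, Sequence], float]:
    if name == "edit":
        mode = params.get("node_mode", "active")
        return lambda g1, g2, nl: edit_distance(g1, g2, node_mode=mode)
    if name == "deltacon":
        return lambda g1, g2, nl: deltacon_distance(g1, g2, nodelist=nl)
    if name == "jsd":
        beta = params.get("beta", 1.0)
        kind = params.get("kind", "combinatorial")
        return lambda g1, g2, nl: jsd_distance(g1, g2, beta=beta, kind=kind, nodelist=nl)
    if name in _SPECTRAL_MEASURES:
        kind, variant = _SPECTRAL_MEASURES[name]
        n_eig = params.get("n_eig")
        return lambda g1, g2, nl: spectral_distance(
            g1, g2, kind=kind, variant=variant, n_eig=n_eig, nodelist=nl
        )
    raise ValueError(
        f"unknown measure {name!r}; valid options: {sorted(MEASURES)}"
    )


#: the seven distance measures, as accepted by pairwise_distance_matrix
MEASURES: tuple[str, ...] = (
    "edit",
    "deltacon",
    "jsd",
    "lap_unnormalized",
    "lap_normalized",
    "nlap_unnormalized",
    "nlap_normalized",
)


def pairwise_distance_matrix(
    snaps: SnapshotSequence,
    measure: str,
    **params,
) -> DistanceMatrix:
    """All-pairs distance matrix between the snapshots of a sequence.

    Each of the t_max(t_max-1)/2 pairs is computed once; per-snapshot
    spectra (spectral measures) and density matrices (jsd) are cached
    and reused across pairs.
    """
    if measure not in MEASURES:
        raise ValueError(
            f"unknown measure {measure!r}; valid options: {sorted(MEASURES)}"
        )
    t_max = snaps.t_max
    if t_max < 2:
        raise ValueError("need at least 2 snapshots for a distance matrix")
    nodes = list(snaps.nodes)
    d = np.zeros((t_max, t_max))

    if measure in _SPECTRAL_MEASURES:
        kind, variant = _SPECTRAL_MEASURES[measure]
        n_eig = params.get("n_eig")
        spectra = [laplacian_spectrum(g, kind, nodes) for g in snaps.graphs]
        for i in range(t_max):
            for j in range(i + 1, t_max):
                d[i, j] = d[j, i] = spectral_distance_from_spectra(
                    spectra[i], spectra[j], variant=variant, n_eig=n_eig
                )
    elif measure == "jsd":
        beta = params.get("beta", 1.0)
        kind = params.get("kind", "combinatorial")
        rhos = [
            density_matrix(g, beta=beta, kind=kind, nodelist=nodes)
            for g in snaps.graphs
        ]
        for i in range(t_max):
            for j in range(i + 1, t_max):
                d[i, j] = d[j, i] = _jsd_from_density(rhos[i], rhos[j])
    else:
        fn = _pair_measure(measure, params)
        for i in range(t_max):
            for j in range(i + 1, t_max):
                d[i, j] = d[j, i] = fn(snaps.graphs[i], snaps.graphs[j], nodes)

    out = DistanceMatrix(d=d, measure=measure, params=dict(params))
    out.validate()
    return out
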