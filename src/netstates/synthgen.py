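"""Random-graph models and planted-state temporal networks.

Three static models with matched mean degree (about six at the default
parameters) supply controlled test beds for the distance measures:

* regular random graphs (RRG) — every node has exactly degree k;
* Barabási–Albert (BA) preferential attachment — power-law degrees
  with exponent three, grown from an m0-clique, node labels randomly
  permuted so the index carries no age information;
* the LFR community benchmark — power-law degrees and community
  sizes, with the mixing parameter mu setting the fraction of each
  node's edges that leave its community.  The degree sequence is drawn
  before mu enters the construction, so the degree distribution is
  independent of mu by design.

RRG-vs-BA pairs differ in degree heterogeneity; LFR pairs with small
and large mu differ only in community structure.  The planted-state
temporal generator strings independent draws from such models into a
contact sequence with a known state sequence, giving ground truth for
end-to-end state recovery.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .snapshots import ContactEvent, EventList
from .graphdist import (
    MEASURES,
    laplacian_spectrum,
    spectral_distance_from_spectra,
    _SPECTRAL_MEASURES,
    _pair_measure,
)

__all__ = [
    "RRGSpec",
    "BASpec",
    "LFRSpec",
    "ModelSpec",
    "PlantedTemporalSpec",
    "regular_random_graph",
    "barabasi_albert",
    "lfr_benchmark",
    "realized_mixing",
    "sample_graph",
    "model_distance_experiment",
    "planted_temporal_network",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class RRGSpec:
    """Regular random graph: every node has degree exactly k."""

    n: int = 100
    k: int = 6
    family = "RRG"

    def __post_init__(self) -> None:
        if self.k >= self.n:
            raise ValueError("RRG requires k < n")
        if (self.n * self.k) % 2 != 0:
            raise ValueError("RRG requires n*k even")


@dataclass(frozen=True)
class BASpec:
    """Barabási–Albert model grown from an m0-clique, m edges per arrival."""

    n: int = 100
    m0: int = 3
    m: int = 3
    family = "BA"

    def __post_init__(self) -> None:
        if not self.m <= self.m0 < self.n:
            raise ValueError("BA requires m <= m0 < n")


@dataclass(frozen=True)
class LFRSpec:
    """LFR community benchmark.

    Defaults follow the standard N=100 setting: mean degree 6, maximum
    degree N/4 = 25, degree exponent 2, community-size exponent 1.
    Community sizes default to the benchmark's usual convention of
    tracking the degree bounds (smallest communities a few nodes,
    largest ``max_degree`` nodes), which yields roughly ten planted
    communities at N=100.  ``mixing_tolerance`` bounds how far the
    realized per-node mixing (mean fraction of edges leaving the
    node's community) may drift from the nominal mu before the draw is
    rejected and regenerated.
    """

    mu: float = 0.1
    n: int = 100
    mean_degree: float = 6.0
    max_degree: int = 25
    degree_exponent: float = 2.0
    community_size_exponent: float = 1.0
    min_community: int = 3
    max_community: int = 25
    mixing_tolerance: float = 0.05
    max_retries: int = 100
    family = "LFR"

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError("LFR requires 0 < mu < 1")
        if self.max_degree >= self.n:
            raise ValueError("LFR requires max_degree < n")
        if self.degree_exponent <= 0 or self.community_size_exponent <= 0:
            raise ValueError("LFR exponents must be positive")
        if not 2 <= self.min_community <= self.max_community <= self.n:
            raise ValueError("invalid community size bounds")


ModelSpec = Union[RRGSpec, BASpec, LFRSpec]


def regular_random_graph(spec: RRGSpec, seed: int | None = None) -> nx.Graph:
    """Simple graph in which every node has degree exactly spec.k."""
    rng = np.random.default_rng(seed)
    G = nx.random_regular_graph(spec.k, spec.n, seed=int(rng.integers(_SEED_MOD)))
    return G


def barabasi_albert(spec: BASpec, seed: int | None = None) -> nx.Graph:
    """BA preferential attachment with randomly permuted node labels.

    Starts from a clique on m0 nodes; each arriving node attaches m
    edges to distinct existing nodes with probability proportional to
    degree.  Edge count is exactly m0(m0-1)/2 + m(n-m0).  The final
    labels are a uniform random permutation, so node index is
    uncorrelated with age and degree.
    """
    rng = np.random.default_rng(seed)
    G = nx.barabasi_albert_graph(
        spec.n,
        spec.m,
        seed=int(rng.integers(_SEED_MOD)),
        initial_graph=nx.complete_graph(spec.m0),
    )
    perm = rng.permutation(spec.n)
    return nx.relabel_nodes(G, {i: int(perm[i]) for i in range(spec.n)})


# ---------------------------------------------------------------------------
# LFR benchmark


@lru_cache(maxsize=32)
def _powerlaw_xmin(gamma: float, mean: float, kmax: int) -> float:
    """Lower cutoff of the continuous power law whose rounded samples
    have the requested mean.  Solved once by bisection."""
    xmax = kmax + 0.499

    def mean_of(xmin: float) -> float:
        ks = np.arange(max(1, int(np.floor(xmin))), kmax + 1)
        lo = np.clip(ks - 0.5, xmin, xmax)
        hi = np.clip(ks + 0.5, xmin, xmax)
        if gamma == 1.0:
            w = np.log(hi) - np.log(lo)
        else:
            w = lo ** (1.0 - gamma) - hi ** (1.0 - gamma)
        total = w.sum()
        if total <= 0:
            return float(kmax)
        return float((ks * w).sum() / total)

    lo_x, hi_x = 1.0, float(kmax)
    if mean_of(lo_x) > mean:
        raise ValueError("mean degree too small for the degree bounds")
    for _ in range(200):
        mid = 0.5 * (lo_x + hi_x)
        if mean_of(mid) < mean:
            lo_x = mid
        else:
            hi_x = mid
    return 0.5 * (lo_x + hi_x)


def _sample_degrees(spec: LFRSpec, rng: np.random.Generator) -> np.ndarray:
    gamma = spec.degree_exponent
    xmin = _powerlaw_xmin(gamma, spec.mean_degree, spec.max_degree)
    xmax = spec.max_degree + 0.499
    u = rng.random(spec.n)
    if gamma == 1.0:
        x = xmin * (xmax / xmin) ** u
    else:
        a, b = xmin ** (1.0 - gamma), xmax ** (1.0 - gamma)
        x = (a - u * (a - b)) ** (1.0 / (1.0 - gamma))
    k = np.clip(np.rint(x).astype(int), 1, spec.max_degree)
    if k.sum() % 2 != 0:
        i = int(rng.integers(spec.n))
        k[i] += 1 if k[i] < spec.max_degree else -1
    return k


def _sample_community_sizes(spec: LFRSpec, dint_max: int, rng: np.random.Generator) -> list[int]:
    smin, smax = spec.min_community, spec.max_community
    support = np.arange(smin, smax + 1)
    w = support.astype(float) ** (-spec.community_size_exponent)
    w /= w.sum()
    for _ in range(1000):
        sizes: list[int] = []
        while sum(sizes) < spec.n:
            sizes.append(int(rng.choice(support, p=w)))
        excess = sum(sizes) - spec.n
        if excess:
            if sizes[-1] - excess >= smin:
                sizes[-1] -= excess
            else:
                extra = sizes.pop()
                spread = extra - excess
                j = 0
                for _ in range(spread):
                    for _ in range(len(sizes)):
                        if sizes[j % len(sizes)] < smax:
                            sizes[j % len(sizes)] += 1
                            break
                        j += 1
                    j += 1
                if sum(sizes) != spec.n:
                    continue
        # the largest community must be able to host the most internal
        # edges any single node demands
        if max(sizes) >= dint_max + 1:
            return sizes
    raise ValueError(
        "could not sample feasible community sizes; "
        "raise max_community or lower mean/max degree"
    )


def _assign_communities(
    sizes: list[int], dint: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Random assignment honouring capacities and internal-degree fits."""
    n = dint.size
    n_com = len(sizes)
    member = -np.ones(n, dtype=int)
    counts = np.zeros(n_com, dtype=int)
    homeless = list(rng.permutation(n))
    for _ in range(2000 * n):
        if not homeless:
            return member
        i = homeless.pop()
        c = int(rng.integers(n_com))
        if dint[i] > sizes[c] - 1:
            homeless.insert(0, i)
            continue
        member[i] = c
        counts[c] += 1
        if counts[c] > sizes[c]:
            others = np.flatnonzero(member == c)
            evict = int(others[rng.integers(others.size)])
            member[evict] = -1
            counts[c] -= 1
            homeless.insert(0, evict)
    return None


def _pair_stubs(
    stubs: np.ndarray,
    rng: np.random.Generator,
    forbidden: set[frozenset],
    same_community_of: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Pair stubs into simple edges, repairing collisions by swaps.

    A pair is invalid if it is a self-loop, duplicates an existing or
    already-formed edge, or (external wiring) joins two nodes of the
    same community.  Invalid pairs are repaired by swapping endpoints
    with randomly chosen other pairs; the few that remain after
    bounded attempts are dropped.
    """
    stubs = rng.permutation(stubs)
    if stubs.size % 2:
        stubs = stubs[:-1]
    pairs = stubs.reshape(-1, 2)
    n_pairs = pairs.shape[0]
    if n_pairs == 0:
        return []

    def ok(a: int, b: int, edges: set[frozenset]) -> bool:
        if a == b:
            return False
        if same_community_of is not None and same_community_of[a] == same_community_of[b]:
            return False
        key = frozenset((a, b))
        return key not in forbidden and key not in edges

    edges: set[frozenset] = set()
    accepted: list[tuple[int, int]] = []
    bad: list[tuple[int, int]] = []
    for a, b in pairs:
        a, b = int(a), int(b)
        if ok(a, b, edges):
            edges.add(frozenset((a, b)))
            accepted.append((a, b))
        else:
            bad.append((a, b))

    for _ in range(20):
        if not bad or not accepted:
            break
        still_bad: list[tuple[int, int]] = []
        for a, b in bad:
            repaired = False
            for _ in range(20):
                j = int(rng.integers(len(accepted)))
                c, d = accepted[j]
                # propose (a, d) and (c, b)
                edges.discard(frozenset((c, d)))
                if ok(a, d, edges) and ok(c, b, edges | {frozenset((a, d))}):
                    edges.add(frozenset((a, d)))
                    edges.add(frozenset((c, b)))
                    accepted[j] = (a, d)
                    accepted.append((c, b))
                    repaired = True
                    break
                edges.add(frozenset((c, d)))
            if not repaired:
                still_bad.append((a, b))
        bad = still_bad
    return accepted


def _lfr_once(spec: LFRSpec, rng: np.random.Generator) -> nx.Graph | None:
    k = _sample_degrees(spec, rng)
    dint = np.rint((1.0 - spec.mu) * k).astype(int)
    dint = np.minimum(dint, k)
    sizes = _sample_community_sizes(spec, int(dint.max()), rng)
    member = _assign_communities(sizes, dint, rng)
    if member is None:
        return None

    n_com = len(sizes)
    G = nx.Graph()
    G.add_nodes_from(range(spec.n))
    all_edges: set[frozenset] = set()

    for c in range(n_com):
        nodes_c = np.flatnonzero(member == c)
        dc = dint[nodes_c].copy()
        if dc.sum() % 2:
            room = np.flatnonzero((dc < k[nodes_c]) & (dc < nodes_c.size - 1))
            if room.size:
                dc[room[int(rng.integers(room.size))]] += 1
            else:
                pos = np.flatnonzero(dc > 0)
                dc[pos[int(rng.integers(pos.size))]] -= 1
        stubs = np.repeat(nodes_c, dc)
        for a, b in _pair_stubs(stubs, rng, all_edges):
            all_edges.add(frozenset((a, b)))
            G.add_edge(a, b)

    # remaining stubs (including any internal pairing shortfall) are wired
    # externally, keeping the realized degree sequence at the sampled one
    internal_realized = np.array([G.degree(i) for i in range(spec.n)])
    ext_stubs = np.clip(k - internal_realized, 0, None)
    stubs = np.repeat(np.arange(spec.n), ext_stubs)
    for a, b in _pair_stubs(stubs, rng, all_edges, same_community_of=member):
        all_edges.add(frozenset((a, b)))
        G.add_edge(a, b)

    nx.set_node_attributes(G, {i: int(member[i]) for i in range(spec.n)}, "community")
    return G


def realized_mixing(G: nx.Graph) -> float:
    """Mean over nodes of the fraction of edges leaving the node's community."""
    fracs = []
    for u in G:
        deg = G.degree(u)
        if deg == 0:
            continue
        cu = G.nodes[u]["community"]
        ext = sum(1 for v in G[u] if G.nodes[v]["community"] != cu)
        fracs.append(ext / deg)
    if not fracs:
        raise ValueError("graph has no edges; mixing undefined")
    return float(np.mean(fracs))


def lfr_benchmark(spec: LFRSpec, seed: int | None = None) -> nx.Graph:
    """LFR benchmark graph with planted communities.

    Degrees are drawn from a truncated power law calibrated to the
    requested mean, community sizes from a power law on
    [min_community, max_community]; each node splits its degree into
    round((1-mu)*k) internal and the rest external stubs, wired by
    configuration-model pairing with swap repairs.  Draws whose
    realized mean mixing deviates from mu by more than
    ``mixing_tolerance`` are rejected; after ``max_retries`` failures
    an error reports the seed.

    Community membership is stored in the ``community`` node attribute.
    """
    rng = np.random.default_rng(seed)
    for _ in range(spec.max_retries):
        G = _lfr_once(spec, rng)
        if G is None or G.number_of_edges() == 0:
            continue
        mix = realized_mixing(G)
        if abs(mix - spec.mu) <= spec.mixing_tolerance:
            G.graph["mu_realized"] = mix
            return G
    raise ValueError(
        f"LFR generation failed after {spec.max_retries} retries (seed={seed}); "
        "realized mixing never matched mu within tolerance"
    )


def sample_graph(spec: ModelSpec, seed: int | None = None) -> nx.Graph:
    """Draw one graph from any of the three model families."""
    if isinstance(spec, RRGSpec):
        return regular_random_graph(spec, seed)
    if isinstance(spec, BASpec):
        return barabasi_albert(spec, seed)
    if isinstance(spec, LFRSpec):
        return lfr_benchmark(spec, seed)
    raise TypeError(f"unknown model spec {type(spec).__name__}")


# ---------------------------------------------------------------------------
# model-discrimination experiment


def model_distance_experiment(
    spec_a: ModelSpec,
    spec_b: ModelSpec,
    n_pairs: int = 1000,
    measures: str | Sequence[str] = "nlap_normalized",
    params: Mapping | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Within- and between-model distance statistics.

    For each of the three comparisons — within model A, within model B,
    and between the two models — draws ``n_pairs`` fresh independent
    pairs of graphs and records the mean and standard deviation of the
    distance under each measure.  ``mean_norm``/``sd_norm`` rescale per
    measure so that the between-model mean is exactly one.

    Returns a DataFrame indexed by (measure, comparison) where the
    comparison is one of ``"AA"``, ``"BB"``, ``"AB"``.
    """
    if n_pairs < 2:
        raise ValueError("need n_pairs >= 2")
    if isinstance(measures, str):
        measures = [measures]
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}; valid options: {sorted(MEASURES)}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    spectral_kinds = {
        _SPECTRAL_MEASURES[m][0] for m in measures if m in _SPECTRAL_MEASURES
    }
    other = [m for m in measures if m not in _SPECTRAL_MEASURES]
    pair_fns = {m: _pair_measure(m, params) for m in other}

    values: dict[tuple[str, str], list[float]] = {
        (m, comp): [] for m in measures for comp in ("AA", "BB", "AB")
    }
    for comp, (sa, sb) in (
        ("AA", (spec_a, spec_a)),
        ("BB", (spec_b, spec_b)),
        ("AB", (spec_a, spec_b)),
    ):
        for _ in range(n_pairs):
            g1 = sample_graph(sa, int(rng.integers(_SEED_MOD)))
            g2 = sample_graph(sb, int(rng.integers(_SEED_MOD)))
            nodelist = sorted(set(g1.nodes) | set(g2.nodes), key=str)
            spectra = {
                kind: (
                    laplacian_spectrum(g1, kind, nodelist),
                    laplacian_spectrum(g2, kind, nodelist),
                )
                for kind in spectral_kinds
            }
            for m in measures:
                if m in _SPECTRAL_MEASURES:
                    kind, variant = _SPECTRAL_MEASURES[m]
                    s1, s2 = spectra[kind]
                    d = spectral_distance_from_spectra(
                        s1, s2, variant=variant, n_eig=params.get("n_eig")
                    )
                else:
                    d = pair_fns[m](g1, g2, nodelist)
                values[(m, comp)].append(d)

    rows = []
    for m in measures:
        ab_mean = float(np.mean(values[(m, "AB")]))
        for comp in ("AA", "BB", "AB"):
            v = np.asarray(values[(m, comp)])
            rows.append(
                {
                    "measure": m,
                    "comparison": comp,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)),
                    "mean_norm": float(v.mean() / ab_mean) if ab_mean else np.nan,
                    "sd_norm": float(v.std(ddof=1) / ab_mean) if ab_mean else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index(["measure", "comparison"])


# ---------------------------------------------------------------------------
# planted-state temporal networks


@dataclass(frozen=True)
class PlantedTemporalSpec:
    """Ground-truth state sequence with one graph model per state."""

    states: tuple[int, ...]
    models: Mapping[int, ModelSpec]
    tau: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        missing = set(self.states) - set(self.models)
        if missing:
            raise ValueError(f"states without a model spec: {sorted(missing)}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def t_max(self) -> int:
        return len(self.states)


def planted_temporal_network(
    spec: PlantedTemporalSpec, seed: int | None = None
) -> tuple[EventList, np.ndarray]:
    """Contact sequence with a known per-window state sequence.

    For each window t an independent graph is drawn from the model of
    state s_t; each edge emits one event at a uniformly random time
    inside the half-open window [(t-1)*tau, t*tau).  Returns the event
    list (time origin fixed at 0 so binning with the same tau
    reproduces each window's edge set exactly) and the ground-truth
    labels for scoring.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    tau = spec.tau
    events: list[ContactEvent] = []
    nodes: set = set()
    for t, s in enumerate(spec.states):
        g = sample_graph(spec.models[s], int(rng.integers(_SEED_MOD)))
        nodes.update(g.nodes)
        for u, v in g.edges:
            time = (t + float(rng.random())) * tau
            events.append(ContactEvent(time=time, u=u, v=v))
    events.sort(key=lambda e: e.time)
    labels = np.asarray(spec.states, dtype=int)
    return EventList(events=events, time_origin=0.0), labels
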