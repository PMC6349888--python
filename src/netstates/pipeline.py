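"""End-to-end orchestration: events -> snapshots -> distances -> states.

A run executes the full workflow on one contact sequence: read the
events, bin them into windows of length tau, compute the pairwise
snapshot distance matrix under the chosen measure, cluster it with
single linkage, select the number of states by Dunn's index, and emit
the state sequence plus the similarity matrix.  All tabular artefacts
are TSV with ``# key=value`` provenance headers; the TSV outputs are
the interface of record (plots are optional and non-authoritative).

The default measure is the normalised spectrum distance on the
normalised Laplacian, the most reliable discriminator of structurally
distinct snapshots among the seven measures.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .snapshots import (
    EventList,
    SnapshotSequence,
    bin_events,
    event_rate_series,
    read_contact_sequence,
    write_snapshots,
)
from .graphdist import MEASURES, DistanceMatrix, pairwise_distance_matrix
from .statecluster import (
    Dendrogram,
    SimilarityMatrix,
    StateAssignment,
    select_states,
    single_linkage,
    to_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunResult",
    "run",
    "run_events",
    "compare_measures",
    "write_distance_matrix",
    "read_distance_matrix",
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``input`` is a contact-sequence path or an in-memory
    :class:`EventList`; ``measure`` is one of the identifiers in
    :data:`netstates.graphdist.MEASURES` with measure parameters
    (``beta``, ``n_eig``, ``kind``, ``node_mode``) in ``params``.
    """

    input: str | Path | EventList
    tau: float
    measure: str = "nlap_normalized"
    params: dict = field(default_factory=dict)
    columns: Mapping[str, int] | None = None
    time_origin: float | None = None
    drop_partial: bool = True
    weighted: bool = False
    outdir: str | Path | None = None
    seed: int | None = None
    plot: bool = False

    def validate(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.measure not in MEASURES:
            raise ValueError(
                f"unknown measure {self.measure!r}; valid options: {sorted(MEASURES)}"
            )


@dataclass
class RunResult:
    """All artefacts of one run, with provenance."""

    snapshots: SnapshotSequence
    distance: DistanceMatrix
    similarity: SimilarityMatrix
    dendrogram: Dendrogram
    states: StateAssignment
    event_rate: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def t_max(self) -> int:
        return self.snapshots.t_max


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_events(
    events: EventList,
    tau: float,
    measure: str = "nlap_normalized",
    params: Mapping | None = None,
    *,
    drop_partial: bool = True,
    weighted: bool = False,
) -> RunResult:
    """Library entry point: full workflow on an in-memory event list."""
    cfg = RunConfig(
        input=events,
        tau=tau,
        measure=measure,
        params=dict(params or {}),
        drop_partial=drop_partial,
        weighted=weighted,
    )
    return run(cfg)


def run(config: RunConfig) -> RunResult:
    """Execute the full workflow described by ``config``.

    Stages: read -> bin -> pairwise distances -> single linkage ->
    state selection -> similarity.  Each stage failure is re-raised
    with the stage name; fewer than three windows is an error (no
    meaningful state selection is possible).
    """
    config.validate()

    if isinstance(config.input, EventList):
        events = config.input
        if config.time_origin is not None:
            events = EventList(
                events=events.events, nodes=events.nodes, time_origin=config.time_origin
            )
        input_desc = f"<in-memory: {len(events)} events>"
    else:
        events = _stage("read")(
            read_contact_sequence,
            config.input,
            config.columns,
            time_origin=config.time_origin,
        )
        input_desc = str(config.input)

    snaps = _stage("bin")(
        bin_events,
        events,
        config.tau,
        drop_partial=config.drop_partial,
        weighted=config.weighted,
    )
    if snaps.t_max < 3:
        raise ValueError(f"too few windows: t_max={snaps.t_max} < 3")
    logger.info("binned %d events into %d windows of tau=%s",
                len(events), snaps.t_max, config.tau)

    dist = _stage("distances")(
        pairwise_distance_matrix, snaps, config.measure, **config.params
    )
    dend = _stage("linkage")(single_linkage, dist)
    states = _stage("select_states")(select_states, dist, dend)
    sim = _stage("similarity")(to_similarity, dist)
    rates = event_rate_series(snaps)

    provenance = {
        "tool": "netstates",
        "version": __version__,
        "input": input_desc,
        "input_hash": _input_hash(config.input),
        "tau": config.tau,
        "measure": config.measure,
        "params": dict(config.params),
        "drop_partial": config.drop_partial,
        "weighted": config.weighted,
        "time_origin": float(events.time_origin),
        "n_nodes": events.n_nodes,
        "t_max": snaps.t_max,
        "node_registry_hash": _registry_hash(snaps.nodes),
        "seed": config.seed,
    }
    result = RunResult(
        snapshots=snaps,
        distance=dist,
        similarity=sim,
        dendrogram=dend,
        states=states,
        event_rate=rates,
        provenance=provenance,
    )
    if config.outdir is not None:
        write_result(result, config.outdir, plot=config.plot)
    return result


def compare_measures(
    config: RunConfig, measures: Sequence[str]
) -> tuple[dict[str, RunResult], pd.DataFrame]:
    """Run several measures on shared snapshots and score their agreement.

    Snapshots are binned once.  Returns per-measure results and the
    pairwise adjusted-Rand-index table between the measures' state
    sequences (diagonal 1 by definition).
    """
    if len(measures) < 2:
        raise ValueError("need at least 2 measures to compare")
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}; valid options: {sorted(MEASURES)}")

    results: dict[str, RunResult] = {}
    for m in measures:
        cfg = RunConfig(
            input=config.input,
            tau=config.tau,
            measure=m,
            params=dict(config.params) if m == config.measure else {},
            columns=config.columns,
            time_origin=config.time_origin,
            drop_partial=config.drop_partial,
            weighted=config.weighted,
        )
        results[m] = run(cfg)

    agreement = pd.DataFrame(
        index=list(measures), columns=list(measures), dtype=float
    )
    for a in measures:
        for b in measures:
            agreement.loc[a, b] = adjusted_rand_score(
                results[a].states.labels, results[b].states.labels
            )
    return results, agreement


# ---------------------------------------------------------------------------
# serialisation


def _provenance_header(prov: Mapping) -> str:
    return "".join(f"# {k}={v}\n" for k, v in prov.items())


def _input_hash(source) -> str:
    if isinstance(source, (str, Path)) and Path(source).exists():
        return hashlib.sha256(Path(source).read_bytes()).hexdigest()[:16]
    if isinstance(source, EventList):
        h = hashlib.sha256()
        for e in source.events:
            h.update(f"{e.time},{e.u},{e.v},{e.weight};".encode())
        return h.hexdigest()[:16]
    return "unknown"


def _registry_hash(nodes: Sequence) -> str:
    return hashlib.sha256(",".join(map(str, nodes)).encode()).hexdigest()[:16]


def _write_matrix(path: Path, mat: np.ndarray, prov: Mapping) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(prov))
        t_max = mat.shape[0]
        fh.write("\t" + "\t".join(str(i + 1) for i in range(t_max)) + "\n")
        for i in range(t_max):
            fh.write(
                str(i + 1) + "\t" + "\t".join(repr(float(x)) for x in mat[i]) + "\n"
            )


def write_distance_matrix(
    dist: DistanceMatrix, path: str | Path, provenance: Mapping | None = None
) -> None:
    """Dense TSV with window indices, plus a JSON sidecar recording the
    measure, its parameters and any extra provenance (e.g. the node
    registry hash)."""
    import json

    path = Path(path)
    prov = {"measure": dist.measure, "params": dict(dist.params)}
    _write_matrix(path, dist.d, prov)
    sidecar = {**prov, **dict(provenance or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a distance matrix written by :func:`write_distance_matrix`."""
    measure = ""
    params: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    rows = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "measure":
                measure = value.strip()
            continue
        rows.append(line.rstrip("\n").split("\t"))
    body = rows[1:]  # skip header row of window indices
    d = np.array([[float(x) for x in r[1:]] for r in body])
    return DistanceMatrix(d=d, measure=measure, params=params)


def write_result(result: RunResult, outdir: str | Path, plot: bool = False) -> Path:
    """Write every artefact of a run as TSV files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = result.provenance

    write_snapshots(result.snapshots, outdir / "snapshots")

    write_distance_matrix(
        result.distance, outdir / "distance.tsv",
        provenance={"node_registry_hash": prov.get("node_registry_hash")},
    )
    _write_matrix(outdir / "similarity.tsv", result.similarity.sim,
                  {**prov, "matrix": "similarity"})

    starts = result.snapshots.window_starts
    states = pd.DataFrame(
        {
            "window": np.arange(1, result.t_max + 1),
            "start_time": starts,
            "state": result.states.labels,
            "events_per_node": result.event_rate,
        }
    )
    with open(outdir / "states.tsv", "w") as fh:
        fh.write(_provenance_header({**prov, "C": result.states.C}))
        states.to_csv(fh, sep="\t", index=False)

    dunn = pd.DataFrame(
        sorted(result.states.dunn_by_C.items()), columns=["C", "dunn"]
    )
    with open(outdir / "dunn.tsv", "w") as fh:
        fh.write(_provenance_header({**prov, "selected_C": result.states.C}))
        dunn.to_csv(fh, sep="\t", index=False)

    dend = pd.DataFrame(
        result.dendrogram.Z, columns=["cluster_a", "cluster_b", "height", "size"]
    )
    with open(outdir / "dendrogram.tsv", "w") as fh:
        fh.write(_provenance_header(prov))
        dend.to_csv(fh, sep="\t", index=False)

    if plot:
        from .plotting import plot_state_dynamics

        plot_state_dynamics(result, outdir / "state_dynamics.png")
    return outdir
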