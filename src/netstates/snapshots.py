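"""Contact-sequence ingestion and time-window aggregation.

A temporal network is represented as a *contact sequence*: a plain-text
event list with one interaction per line (``time  node_i  node_j
[weight]``), the standard dialect of proximity-sensor studies.  Events
are binned into consecutive, non-overlapping windows of length ``tau``;
the t-th snapshot graph aggregates all events with (origin-shifted)
timestamps in the half-open interval ``[(t-1)*tau, t*tau)``.

Every snapshot is defined on the *global* node registry — the union of
all node identifiers appearing anywhere in the data — padding windows
with isolated nodes.  This keeps all adjacency matrices at a common
dimension, which the spectral distance measures require.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ContactEvent",
    "EventList",
    "SnapshotSequence",
    "read_contact_sequence",
    "bin_events",
    "event_rate_series",
    "write_snapshots",
]

#: default column order of the ``tij`` dialect
DEFAULT_COLUMNS: Mapping[str, int] = {"time": 0, "u": 1, "v": 2}


@dataclass(frozen=True)
class ContactEvent:
    """A single time-stamped interaction between two nodes."""

    time: float
    u: str
    v: str
    weight: float = 1.0


@dataclass
class EventList:
    """Time-sorted contact events plus the global node registry.

    Parameters
    ----------
    events
        Events sorted non-decreasingly in time; self-events removed.
    nodes
        Ordered registry of every node identifier in the data.
    time_origin
        Timestamp that maps to window time 0.  Defaults to the first
        event's timestamp; override it to align windows to wall-clock
        boundaries.
    """

    events: list[ContactEvent]
    nodes: tuple[str, ...] = field(default_factory=tuple)
    time_origin: float | None = None

    def __post_init__(self) -> None:
        if not self.nodes:
            self.nodes = _registry(self.events)
        if self.time_origin is None and self.events:
            self.time_origin = self.events[0].time

    def __len__(self) -> int:
        return len(self.events)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def span(self) -> float:
        """Observation span from the time origin to the last event."""
        if not self.events:
            return 0.0
        return self.events[-1].time - float(self.time_origin)


@dataclass
class SnapshotSequence:
    """A sequence of ``t_max`` static graphs, one per window of length tau.

    All graphs share the identical, identically ordered node set
    (``nodes``); nodes inactive in a window appear as isolates.
    """

    tau: float
    graphs: list[nx.Graph]
    nodes: tuple[str, ...]
    weighted: bool = False
    per_window_event_count: np.ndarray | None = None
    window_starts: np.ndarray | None = None

    @property
    def t_max(self) -> int:
        return len(self.graphs)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def __len__(self) -> int:
        return self.t_max

    def __iter__(self):
        return iter(self.graphs)


def _registry(events: Sequence[ContactEvent]) -> tuple[str, ...]:
    names = {e.u for e in events} | {e.v for e in events}
    return tuple(sorted(names, key=_node_key))


def _node_key(name: str):
    # numeric ids sort numerically, everything else lexicographically
    try:
        return (0, float(name), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(name))


def read_contact_sequence(
    path: str | Path,
    column_spec: Mapping[str, int] | None = None,
    *,
    time_origin: float | None = None,
    deduplicate: bool = False,
) -> EventList:
    """Parse a whitespace/tab-separated contact sequence file.

    Parameters
    ----------
    path
        Event-list file; one event per line, ``#`` comments allowed.
    column_spec
        Maps ``time``/``u``/``v`` (and optionally ``weight``) to
        0-based column indices.  Defaults to the ``tij`` order.
    time_origin
        Override for the window origin (default: first event's time).
    deduplicate
        Drop byte-identical duplicate events.  Off by default: sensors
        legitimately re-report contacts, and repeated events carry
        weight in weighted mode.

    Raises
    ------
    ValueError
        On an empty file, unresolvable columns, or malformed lines
        (the error names the first offending line number).
    """
    cols = dict(column_spec or DEFAULT_COLUMNS)
    for key in ("time", "u", "v"):
        if key not in cols:
            raise ValueError(f"column_spec must map {key!r} to a column index")

    try:
        table = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#", dtype=str, engine="python"
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"no events in {path}") from None

    needed = max(cols.values()) + 1
    if table.shape[1] < needed:
        bad = table[table.notna().sum(axis=1) < needed]
        line = int(bad.index[0]) + 1 if len(bad) else 1
        raise ValueError(
            f"{path}: line {line}: expected at least {needed} columns, "
            f"found {table.shape[1]}"
        )

    times = pd.to_numeric(table.iloc[:, cols["time"]], errors="coerce")
    if times.isna().any():
        line = int(times.index[times.isna()][0]) + 1
        raise ValueError(f"{path}: line {line}: non-numeric timestamp")

    short = table.iloc[:, [cols["u"], cols["v"]]].isna().any(axis=1)
    if short.any():
        line = int(short.index[short][0]) + 1
        raise ValueError(f"{path}: line {line}: missing node identifier")

    if "weight" in cols:
        weights = pd.to_numeric(table.iloc[:, cols["weight"]], errors="coerce")
        if weights.isna().any():
            line = int(weights.index[weights.isna()][0]) + 1
            raise ValueError(f"{path}: line {line}: non-numeric weight")
        weights = weights.to_numpy(dtype=float)
    else:
        weights = np.ones(len(table))

    u = table.iloc[:, cols["u"]].astype(str).to_numpy()
    v = table.iloc[:, cols["v"]].astype(str).to_numpy()
    t = times.to_numpy(dtype=float)

    self_mask = u == v
    if self_mask.any():
        logger.info("dropped %d self-event(s)", int(self_mask.sum()))

    events = [
        ContactEvent(float(ti), ui, vi, float(wi))
        for ti, ui, vi, wi in zip(t, u, v, weights)
        if ui != vi
    ]
    if not events:
        raise ValueError(f"no events in {path}")
    if deduplicate:
        seen: set[tuple] = set()
        unique = []
        for e in events:
            key = (e.time, e.u, e.v, e.weight)
            if key not in seen:
                seen.add(key)
                unique.append(e)
        events = unique
    events.sort(key=lambda e: e.time)
    return EventList(events=events, time_origin=time_origin)


def bin_events(
    events: EventList,
    tau: float,
    *,
    drop_partial: bool = True,
    weighted: bool = False,
) -> SnapshotSequence:
    """Aggregate events into snapshot graphs over windows of length tau.

    An event at origin-shifted time ``s`` lands in window
    ``floor(s / tau) + 1`` (1-based); window t covers the half-open
    interval ``[(t-1)*tau, t*tau)``.  Multiple events on the same node
    pair within a window collapse to a single edge (unweighted mode) or
    to an edge carrying the summed event weights (weighted mode).

    With ``drop_partial`` (default) a trailing window not fully covered
    by the observation span ``[time_origin, last event time]`` is
    discarded, so ``t_max = floor(span / tau)``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not events.events:
        raise ValueError("no events to bin")

    origin = float(events.time_origin)
    shifted = np.array([e.time - origin for e in events.events])
    early = shifted < 0
    if early.any():
        logger.warning(
            "dropped %d event(s) before the time origin", int(early.sum())
        )
    idx = np.floor(shifted / tau).astype(int)  # 0-based window index

    span = events.span
    if drop_partial:
        t_max = int(np.floor(span / tau))
    else:
        t_max = int(idx[~early].max()) + 1 if (~early).any() else 0
    if t_max < 1:
        raise ValueError(
            "observation span shorter than one window; no complete snapshot"
        )
    if t_max == 1:
        warnings.warn(
            "all events fall in a single window; clustering will be degenerate",
            stacklevel=2,
        )

    nodes = events.nodes
    counts = np.zeros(t_max, dtype=int)
    graphs = []
    for _ in range(t_max):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        graphs.append(g)

    for e, s, t in zip(events.events, shifted, idx):
        if s < 0 or t >= t_max:
            continue
        counts[t] += 1
        g = graphs[t]
        if weighted:
            w = g.edges[e.u, e.v]["weight"] if g.has_edge(e.u, e.v) else 0.0
            g.add_edge(e.u, e.v, weight=w + e.weight)
        else:
            g.add_edge(e.u, e.v)

    starts = origin + tau * np.arange(t_max)
    return SnapshotSequence(
        tau=tau,
        graphs=graphs,
        nodes=nodes,
        weighted=weighted,
        per_window_event_count=counts,
        window_starts=starts,
    )


def event_rate_series(snaps: SnapshotSequence) -> np.ndarray:
    """Events per individual in each window: count_t / N."""
    if snaps.per_window_event_count is None:
        raise ValueError("snapshot sequence has no per-window event counts")
    return snaps.per_window_event_count / snaps.n_nodes


def write_snapshots(snaps: SnapshotSequence, outdir: str | Path) -> Path:
    """Write one edge-list TSV per window plus a window index table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t, g in enumerate(snaps.graphs, start=1):
        with open(outdir / f"snapshot_{t:04d}.tsv", "w") as fh:
            for u, v, data in g.edges(data=True):
                if snaps.weighted:
                    fh.write(f"{u}\t{v}\t{data.get('weight', 1.0)}\n")
                else:
                    fh.write(f"{u}\t{v}\n")
    index = pd.DataFrame(
        {
            "window": np.arange(1, snaps.t_max + 1),
            "start_time": snaps.window_starts,
            "end_time": snaps.window_starts + snaps.tau,
            "n_events": snaps.per_window_event_count,
        }
    )
    path = outdir / "windows.tsv"
    index.to_csv(path, sep="\t", index=False)
    return path
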