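"""Parse a contact sequence and bin it into snapshot graphs.

Builds a tiny proximity-style event list (time, node_i, node_j), reads
it back with the standard tij parser, and aggregates events into
20-minute windows.  The per-window event rate is the paper-and-pencil
sanity check: events in the window divided by the number of nodes.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from netstates import bin_events, event_rate_series, read_contact_sequence

CONTACTS = """\
0   alice  bob
3   alice  carol
12  bob    carol
21  bob    dave
25  alice  dave
44  carol  dave
59  alice  bob
"""

with TemporaryDirectory() as tmp:
    path = Path(tmp) / "contacts.tsv"
    path.write_text(CONTACTS)
    events = read_contact_sequence(path)
    snaps = bin_events(events, tau=20.0, drop_partial=False)

print(f"{len(events)} events over {events.n_nodes} nodes, span {events.span:.0f} min")
print(f"tau=20 min -> t_max={snaps.t_max} windows")
for t, g in enumerate(snaps.graphs, start=1):
    print(f"  window {t}: edges={sorted(tuple(sorted(e)) for e in g.edges)}")
print("events per node per window:", [float(r) for r in event_rate_series(snaps)])
# Each window is a static graph on the full node registry; inactive
# nodes stay as isolates so all windows share one matrix dimension.
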