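# netstates

Detect recurrent discrete **system states** in temporal networks.

Many interacting systems — school children wearing proximity sensors,
students' Bluetooth contacts, dynamic protein interactions, functional
brain connectivity — leave a stream of time-stamped pairwise events.
`netstates` condenses such a stream into a coarse-grained narrative: a
time series of discrete states, where each state is a group of time
windows whose interaction networks look alike.

## Method

1. **Windowing.** The event list is split into `t_max` consecutive
   non-overlapping windows of length τ; window *t* aggregates all
   events in `[(t−1)τ, tτ)` into one static snapshot graph on the
   global node set.
2. **Graph distances.** Every pair of snapshots is compared with one of
   seven measures: labelled graph edit distance, exact DELTACON,
   quantum spectral Jensen–Shannon divergence
   (ρ = e^{−βL}/tr e^{−βL}, entropies in bits), and four Laplacian
   spectrum distances — the Euclidean distance between sorted spectra
   of the combinatorial Laplacian L = D − A or the normalised
   Laplacian L′ = I − D^{−1/2}AD^{−1/2}, raw or divided by the larger
   spectral energy (which bounds the distance by √2).
3. **Clustering.** Single-linkage hierarchical clustering of the
   distance matrix; the number of states C is chosen by maximising
   Dunn's index, the smallest between-state distance divided by the
   largest within-state diameter, over the dendrogram cuts
   2 ≤ C ≤ t_max.

A synthetic module supplies regular random graphs, Barabási–Albert
graphs and an LFR community benchmark (all calibrated to mean degree
≈ 6 at N = 100), model-pair discrimination experiments, and
planted-state temporal networks with ground truth for end-to-end
validation.

## Worked example

Simulate a temporal network alternating every window between a
4-regular regime and a scale-free regime (similar event rates,
different structure), then run the full pipeline
(`examples/04_planted_state_recovery.py`):

```python
from sklearn.metrics import adjusted_rand_score
from netstates import BASpec, PlantedTemporalSpec, RRGSpec, planted_temporal_network
from netstates.pipeline import run_events

spec = PlantedTemporalSpec(
    states=(1, 2) * 6,
    models={1: RRGSpec(n=60, k=4), 2: BASpec(n=60, m0=3, m=3)},
    tau=1.0, seed=5,
)
events, truth = planted_temporal_network(spec)
result = run_events(events, tau=1.0, drop_partial=False)
print(result.states.C, adjusted_rand_score(truth, result.states.labels))
```

Output:

```
simulated 1764 events over 12 windows
selected number of states C = 2
truth     : 1 2 1 2 1 2 1 2 1 2 1 2
recovered : 1 2 1 2 1 2 1 2 1 2 1 2
adjusted Rand index vs truth = 1.000
Dunn's index at C=2..5: {2: 3.56, 3: 0.795, 4: 0.779, 5: 0.903}
```

C = 2 states were selected because Dunn's index peaks at the two-state
cut (3.56, far above every other cut), and the recovered alternating
label sequence matches the planted truth exactly (ARI = 1).

The command-line interface mirrors the library:

```sh
netstates simulate --states 1,2,1,2,1,2 -o contacts.tsv
netstates run contacts.tsv --tau 1 --time-origin 0 --keep-partial -o out/
```

writes the states, distance/similarity matrices, Dunn trace and
dendrogram as TSV files with provenance headers.

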