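# Methods

## Model and procedure

A temporal network is a contact sequence: events (t, u, v[, w]) between
labelled nodes.  The analysis assumes the system occupies, at every
moment, one of a small number of recurrent discrete states, and that
the state is expressed in the *structure* of the interaction network —
not necessarily in the event rate.  The pipeline estimates the state
sequence in three conventional steps combined into one workflow:
consecutive non-overlapping windows of length τ aggregate events into
snapshot graphs; a graph distance is evaluated on all snapshot pairs;
single-linkage hierarchical clustering of the distance matrix groups
snapshots, each cluster being a state, with the number of states chosen
by Dunn's index.

Snapshots are undirected and simple by default (weighted aggregation is
a flag; direction is out of scope).  Every snapshot is defined on the
global node registry — the union of all nodes observed anywhere — with
inactive nodes as isolates, so all adjacency matrices share one
dimension N, as the spectral distances require.

### Windowing

An event at origin-shifted time s falls in window ⌊s/τ⌋ + 1; windows
are half-open [(t−1)τ, tτ).  The time origin defaults to the first
event and can be overridden to align windows with wall clocks.  A
trailing window not fully covered by the observation span is dropped by
default (`drop_partial`): a 515-minute recording day at τ = 20 min
yields exactly ⌊515/20⌋ = 25 windows.  τ is a free parameter chosen by
the analyst; the package deliberately offers no automatic τ selection.

### Distance measures

* **Edit distance** (labelled, no vertex matching):
  d = N(G₁) + N(G₂) − 2N(G₁∩G₂) + M(G₁) + M(G₂) − 2M(G₁∩G₂) over
  common nodes and edges.  In the default `active` mode N(G) counts
  non-isolated nodes, since on a global registry the node terms would
  always cancel; `global` mode reduces d to the edge symmetric
  difference.  Weighted input is refused rather than silently
  binarised.
* **DELTACON** (exact variant): per-graph node-affinity matrices
  S = [I + ε²D − εA]⁻¹ with ε = 1/(1 + d_max) shared by the two graphs
  (a common ε keeps the measure symmetric), compared by the Matusita
  distance √Σ(√S₁ − √S₂)².  In the all-pairs matrix ε is recomputed
  per pair, so matrix entries equal independent pairwise calls exactly;
  affinities are therefore not cached across pairs.
* **Quantum spectral Jensen–Shannon distance**: density matrix
  ρ = e^{−βL}/tr e^{−βL} (computed by eigendecomposition with the
  smallest eigenvalue factored out), von Neumann entropies in bits,
  d = √(S((ρ₁+ρ₂)/2) − [S(ρ₁)+S(ρ₂)]/2) ∈ [0, 1].  β > 0 is the
  diffusion time: small β probes local structure, large β global
  structure.  Default β = 1, with 0.1 and 10 as the usual alternates.
  A radicand in [−1e−10, 0) is clamped to zero.
* **Laplacian spectrum distances**: for L = D − A or
  L′ = I − D^{−1/2}AD^{−1/2}, the Euclidean distance between the n_eig
  largest eigenvalues (default n_eig = N).  The *max-normalised*
  variant divides the squared sum by the larger of the two spectral
  energies before the root, bounding d by √2 (a min-normaliser would
  be unbounded); two empty graphs get distance 0.  Eigenvalues come
  from a full dense symmetric decomposition (data sets here have
  N up to a few thousand), sorted ascending, with negatives above
  −1e−9 clipped to zero.

Isolated nodes make D^{−1/2} undefined; the corresponding rows and
columns of L′ are set to zero, so each isolate contributes one zero
eigenvalue and the spectrum stays in [0, 2] at full dimension N.
Isolates then never inflate a distance — appropriate for sensor data
where most of the registry is inactive in any one window.

The default measure is the max-normalised spectrum distance on the
normalised Laplacian.  The combinatorial Laplacian's largest eigenvalue
tracks the largest degree, so degree fluctuations drown the small
eigenvalues that encode community structure; the normalised Laplacian's
spectrum is confined to [0, 2] and remains sensitive to it.  The
model-discrimination experiment reproduces this: both normalised-
Laplacian variants separate LFR ensembles with mixing μ = 0.1 from
μ = 0.9 by ≥ 2 within-model SDs, while the combinatorial variants and
the edit distance do not (edit ≈ 0σ), and all four spectral variants
separate regular random graphs from Barabási–Albert graphs.

### Clustering and state selection

Single linkage ("shortest distance" between clusters) is computed by
the minimum-spanning-tree formulation; merge heights are the sorted MST
edge weights and hence independent of tie-breaking, and the merge order
under ties follows the implementation's deterministic MST order, making
results bit-reproducible.  Cutting the dendrogram after t_max − C
merges gives the C-state partition; labels are renumbered by first
appearance in time so state 1 always begins at window 1.

Dunn's index of a partition is (min inter-state distance)/(max
intra-state diameter), with singleton diameter 0.  C is the smallest
maximiser over the dendrogram cuts 2 ≤ C ≤ t_max.  Cuts whose largest
diameter is zero (e.g. duplicate snapshots cut into singletons) leave
the index undefined and are excluded — otherwise the all-singleton cut
would trivially dominate.  Candidate partitions are restricted to
dendrogram cuts, not arbitrary labellings.  Both the merge heights and
the index are verified against naive brute-force implementations on
1,000 random instances.

For visualisation the distance matrix is mapped to a similarity matrix
sim = 1 − d/max d ∈ [0, 1]; zero distance ↦ similarity one.

## Synthetic models

The generators define the controlled conditions under which the
pipeline is validated; all are pure functions of (spec, seed).

* **Regular random graph** (N = 100, k = 6 by default): exact
  k-regular simple graphs via the configuration-model family.
* **Barabási–Albert** (N = 100, m₀ = 3, m = 3): growth from an
  m₀-clique, m distinct degree-proportional attachments per arrival,
  exactly m₀(m₀−1)/2 + m(N−m₀) = 294 edges (mean degree 5.88 ≈ 6),
  final labels uniformly permuted so node index carries no age signal.
* **LFR benchmark** (N = 100, mean degree 6, max degree N/4 = 25,
  degree exponent 2, community-size exponent 1): implemented in-house.
  Degrees are drawn from a truncated continuous power law whose lower
  cutoff is solved (once, by bisection) so the rounded samples hit the
  target mean; community sizes are drawn from a discrete power law on
  [3, max_degree] — the benchmark's usual convention of tying community
  bounds to degree bounds, which yields roughly ten communities at
  N = 100; nodes are assigned under capacity and internal-degree
  constraints; each node splits its degree into round((1−μ)k) internal
  and the rest external stubs, wired by configuration-model pairing
  with bounded swap repairs of self-loops, duplicates and (for external
  stubs) within-community pairs.  Draws whose realized mean mixing
  deviates from μ by more than 0.05 are rejected and regenerated
  (bounded retries).  Because degrees are fixed before μ enters, the
  degree distribution is independent of μ by construction.
* **Planted-state temporal networks**: given a state sequence and one
  model per state, each window draws an independent graph from its
  state's model and emits one event per edge at a uniform time inside
  the window (any placement within the half-open window is equivalent
  after binning; uniform is used for realism and reproducibility).
  The event list carries time origin 0 so re-binning with the same τ
  reproduces each window's edge set exactly.

What the generators do *not* emulate: real proximity data's bursty
event timing, circadian/weekly rate modulation, node churn, sensor
noise and repeated contact re-reports, and — importantly — the
*persistence* of structure within a state (see limitations).  Passing
the synthetic tests therefore shows the machinery is correct and that
structurally distinct regimes are separable, not that any particular
empirical data set will exhibit clean states.

## Numerical choices

Symmetric eigensolvers throughout (`scipy.linalg.eigh`); normalised-
Laplacian eigenvalues clipped to [0, 2 + 1e−9] tolerance in tests;
density-matrix traces accurate to 1e−12; the DELTACON linear system is
solved as SPD (ε is below the spectral bound, so singularity cannot
occur for simple graphs; a solver failure is still surfaced as an
error).  Distance matrices are exactly symmetric by construction (each
pair computed once).  All-pairs computation caches per-snapshot spectra
(spectral measures) and density matrices (JSD).

## Known limitations

* **Dunn's index degenerates when states overlap.**  A cut that leaves
  one merged pair plus singletons scores d₍₂₎/d₍₁₎ — the ratio of the
  two smallest merge heights, typically just above 1.  The true
  C-state cut wins only if (min between-state distance)/(max
  within-state diameter) exceeds that ratio, i.e. if the states are
  *completely* separated in the distance order statistics.  With
  windows drawn independently from two LFR ensembles (μ = 0.1 vs 0.9)
  the within-state spread overlaps the between-state gap, so although
  the forced two-cluster cut recovers the planted bipartition almost
  always, Dunn's index instead selects C near t_max and full recovery
  fails; the acceptance script reports both numbers
  (`planted_forced_two_state_ari` vs `planted_two_state_recovery_rate`).
  Strongly separated regimes (e.g. 4-regular vs scale-free windows)
  are recovered perfectly end-to-end.  Real recurrent states, whose
  structure persists rather than being redrawn each window, sit closer
  to the strongly separated case.
* Single-state description: the whole network is assigned one state
  per window; coexisting per-community states are not modelled.
* No temporal smoothing or inertia: consecutive windows are clustered
  independently of their adjacency in time.
* The edit distance and DELTACON compare identity-matched edges, which
  is usually too stringent for sparse snapshots — two independent
  draws of the *same* model already share almost no edges.  They are
  provided for comparison, as measures, not recommendations.
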