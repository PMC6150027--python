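# Methods

## Model and assumptions

`segc` treats an interactome as a simple undirected graph over opaque string
identifiers: self-loops and duplicate (or reversed-duplicate) records are
dropped at load time, extra edge-list columns (confidence scores) are
ignored, and no gene-name normalization is attempted — identifier hygiene is
the caller's job. The working assumption is the standard one for complex
detection: a complex is a connected, relatively dense subgraph of small
diameter. Two consequences follow directly. First, the diameter cap θ is a
hard constraint on every cluster, enforced during expansion. Second, the
algorithm never removes clustered nodes or edges from the graph, so clusters
can overlap and the seed loop runs until every node is covered.

## The three phases

**Weighting.** The weight iteration
`w_i(v) = β₁ w_{i−1}(v) + β₂ Σ_{u∈N(v)} w_{i−1}(u) + β₃ Σ_{u∈N(v)} τ(v,u)`
mixes three attributes: the node's own previous weight, its neighbors'
previous weights, and the (static) sum of common-neighbor edge weights on
its incident edges. β₃ is always derived as 1 − β₁ − β₂; parameter sets with
β₁ + β₂ > 1 are rejected rather than renormalized. Degenerate corners are
useful checks rather than errors: β₁ = 1 freezes the weight at the degree
for every iteration, and β₃ = 1 after one iteration gives the incident-
triangle weight familiar from density-periphery clustering. k = 0 is allowed
(returns only w₀ = degree) for ablation work; the default is k = 3.
Weights are plain floats; all accumulation is left-to-right over nodes
sorted by identifier, so results are bit-reproducible.

**Seeding.** Selection probabilities are squared final weights normalized
over the *eligible* (unclustered) set. Normalizing over the eligible set
rather than all nodes changes nothing for sampling (the restriction is a
conditional distribution) and is the only reading compatible with never
re-seeding a clustered node. One uniform variate is inverted against the
cumulative sum over sorted node ids. Edge case: if every eligible node has
weight zero (isolated leftovers near the end of a run), the distribution
falls back to uniform so the full-coverage guarantee cannot stall.

**Expansion.** One node per round: candidates are outside neighbors of the
cluster, scored by NC with λ recomputed from the *current* cluster size
before the admission; the strict comparison `NC > ε` is used. Ties on NC
break to the lexicographically smallest node id, making the member sequence
a pure function of (graph, seed, parameters). The diameter test is
incremental: when the cluster already satisfies `D ≤ θ`, adding one node
cannot increase distances among existing members (shortest paths in a
supergraph are never longer), so only the entering node's eccentricity
within the enlarged induced subgraph needs to be computed. A property test
validates this argument against full Floyd–Warshall recomputation on random
instances. Disconnected induced subgraphs report an infinite sentinel
diameter, which simply fails any θ.

## Driver contract

The weight table is computed exactly once per run (asserted by call counting
in the tests). Each loop iteration clusters at least its seed, bounding the
loop at n iterations. Clusters whose member set duplicates an earlier
cluster exactly are dropped at insertion — distinct seeds inside the same
dense region otherwise produce verbatim repeats. `min_cluster_size`
filtering is off by default because it breaks the full-coverage property;
it exists because comparison practice often discards size-1/2 clusters.
Restart i of `run_restarts` uses rng seed `rng_seed + i`, so any single run
can be reproduced in isolation. No "best run" is auto-selected: no
unsupervised objective is defined for that choice, so the function returns
per-run summaries (cluster count, mean size, mean intra-cluster density) and
leaves ranking — typically by F-measure against a reference — to the caller.

## Evaluation notes

The clustering-wise PPV is implemented in its standard form
`Σ_i max_j T_ij / Σ_ij T_ij` (with PPV := 0 when no prediction overlaps any
reference), paralleling the sensitivity `Σ_j max_i T_ij / Σ_j |CO_j|`.
NA matching uses `≥ μ`, default μ = 0.2. Reference complexes are used
exactly as supplied unless the caller opts into restricting them to the
network's node set; the default avoids silently inflating recall. Singleton
predictions count in the precision denominator unless filtered upstream —
this materially shifts precision on networks with isolated nodes, which is
visible in the worked example in the README.

## Synthetic benchmark

The planted-complex generator emulates what the detection problem assumes:
dense within-complex wiring (probability `p_in`, resampled until each
complex is connected), a weak background (`p_out` across all non-co-complex
pairs), optional single-node sharing between complexes, and isolated
background proteins. Defaults — ten complexes of 5–10 nodes, 50 background
nodes, p_in = 0.9, p_out = 0.005, overlap 0.1 — give networks of roughly
100–130 nodes with the sparse overall density typical of TAP-style yeast
interactomes. The generator does **not** reproduce power-law degree
distributions, experiment-specific false-positive/negative structure, or
interactome scale, so passing recovery tests demonstrate correctness of the
machinery and sane behavior under planted signal, not field performance on
real data. Note also that an edge-list file cannot carry degree-0 nodes, so
a network round-tripped through `segc synth`'s edge output loses isolated
background proteins; the in-memory `GroundTruth` object keeps them.

Problem sizes used in the test suite — 50 planted networks of ≤ 300 nodes
for the coverage invariant, 10 generator seeds for near-clique recovery,
20 restarts for the stability check — were chosen as the smallest scales at
which the respective properties are meaningfully exercised; the whole suite
runs in a few seconds.

## The 12-node example network

The fixed example (6-clique {v1..v6}, 5-clique {v8..v12}, connector v7
adjacent to v1 and v2, connector v9 additionally adjacent to v5 and v6) is
the package's reference computation. Its adjacency was recovered by
constraint satisfaction from the published worked-example anchors (degrees
of v2/v5/v9, completeness of {v1..v6}, the four iterated weight values
under β = (0.2, 0.6, 0.2), and the 0.5-threshold admission example), and it
is unique up to relabeling the interchangeable clique nodes. The
constructor re-derives every anchor and refuses to return a network that
fails any of them, so the transcription is falsifiable. The second-iteration
weights are exactly 86.16 and 92.88, printing to one decimal as 86.2
and 92.9.

## Known limitations

- Pure-Python graph traversal: networks of ~10⁴ nodes cluster in seconds to
  minutes, but the implementation is not tuned for much larger graphs.
- No weighted-edge or directed input; confidence columns are ignored by
  design, since τ is always recomputed from topology.
- ε is global; very dense networks benefit from raising it (≈ 0.55), but no
  density-adaptive rule is implemented.
- No core-attachment seeding, cluster merging, or GO-annotation filtering.
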