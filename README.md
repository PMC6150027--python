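# segc — seed-expansion graph clustering for protein-complex detection

Proteins rarely act alone: most of them carry out their function as members
of physical complexes, which appear in protein–protein interaction (PPI)
networks as dense, small-diameter subgraphs. `segc` detects such complexes
by **seed-expansion graph clustering (SEGC)**: it scores every node by an
iterated multi-attribute weight, draws seeds by roulette wheel among the
not-yet-clustered nodes, and greedily grows each seed into a cluster under a
closeness threshold and a diameter cap. Clusters may overlap (a protein can
sit in several complexes), and **every** node of the network ends up in at
least one cluster — full coverage, which matters because sparse complexes
are easily missed by density-only methods.

The package is aimed at computational biologists who have an interactome as
a plain two-column edge list (e.g. the yeast Gavin/Krogan/BioGRID networks)
and, optionally, a reference complex catalogue in the one-complex-per-line
layout of CYC2008.

## The algorithm

**Node weighting.** With `w_0(v) = deg(v)` and the static edge weight
`τ(u,v) = |N(u) ∩ N(v)|` (common neighbors, i.e. triangles through the
edge), iterate k times:

    w_i(v) = β₁·w_{i−1}(v) + β₂·Σ_{u∈N(v)} w_{i−1}(u) + β₃·Σ_{u∈N(v)} τ(v,u)

with β₁ + β₂ + β₃ = 1. After k rounds, `w_k(v)` summarizes the
k-neighborhood of v: high-weight nodes sit centrally inside locally dense
regions.

**Seed selection.** A seed is drawn from the unclustered nodes with
probability `P(v) ∝ w_k(v)²`. Squaring keeps the weight ordering but
sharpens the selection, which is why repeated runs are nearly as stable as
a deterministic argmax while still exploring alternative seeds.

**Cluster expansion.** A cluster C grows one node per round. Each outside
neighbor u is scored by the closeness

    NC(u, C) = λ·|N(u) ∩ C| / |C| + (1 − λ)·|N(u) ∩ C| / |N(u)|,

with the schedule `λ = 1 / (r·(|C| − 1) + 1)` (λ = 1 for the singleton
cluster, decaying as C grows, so dense cores form first and sparse
periphery nodes — including degree-1 pendants — can join late). The
highest-NC candidate with `NC > ε` whose addition keeps the induced-subgraph
diameter ≤ θ is admitted; expansion stops when no candidate qualifies.
Already-clustered nodes remain eligible, producing overlap.

Default parameters: `(β₁, β₂, k, ε, r, θ) = (0.6, 0, 3, 0.4, 0.3, 2)`.
For unusually dense networks a larger ε (≈ 0.55) gives tighter clusters.

**Evaluation.** Predictions are scored against a reference complex set by
neighborhood-affinity matching `NA(A,B) = |A∩B|²/(|A|·|B|) ≥ μ` (μ = 0.2):
precision, recall and F-measure; plus the clustering-wise PPV, sensitivity
(Sn) and their geometric mean (accuracy) from the overlap matrix
`T_ij = |C_i ∩ CO_j|`; plus coverage.

## Worked example

Generate a small benchmark with five planted complexes in a 20-node
background, cluster it, and score the result against the planted truth:

```bash
segc synth --n-complexes 5 --n-background 20 --size 5 8 \
           --p-in 0.9 --p-out 0.005 --rng-seed 7 \
           --out-edges net.tsv --out-gold gold.txt
segc cluster --edges net.tsv --rng-seed 42 --out clusters.txt
segc eval --clusters clusters.txt --gold gold.txt --network net.tsv
```

which prints:

```
56 nodes, 112 edges, 5 planted complexes
run 0: 6 clusters, mean size 7.00, mean density 0.829, coverage 1.000 -> clusters.txt
precision	recall	f_measure	ppv	sn	accuracy	coverage
0.8333	1.0000	0.9091	0.9487	1.0000	0.9740	1.0000
```

All five planted complexes are recovered (recall 1.0) and five of the six
predicted clusters match a planted complex (precision 5/6 ≈ 0.83); the sixth
is a spurious cluster assembled from background noise edges. Coverage 1.0
reflects the full-coverage guarantee.

The same pipeline is available as a scikit-learn-style estimator:

```python
import networkx as nx
from segc import SEGC, evaluate, load_edge_list

net = load_edge_list("net.tsv")
est = SEGC(epsilon=0.4, theta=2, random_state=42).fit(net)
print(len(est.clustering_), "clusters, coverage", est.clustering_.coverage)
```

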