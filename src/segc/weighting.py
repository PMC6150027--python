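"""Iterative multi-attribute node weighting.

Every node starts at its degree, w0(v) = DC(v).  Each iteration mixes three
topological attributes with coefficients (β1, β2, β3), β1 + β2 + β3 = 1:

    w_i(v) = β1·w_{i-1}(v) + β2·Σ_{u∈N(v)} w_{i-1}(u) + β3·Σ_{u∈N(v)} τ(v, u)

where the static edge weight τ(u, v) = |N(u) ∩ N(v)| counts the common
neighbors of the endpoints (triangles through the edge).  After k iterations
the weight of a node summarizes its k-neighborhood: β1 = 1 freezes the weight
at the degree, β3 = 1 gives the classic incident-triangle weight used by
density-periphery seed-expansion methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import networkx as nx

from .graph_core import common_neighbor_count


@dataclass(frozen=True)
class WeightParams:
    """Coefficients (β1, β2) and iteration count k; β3 = 1 − β1 − β2."""

    beta1: float = 0.6
    beta2: float = 0.0
    k: int = 3

    def __post_init__(self):
        if not (0.0 <= self.beta1 <= 1.0 and 0.0 <= self.beta2 <= 1.0):
            raise ValueError("beta1 and beta2 must lie in [0, 1]")
        if self.beta1 + self.beta2 > 1.0 + 1e-12:
            raise ValueError("beta1 + beta2 must not exceed 1")
        if self.k < 0:
            raise ValueError("k must be a nonnegative integer")

    @property
    def beta3(self) -> float:
        return 1.0 - self.beta1 - self.beta2


@dataclass
class NodeWeightTable:
    """Per-node weights for iterations 0..k plus the static edge-weight map."""

    tau: Dict[Tuple[str, str], int]
    weights: List[Dict[str, float]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.weights) - 1

    def w(self, i: int, v) -> float:
        return self.weights[i][v]

    @property
    def final(self) -> Dict[str, float]:
        """Weights at the last iteration, w_k — the seed-selection fitness."""
        return self.weights[-1]

    def to_tsv(self, path) -> None:
        """Debug dump: one row per node, columns w_0..w_k."""
        with open(path, "w") as fh:
            header = "node\t" + "\t".join(f"w{i}" for i in range(self.k + 1))
            fh.write(header + "\n")
            for v in sorted(self.weights[0]):
                row = "\t".join(repr(wi[v]) for wi in self.weights)
                fh.write(f"{v}\t{row}\n")


def compute_edge_weights(net: nx.Graph) -> Dict[Tuple[str, str], int]:
    """τ for every edge: common-neighbor count of the endpoints.

    Keys are edges as sorted 2-tuples of node ids.
    """
    return {
        tuple(sorted((u, v))): common_neighbor_count(net, u, v)
        for u, v in net.edges()
    }


def iterate_node_weights(net: nx.Graph, params: WeightParams) -> NodeWeightTable:
    """Run the weight iteration for ``params.k`` rounds from w0 = degree.

    The τ-sum attribute is constant across iterations and precomputed once.
    ``k = 0`` is a valid degenerate request returning only w0.
    """
    if not isinstance(params, WeightParams):
        params = WeightParams(*params)
    tau = compute_edge_weights(net)
    nodes = sorted(net.nodes)
    tau_sum = {
        v: sum(tau[tuple(sorted((v, u)))] for u in net[v]) for v in nodes
    }
    w = {v: float(net.degree(v)) for v in nodes}
    table = NodeWeightTable(tau=tau, weights=[w])
    b1, b2, b3 = params.beta1, params.beta2, params.beta3
    for _ in range(params.k):
        prev = table.weights[-1]
        nxt = {
            v: b1 * prev[v]
            + b2 * sum(prev[u] for u in net[v])
            + b3 * tau_sum[v]
            for v in nodes
        }
        table.weights.append(nxt)
    return table
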