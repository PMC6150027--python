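"""Synthetic networks with known ground truth.

Three generators:

* :func:`make_planted_network` — a planted-complex benchmark: dense,
  small-diameter groups (the "complexes") wired with probability ``p_in``,
  embedded in a sparse background wired with probability ``p_out``.  The
  planted membership is returned alongside the network, so recovery can be
  scored exactly.
* :func:`make_example_network` — a fixed 12-node example: a 6-clique and a
  5-clique joined through two low-degree connector nodes.  Its adjacency was
  recovered by constraint satisfaction from published worked-example values
  and it self-validates on construction, so any transcription drift fails
  loudly.
* :func:`make_fixture` — classic deterministic graphs (clique, star, path,
  cycle, two bridged cliques) for unit tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Set, Tuple

import networkx as nx
import numpy as np

from .expansion import closeness, lambda_for_size
from .weighting import WeightParams, iterate_node_weights


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of the planted-complex benchmark.

    Defaults emulate a small sparse interactome region: ten complexes of
    5-10 proteins (dense, p_in = 0.9), 50 background proteins, weak
    background wiring (p_out = 0.005), and occasional single-protein sharing
    between complexes (overlap_fraction = 0.1).
    """

    n_background: int = 50
    n_complexes: int = 10
    size_range: Tuple[int, int] = (5, 10)
    p_in: float = 0.9
    p_out: float = 0.005
    overlap_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_background < 0 or self.n_complexes < 1:
            raise ValueError("need nonnegative background and >=1 complex")
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError("complex sizes must satisfy 3 <= min <= max")
        if not (0.0 < self.p_in <= 1.0):
            raise ValueError("p_in must lie in (0, 1]")
        if not (0.0 <= self.p_out < 1.0):
            raise ValueError("p_out must lie in [0, 1)")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """A generated network together with its planted complex memberships."""

    network: nx.Graph
    complexes: List[Set[str]]


def _wire_complex(rng: np.random.Generator, members: List[str], p_in: float,
                  max_tries: int = 1000) -> List[Tuple[str, str]]:
    """Sample within-complex edges until the complex is connected."""
    pairs = list(itertools.combinations(sorted(members), 2))
    for _ in range(max_tries):
        mask = rng.random(len(pairs)) < p_in
        edges = [pairs[i] for i in range(len(pairs)) if mask[i]]
        g = nx.Graph(edges)
        g.add_nodes_from(members)
        if nx.is_connected(g):
            return edges
    raise ValueError(
        f"could not wire a connected complex of size {len(members)} "
        f"at p_in={p_in} in {max_tries} attempts"
    )


def make_planted_network(model: PlantedModel = PlantedModel()) -> GroundTruth:
    """Generate a planted-complex network; deterministic given rng_seed."""
    rng = np.random.default_rng(model.rng_seed)
    lo, hi = model.size_range
    sizes = rng.integers(lo, hi + 1, size=model.n_complexes)

    next_id = 0

    def new_node() -> str:
        nonlocal next_id
        name = f"p{next_id:04d}"
        next_id += 1
        return name

    complexes: List[List[str]] = []
    for i, size in enumerate(sizes):
        members: List[str] = []
        if i > 0 and rng.random() < model.overlap_fraction:
            donor = complexes[int(rng.integers(0, i))]
            members.append(donor[int(rng.integers(0, len(donor)))])
        while len(members) < size:
            members.append(new_node())
        complexes.append(members)
    background = [new_node() for _ in range(model.n_background)]

    net = nx.Graph()
    all_nodes = sorted({v for c in complexes for v in c} | set(background))
    net.add_nodes_from(all_nodes)

    co_complex: Set[Tuple[str, str]] = set()
    for members in complexes:
        for pair in itertools.combinations(sorted(members), 2):
            co_complex.add(pair)
        net.add_edges_from(_wire_complex(rng, members, model.p_in))

    if model.p_out > 0.0:
        outside = [
            pair
            for pair in itertools.combinations(all_nodes, 2)
            if pair not in co_complex
        ]
        mask = rng.random(len(outside)) < model.p_out
        net.add_edges_from(
            outside[i] for i in range(len(outside)) if mask[i]
        )

    return GroundTruth(network=net, complexes=[set(c) for c in complexes])


#: Adjacency of the 12-node worked-example network: a 6-clique {v1..v6} and a
#: 5-clique {v8..v12}; connector v7 touches two clique nodes (v1, v2);
#: v9 additionally touches v5 and v6, linking the two dense groups.
_EXAMPLE_EDGES = (
    [tuple(sorted(p)) for p in itertools.combinations(
        ["v1", "v2", "v3", "v4", "v5", "v6"], 2)]
    + [tuple(sorted(p)) for p in itertools.combinations(
        ["v8", "v9", "v10", "v11", "v12"], 2)]
    + [("v1", "v7"), ("v2", "v7"), ("v5", "v9"), ("v6", "v9")]
)


def make_example_network() -> nx.Graph:
    """The fixed 12-node example network, self-validated on construction.

    The validation re-derives the published worked-example anchors: the
    complete subgraph on {v1..v6}; deg(v2) = deg(v5) = deg(v9) = 6; the
    iterated weights under β = (0.2, 0.6, 0.2) — w1(v2) = 23.6, w1(v5) = 26,
    and w2 values that print (to one decimal) as 86.2 and 92.9; and the
    expansion example at priority threshold 0.5, where v7 qualifies for the
    cluster {v1..v6} and v9 does not.
    """
    net = nx.Graph(_EXAMPLE_EDGES)

    k6 = ["v1", "v2", "v3", "v4", "v5", "v6"]
    if net.subgraph(k6).number_of_edges() != 15:
        raise RuntimeError("example fixture: {v1..v6} is not complete")
    for v in ("v2", "v5", "v9"):
        if net.degree(v) != 6:
            raise RuntimeError(f"example fixture: deg({v}) != 6")

    table = iterate_node_weights(net, WeightParams(beta1=0.2, beta2=0.6, k=2))
    checks = [
        (table.w(0, "v2"), 6.0), (table.w(0, "v5"), 6.0),
        (table.w(1, "v2"), 23.6), (table.w(1, "v5"), 26.0),
        (round(table.w(2, "v2"), 1), 86.2), (round(table.w(2, "v5"), 1), 92.9),
    ]
    for got, want in checks:
        if abs(got - want) > 1e-9:
            raise RuntimeError(
                f"example fixture: weight check failed ({got} != {want})"
            )

    cluster = set(k6)
    lam = lambda_for_size(len(cluster), r=0.3)
    if not closeness(net, "v7", cluster, lam) > 0.5:
        raise RuntimeError("example fixture: v7 should pass the 0.5 threshold")
    if closeness(net, "v9", cluster, lam) > 0.5:
        raise RuntimeError("example fixture: v9 should fail the 0.5 threshold")
    return net


def make_fixture(kind: str, n: int) -> nx.Graph:
    """Deterministic named graphs over nodes v1..vN.

    kinds: ``clique`` (n >= 1 nodes), ``star`` (n >= 2 total nodes, v1 is
    the center), ``path``, ``cycle`` (n >= 3), ``two_cliques_bridge`` (two
    n-cliques, n >= 2, joined by a single bridge edge).
    """

    def names(count: int, offset: int = 0) -> List[str]:
        return [f"v{i + 1 + offset}" for i in range(count)]

    if kind == "clique":
        if n < 1:
            raise ValueError("clique needs n >= 1")
        g = nx.complete_graph(n)
    elif kind == "star":
        if n < 2:
            raise ValueError("star needs n >= 2")
        g = nx.star_graph(n - 1)
    elif kind == "path":
        if n < 1:
            raise ValueError("path needs n >= 1")
        g = nx.path_graph(n)
    elif kind == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        g = nx.cycle_graph(n)
    elif kind == "two_cliques_bridge":
        if n < 2:
            raise ValueError("two_cliques_bridge needs clique size n >= 2")
        g = nx.Graph()
        left, right = names(n), names(n, offset=n)
        g.add_edges_from(itertools.combinations(left, 2))
        g.add_edges_from(itertools.combinations(right, 2))
        g.add_edge(left[0], right[0])
        return g
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return nx.relabel_nodes(g, {i: f"v{i + 1}" for i in g.nodes})
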