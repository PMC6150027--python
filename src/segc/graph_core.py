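"""Graph data model, edge-list I/O, and neighborhood/distance primitives.

A PPI network is represented as a plain :class:`networkx.Graph` over opaque
string node identifiers.  The functions here enforce the simple-undirected
contract (no self-loops, no parallel edges) and provide the induced-subgraph
distance primitives used by cluster expansion: diameter of a node subset and
eccentricity of one node within a subset.

Disconnected induced subgraphs report :data:`DISCONNECTED` (``math.inf``),
which compares greater than any finite diameter threshold, so a diameter cap
simply fails for them.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Set

import networkx as nx

logger = logging.getLogger(__name__)

#: Sentinel diameter/eccentricity for disconnected induced subgraphs.
DISCONNECTED = math.inf


def load_edge_list(path) -> nx.Graph:
    """Read a two-column whitespace-separated edge list into a simple graph.

    Lines starting with ``#`` and blank lines are skipped.  The first two
    tokens of each line are the edge endpoints; any further columns (e.g.
    confidence scores) are ignored, because the clustering recomputes all
    edge weights from topology.  Self-loops and duplicate (or reversed
    duplicate) records are silently dropped; counts are reported via logging.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If a non-comment line has fewer than two tokens (the message names
        the offending line number).
    """
    net = nx.Graph()
    n_self, n_dup, n_edges = 0, 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least two "
                    f"whitespace-separated tokens, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                n_self += 1
                net.add_node(u)
                continue
            if net.has_edge(u, v):
                n_dup += 1
                continue
            net.add_edge(u, v)
            n_edges += 1
    logger.info(
        "loaded %s: %d nodes, %d edges (%d self-loops and %d duplicate "
        "records dropped)",
        path, net.number_of_nodes(), n_edges, n_self, n_dup,
    )
    return net


def degree(net: nx.Graph, v) -> int:
    """Number of neighbors of ``v`` (degree centrality DC(v))."""
    if v not in net:
        raise KeyError(f"node {v!r} not in network")
    return net.degree(v)


def common_neighbor_count(net: nx.Graph, u, v) -> int:
    """|N(u) ∩ N(v)|: the number of triangles through the pair (u, v)."""
    if u not in net:
        raise KeyError(f"node {u!r} not in network")
    if v not in net:
        raise KeyError(f"node {v!r} not in network")
    nu, nv = net[u], net[v]
    if len(nu) > len(nv):
        nu, nv = nv, nu
    return sum(1 for x in nu if x in nv)


def subgraph_diameter(net: nx.Graph, members: Iterable) -> float:
    """Diameter of the subgraph induced by ``members``.

    Returns :data:`DISCONNECTED` if the induced subgraph is disconnected.
    """
    members = set(members)
    if not members:
        raise ValueError("members must be nonempty")
    missing = members - set(net.nodes)
    if missing:
        raise KeyError(f"nodes not in network: {sorted(missing)}")
    if len(members) == 1:
        return 0
    sub = net.subgraph(members)
    best = 0
    for u in members:
        dist = nx.single_source_shortest_path_length(sub, u)
        if len(dist) < len(members):
            return DISCONNECTED
        best = max(best, max(dist.values()))
    return best


def eccentricity_within(net: nx.Graph, members: Iterable, u) -> float:
    """Max BFS distance from ``u`` to any member inside the induced subgraph.

    Used as an incremental diameter check during expansion: when a new node
    enters a cluster whose diameter already satisfies the cap, existing
    pairwise distances cannot grow, so only the entering node's eccentricity
    needs checking.  Returns :data:`DISCONNECTED` if some member is
    unreachable from ``u`` within the induced subgraph.
    """
    members = set(members)
    if u not in members:
        raise ValueError(f"node {u!r} is not in the member set")
    sub = net.subgraph(members)
    dist = nx.single_source_shortest_path_length(sub, u)
    if len(dist) < len(members):
        return DISCONNECTED
    return max(dist.values())
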