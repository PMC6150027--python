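"""Greedy cluster expansion from a seed under a closeness and diameter cap.

A cluster starts as the singleton {seed}.  Each round, every outside
neighbor u of the cluster C is scored by its closeness

    NC(u, C) = λ·|N(u) ∩ C| / |C|  +  (1 − λ)·|N(u) ∩ C| / |N(u)|,

a convex mix of "how much of the cluster u touches" and "how much of u's
neighborhood lies in the cluster".  The mixing weight follows the schedule
λ = 1 / (r·(|C| − 1) + 1): it equals 1 for the singleton cluster (favoring
densely connected additions near the seed) and decays as the cluster grows
(letting sparsely connected periphery nodes join late).  The single frontier
node with the highest NC that strictly exceeds ε *and* keeps the induced
subgraph diameter within θ is admitted; expansion stops when no frontier
node qualifies.

Nodes that already belong to other clusters remain eligible, which is what
produces overlapping clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Set, Union

import networkx as nx

from .graph_core import eccentricity_within


@dataclass(frozen=True)
class ExpansionParams:
    """Closeness threshold ε, λ reduce rate r, and diameter cap θ."""

    epsilon: float = 0.4
    r: float = 0.3
    theta: int = 2

    def __post_init__(self):
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")
        if self.r <= 0.0:
            raise ValueError("r must be positive")
        if self.theta < 1:
            raise ValueError("theta must be a positive integer")


@dataclass
class Cluster:
    """A seed plus its members in admission order (seed first)."""

    seed: str
    members: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            self.members = [self.seed]
        if self.members[0] != self.seed:
            raise ValueError("members[0] must be the seed")
        if len(set(self.members)) != len(self.members):
            raise ValueError("members must be distinct")

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, v) -> bool:
        return v in self.members


def lambda_for_size(size: int, r: float) -> float:
    """λ = 1 / (r·(size − 1) + 1): 1 at size 1, strictly decreasing."""
    if size < 1:
        raise ValueError("cluster size must be at least 1")
    return 1.0 / (r * (size - 1) + 1.0)


def closeness(
    net: nx.Graph,
    u,
    cluster: Union[Cluster, Set[str], Sequence[str]],
    lam: float,
) -> float:
    """NC(u, C): λ·|N(u)∩C|/|C| + (1−λ)·|N(u)∩C|/|N(u)|, in [0, 1]."""
    members = cluster.member_set if isinstance(cluster, Cluster) else set(cluster)
    if u in members:
        raise ValueError(f"candidate {u!r} is already a cluster member")
    deg = net.degree(u)
    if deg == 0:
        raise ValueError(f"candidate {u!r} is isolated (degree 0)")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    inside = sum(1 for x in net[u] if x in members)
    return lam * inside / len(members) + (1.0 - lam) * inside / deg


def expand(net: nx.Graph, seed, params: ExpansionParams = ExpansionParams()) -> Cluster:
    """Grow one cluster from ``seed``; returns the final cluster.

    One node is admitted per round — the NC-argmax over the qualifying
    frontier, ties broken by lexicographically smallest node id — after
    which λ and the frontier are recomputed.  The diameter condition is
    checked incrementally via the entering node's eccentricity inside the
    enlarged induced subgraph, which is equivalent to a full recomputation
    because existing pairwise distances cannot grow when a node is added.
    """
    if seed not in net:
        raise KeyError(f"seed {seed!r} not in network")
    members: List[str] = [seed]
    member_set: Set[str] = {seed}
    # frontier bookkeeping: |N(x) ∩ C| for every outside neighbor x of C
    inside_count = {x: 1 for x in net[seed]}
    while inside_count:
        lam = lambda_for_size(len(members), params.r)
        size = len(members)
        scored = []
        for x, cnt in inside_count.items():
            nc = lam * cnt / size + (1.0 - lam) * cnt / net.degree(x)
            if nc > params.epsilon:
                scored.append((-nc, x))
        scored.sort()
        admitted = None
        for _, x in scored:
            ecc = eccentricity_within(net, member_set | {x}, x)
            if ecc <= params.theta:
                admitted = x
                break
        if admitted is None:
            break
        members.append(admitted)
        member_set.add(admitted)
        del inside_count[admitted]
        for nb in net[admitted]:
            if nb not in member_set:
                inside_count[nb] = inside_count.get(nb, 0) + 1
    return Cluster(seed=seed, members=members)
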