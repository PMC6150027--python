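"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately naive — adjacency-matrix Floyd-Warshall for
distances, double loops over set pairs for the evaluation metrics, and a
from-scratch expansion simulator that recomputes every quantity each round —
so that the package's optimized paths are checked against straight-line code.
"""

import itertools
import math

import networkx as nx
import numpy as np


def floyd_warshall_diameter(net: nx.Graph, members) -> float:
    """All-pairs shortest paths on the induced subgraph via Floyd-Warshall."""
    nodes = sorted(members)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in net.subgraph(nodes).edges():
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    return float(dist.max())


def brute_common_neighbors(net: nx.Graph, u, v) -> int:
    return len(set(net[u]) & set(net[v]))


def naive_precision_recall_f(pred, gold, mu=0.2):
    def na(a, b):
        return len(a & b) ** 2 / (len(a) * len(b))

    mc = [c for c in pred if any(na(c, co) >= mu for co in gold)]
    mco = [co for co in gold if any(na(c, co) >= mu for c in pred)]
    p = len(mc) / len(pred)
    r = len(mco) / len(gold)
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f


def naive_ppv_sn_accuracy(pred, gold):
    t = np.array([[len(c & co) for co in gold] for c in pred], dtype=float)
    total = t.sum()
    ppv = t.max(axis=1).sum() / total if total > 0 else 0.0
    sn = t.max(axis=0).sum() / sum(len(co) for co in gold)
    return ppv, sn, math.sqrt(ppv * sn)


def naive_expand(net: nx.Graph, seed, epsilon, r, theta):
    """From-scratch expansion: full frontier scan and full diameter
    recomputation every round (no incremental bookkeeping)."""
    members = [seed]
    while True:
        mset = set(members)
        lam = 1.0 / (r * (len(members) - 1) + 1.0)
        frontier = {x for m in members for x in net[m]} - mset
        qualified = []
        for x in sorted(frontier):
            inside = len(set(net[x]) & mset)
            nc = lam * inside / len(members) + (1 - lam) * inside / net.degree(x)
            if nc <= epsilon:
                continue
            enlarged = mset | {x}
            sub = net.subgraph(enlarged)
            if not nx.is_connected(sub):
                continue
            diam = max(
                d
                for u in enlarged
                for d in nx.single_source_shortest_path_length(sub, u).values()
            )
            if diam <= theta:
                qualified.append((nc, x))
        if not qualified:
            return members
        best_nc = max(nc for nc, _ in qualified)
        pick = min(x for nc, x in qualified if nc == best_nc)
        members.append(pick)


def random_complex_sets(rng, universe_size=30, max_sets=10):
    universe = [f"u{i}" for i in range(universe_size)]
    def one_side():
        k = int(rng.integers(1, max_sets + 1))
        return [
            set(rng.choice(universe, size=int(rng.integers(1, 8)), replace=False))
            for _ in range(k)
        ]
    return one_side(), one_side()
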