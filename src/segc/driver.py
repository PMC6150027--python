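"""Orchestration: weight once, then alternate seed selection and expansion.

The main loop clusters a network to *full coverage*: while any node remains
outside every cluster, a seed is drawn from the unclustered nodes by roulette
wheel and expanded into a cluster.  Already-clustered nodes may re-enter
later clusters (overlap), but are never seeds again, so each iteration covers
at least the seed and the loop terminates after at most n iterations.  The
node-weight table is computed exactly once per run.

:class:`SEGC` is the scikit-learn-style front door (``fit`` on a
``networkx.Graph``); :func:`run_segc` and :func:`run_restarts` are thin
functional wrappers over it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .expansion import Cluster, ExpansionParams, expand
from .seeding import draw_seed, seed_probabilities
from .weighting import NodeWeightTable, WeightParams, iterate_node_weights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SEGCConfig:
    """All run parameters; defaults are the recommended settings
    (β1, β2, k, ε, r, θ) = (0.6, 0, 3, 0.4, 0.3, 2)."""

    beta1: float = 0.6
    beta2: float = 0.0
    k: int = 3
    epsilon: float = 0.4
    r: float = 0.3
    theta: int = 2
    rng_seed: int = 42
    restarts: int = 1
    min_cluster_size: int = 1

    def __post_init__(self):
        # delegate numeric validation to the component parameter types
        self.weight_params()
        self.expansion_params()
        if self.restarts < 1:
            raise ValueError("restarts must be at least 1")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be at least 1")

    def weight_params(self) -> WeightParams:
        return WeightParams(beta1=self.beta1, beta2=self.beta2, k=self.k)

    def expansion_params(self) -> ExpansionParams:
        return ExpansionParams(epsilon=self.epsilon, r=self.r, theta=self.theta)


@dataclass
class Clustering:
    """A collection of (possibly overlapping) clusters over one network."""

    clusters: List[Cluster]
    network_size: int

    def covered_nodes(self) -> Set[str]:
        out: Set[str] = set()
        for c in self.clusters:
            out.update(c.members)
        return out

    @property
    def coverage(self) -> float:
        if self.network_size == 0:
            raise ValueError("network size must be positive")
        return len(self.covered_nodes()) / self.network_size

    def member_sets(self) -> List[Set[str]]:
        return [set(c.members) for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)

    def summary(self, net: nx.Graph = None) -> Dict[str, float]:
        """Unsupervised per-run summary: count, mean size, mean density."""
        sizes = [len(c) for c in self.clusters]
        out = {
            "n_clusters": len(self.clusters),
            "mean_size": float(np.mean(sizes)) if sizes else 0.0,
        }
        if net is not None:
            dens = []
            for c in self.clusters:
                s = len(c)
                if s < 2:
                    dens.append(0.0)
                else:
                    e = net.subgraph(c.members).number_of_edges()
                    dens.append(2.0 * e / (s * (s - 1)))
            out["mean_density"] = float(np.mean(dens)) if dens else 0.0
        return out


class SEGC(BaseEstimator):
    """Seed-expansion graph clustering for overlapping complex detection.

    Parameters mirror the algorithm's six knobs plus reproducibility and
    output-filter options:

    beta1, beta2 : float
        Weight-mix coefficients; β3 = 1 − β1 − β2.
    k : int
        Number of weight iterations (neighborhood radius of the weights).
    epsilon : float
        Closeness admission threshold ε (strict: NC must exceed it).
    r : float
        Reduce rate of the λ schedule.
    theta : int
        Diameter cap θ of every cluster's induced subgraph.
    random_state : int
        Seed for the roulette wheel.
    min_cluster_size : int
        Output filter; 1 (default) keeps everything, preserving full coverage.

    Attributes (after ``fit``)
    --------------------------
    clustering_ : Clustering
        The predicted clusters.
    weight_table_ : NodeWeightTable
        Iterated node weights w_0..w_k and the edge-weight map τ.
    n_nodes_ : int
        Number of nodes in the fitted network.
    """

    def __init__(
        self,
        beta1: float = 0.6,
        beta2: float = 0.0,
        k: int = 3,
        epsilon: float = 0.4,
        r: float = 0.3,
        theta: int = 2,
        random_state: int = 42,
        min_cluster_size: int = 1,
    ):
        self.beta1 = beta1
        self.beta2 = beta2
        self.k = k
        self.epsilon = epsilon
        self.r = r
        self.theta = theta
        self.random_state = random_state
        self.min_cluster_size = min_cluster_size

    def _config(self) -> SEGCConfig:
        return SEGCConfig(
            beta1=self.beta1, beta2=self.beta2, k=self.k,
            epsilon=self.epsilon, r=self.r, theta=self.theta,
            rng_seed=self.random_state,
            min_cluster_size=self.min_cluster_size,
        )

    def fit(self, G: nx.Graph, y=None) -> "SEGC":
        """Cluster the graph; returns self with ``clustering_`` set."""
        config = self._config()
        if G.number_of_nodes() == 0:
            raise ValueError("network must be nonempty")
        wp = config.weight_params()
        ep = config.expansion_params()
        table = iterate_node_weights(G, wp)
        rng = np.random.default_rng(config.rng_seed)
        unclustered = set(G.nodes)
        clusters: List[Cluster] = []
        seen: Set[frozenset] = set()
        while unclustered:
            probs = seed_probabilities(table.final, unclustered)
            seed = draw_seed(probs, rng)
            cluster = expand(G, seed, ep)
            unclustered -= set(cluster.members)
            key = cluster.member_set
            if key not in seen:
                seen.add(key)
                clusters.append(cluster)
        if config.min_cluster_size > 1:
            clusters = [c for c in clusters if len(c) >= config.min_cluster_size]
        self.weight_table_ = table
        self.n_nodes_ = G.number_of_nodes()
        self.clustering_ = Clustering(clusters=clusters, network_size=self.n_nodes_)
        logger.info(
            "SEGC run (seed=%d): %d clusters, coverage %.3f",
            config.rng_seed, len(clusters), self.clustering_.coverage,
        )
        return self

    def fit_predict(self, G: nx.Graph, y=None) -> List[Set[str]]:
        """Fit and return the cluster member sets."""
        return self.fit(G).clustering_.member_sets()


def run_segc(net: nx.Graph, config: SEGCConfig = SEGCConfig()) -> Clustering:
    """One complete clustering run under ``config`` (wrapper over SEGC)."""
    est = SEGC(
        beta1=config.beta1, beta2=config.beta2, k=config.k,
        epsilon=config.epsilon, r=config.r, theta=config.theta,
        random_state=config.rng_seed, min_cluster_size=config.min_cluster_size,
    )
    return est.fit(net).clustering_


def run_restarts(
    net: nx.Graph, config: SEGCConfig = SEGCConfig()
) -> List[Tuple[Clustering, Dict[str, float]]]:
    """Repeat the stochastic run ``config.restarts`` times.

    Run i uses rng seed ``config.rng_seed + i``, so each run is individually
    reproducible.  Returns (clustering, unsupervised summary) pairs; ranking
    the runs — e.g. by F-measure against a gold standard — is left to the
    caller, since no unsupervised objective is defined for "best".
    """
    out = []
    for i in range(config.restarts):
        cfg_i = SEGCConfig(
            beta1=config.beta1, beta2=config.beta2, k=config.k,
            epsilon=config.epsilon, r=config.r, theta=config.theta,
            rng_seed=config.rng_seed + i, restarts=1,
            min_cluster_size=config.min_cluster_size,
        )
        clustering = run_segc(net, cfg_i)
        out.append((clustering, clustering.summary(net)))
    return out


def write_clusters(clustering, path) -> None:
    """One cluster per line, members whitespace-separated and sorted.

    This is the same layout as gold-standard complex files, so written
    cluster files and reference files are interchangeable for evaluation.
    Accepts a :class:`Clustering` or any iterable of node sets.
    """
    sets = (
        clustering.member_sets()
        if isinstance(clustering, Clustering)
        else [set(s) for s in clustering]
    )
    try:
        with open(path, "w") as fh:
            for members in sets:
                fh.write(" ".join(sorted(members)) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write clusters to {path}: {exc}") from exc


def read_clusters(path) -> List[Set[str]]:
    """Read a one-complex-per-line file into a list of node sets.

    Duplicate lines are kept as distinct entries; whether duplicates are
    meaningful is the evaluator's decision.
    """
    out: List[Set[str]] = []
    try:
        with open(path) as fh:
            for line in fh:
                tokens = line.split()
                if tokens:
                    out.append(set(tokens))
    except OSError as exc:
        raise OSError(f"cannot read clusters from {path}: {exc}") from exc
    return out
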