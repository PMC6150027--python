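"""Fitness-proportionate (roulette-wheel) seed selection.

A seed is drawn from the not-yet-clustered nodes with probability
proportional to the *square* of its final iterated weight,

    P(v) = w_k(v)² / Σ_{x ∈ eligible} w_k(x)².

Squaring preserves the weight ordering while sharpening the contrast
between strong and weak candidates, which keeps repeated stochastic runs
stable.  Normalization is over the eligible (unclustered) set only; once a
node belongs to a cluster it is never selected as a seed again, although it
may still join other clusters during expansion.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Union

import numpy as np

from .weighting import NodeWeightTable


def seed_probabilities(
    weights: Union[NodeWeightTable, Mapping[str, float]],
    eligible: Iterable[str],
) -> Dict[str, float]:
    """Squared-weight selection probabilities over the eligible node set.

    If every eligible node has zero weight (isolated leftovers at the end of
    a run), falls back to the uniform distribution so that the full-coverage
    guarantee of the driver holds.
    """
    if isinstance(weights, NodeWeightTable):
        weights = weights.final
    eligible = sorted(eligible)
    if not eligible:
        raise ValueError("eligible set must be nonempty")
    sq = np.array([weights[v] ** 2 for v in eligible], dtype=float)
    total = sq.sum()
    if total <= 0.0:
        p = np.full(len(eligible), 1.0 / len(eligible))
    else:
        p = sq / total
    return dict(zip(eligible, p))


def draw_seed(probs: Mapping[str, float], rng: np.random.Generator) -> str:
    """Sample one node by cumulative-sum inversion of a single uniform.

    Deterministic given the generator state; iteration order is the sorted
    node order so results are reproducible across runs.
    """
    nodes = sorted(probs)
    p = np.array([probs[v] for v in nodes], dtype=float)
    cum = np.cumsum(p)
    u = rng.random() * cum[-1]
    idx = int(np.searchsorted(cum, u, side="right"))
    return nodes[min(idx, len(nodes) - 1)]
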