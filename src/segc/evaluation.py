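"""Complex-prediction quality metrics.

Predicted clusters are matched to reference complexes by the neighborhood
affinity score NA(A, B) = |A ∩ B|² / (|A|·|B|); a pair with NA ≥ μ
(default μ = 0.2) counts as a match.  From the matches come precision
(|matched predictions| / |predictions|), recall (|matched references| /
|references|) and their harmonic mean, the F-measure.  A second family of
metrics works on the overlap matrix T_ij = |C_i ∩ CO_j|: clustering-wise
positive predictive value PPV = Σ_i max_j T_ij / Σ_ij T_ij, clustering-wise
sensitivity Sn = Σ_j max_i T_ij / Σ_j |CO_j|, and their geometric mean, the
accuracy.  Coverage is the fraction of network nodes placed in ≥ 1 cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set

from .driver import Clustering

#: Default neighborhood-affinity match threshold.
DEFAULT_MU = 0.2


def na_score(ci: Set[str], coj: Set[str]) -> float:
    """Neighborhood affinity |Ci ∩ COj|² / (|Ci|·|COj|) ∈ [0, 1]."""
    if not ci or not coj:
        raise ValueError("complexes must be nonempty")
    inter = len(set(ci) & set(coj))
    return inter * inter / (len(ci) * len(coj))


def _as_sets(complexes: Iterable) -> List[Set[str]]:
    out = [set(c) for c in complexes]
    if not out:
        raise ValueError("complex list must be nonempty")
    if any(not c for c in out):
        raise ValueError("complexes must be nonempty")
    return out


def precision_recall_f(
    pred: Sequence[Set[str]],
    gold: Sequence[Set[str]],
    mu: float = DEFAULT_MU,
):
    """(precision, recall, F) under NA ≥ μ matching.

    F is defined as 0 when precision + recall = 0.
    """
    pred = _as_sets(pred)
    gold = _as_sets(gold)
    matched_pred = sum(
        1 for c in pred if any(na_score(c, co) >= mu for co in gold)
    )
    matched_gold = sum(
        1 for co in gold if any(na_score(c, co) >= mu for c in pred)
    )
    precision = matched_pred / len(pred)
    recall = matched_gold / len(gold)
    if precision + recall == 0.0:
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f


def ppv_sn_accuracy(pred: Sequence[Set[str]], gold: Sequence[Set[str]]):
    """(PPV, Sn, accuracy) from the overlap matrix T_ij = |C_i ∩ CO_j|.

    PPV is defined as 0 when no prediction overlaps any reference.
    """
    pred = _as_sets(pred)
    gold = _as_sets(gold)
    t = [[len(c & co) for co in gold] for c in pred]
    total = sum(sum(row) for row in t)
    ppv = sum(max(row) for row in t) / total if total > 0 else 0.0
    sn = sum(max(t[i][j] for i in range(len(pred))) for j in range(len(gold)))
    sn /= sum(len(co) for co in gold)
    return ppv, sn, math.sqrt(ppv * sn)


def coverage(clustering) -> float:
    """Fraction of network nodes appearing in at least one cluster.

    Accepts a :class:`~segc.driver.Clustering`, or a ``(member_sets, n)``
    pair for cluster files evaluated against a known network size.
    """
    if isinstance(clustering, Clustering):
        return clustering.coverage
    sets, n = clustering
    if n < 1:
        raise ValueError("network size must be positive")
    covered = set()
    for s in sets:
        covered.update(s)
    return len(covered) / n


@dataclass(frozen=True)
class EvalReport:
    """All seven quality figures plus the raw match counts."""

    precision: float
    recall: float
    f_measure: float
    ppv: float
    sn: float
    accuracy: float
    coverage: float
    matched_predictions: int
    matched_references: int

    #: Column order used for tabular output.
    COLUMNS = (
        "precision", "recall", "f_measure", "ppv", "sn", "accuracy", "coverage",
    )

    def to_tsv(self) -> str:
        header = "\t".join(self.COLUMNS)
        row = "\t".join(f"{getattr(self, c):.4f}" for c in self.COLUMNS)
        return header + "\n" + row + "\n"


def evaluate(
    pred: Sequence[Set[str]],
    gold: Sequence[Set[str]],
    n_nodes: int = None,
    mu: float = DEFAULT_MU,
    restrict_to_network: Iterable[str] = None,
) -> EvalReport:
    """Full report of a prediction against a reference complex set.

    ``restrict_to_network``, if given, intersects every reference complex
    with the supplied node set first (dropping references that vanish); by
    default references are used exactly as given.  ``n_nodes`` is required
    for coverage; when omitted, coverage is reported relative to the union
    of predicted members (i.e. 1.0).
    """
    pred = _as_sets(pred)
    gold = _as_sets(gold)
    if restrict_to_network is not None:
        nodes = set(restrict_to_network)
        gold = [co & nodes for co in gold]
        gold = [co for co in gold if co]
        if not gold:
            raise ValueError("no reference complex intersects the network")
    precision, recall, f = precision_recall_f(pred, gold, mu=mu)
    ppv, sn, acc = ppv_sn_accuracy(pred, gold)
    covered = set()
    for c in pred:
        covered.update(c)
    n = n_nodes if n_nodes is not None else len(covered)
    return EvalReport(
        precision=precision,
        recall=recall,
        f_measure=f,
        ppv=ppv,
        sn=sn,
        accuracy=acc,
        coverage=len(covered) / n if n else 0.0,
        matched_predictions=round(precision * len(pred)),
        matched_references=round(recall * len(gold)),
    )
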