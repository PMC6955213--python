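"""Recovery metrics against simulator ground truth."""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.metrics import average_precision_score

from .network import RankedEdgeList
from .simulate import GRNTruth

__all__ = ["undirected_aupr", "edge_density"]


def undirected_aupr(edges: RankedEdgeList, truth: GRNTruth) -> float:
    """Area under precision-recall for the undirected edge ranking.

    Every unordered gene pair is scored by the larger combined score of its
    two directions (0 if neither survived the combination) and labelled by
    membership in the ground-truth undirected edge set.
    """
    score = {}
    for _, row in edges.edges.iterrows():
        key = frozenset((row["source"], row["target"]))
        score[key] = max(score.get(key, 0.0), float(row["combined"]))
    truth_set = truth.undirected_edge_set()
    y, s = [], []
    for a, b in itertools.combinations(truth.genes, 2):
        key = frozenset((a, b))
        y.append(1 if key in truth_set else 0)
        s.append(score.get(key, 0.0))
    return float(average_precision_score(np.array(y), np.array(s)))


def edge_density(truth: GRNTruth) -> float:
    """Fraction of unordered gene pairs that are true (undirected) edges —
    the expected precision of a random ranking, hence the AUPR baseline."""
    n = len(truth.genes)
    n_pairs = n * (n - 1) // 2
    return len(truth.undirected_edge_set()) / n_pairs
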