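"""Partitioning around medoids (PAM) with the classic BUILD + SWAP phases.

BUILD greedily seeds k medoids (first the point minimising total distance to
all others, then the point giving the largest cost reduction).  SWAP
repeatedly performs the single (medoid, non-medoid) exchange that lowers the
total dissimilarity most, stopping at a local optimum where no exchange
helps.  Cost is the sum of each point's distance to its medoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["ClusterAssignment", "pam", "pairwise_distances"]


@dataclass
class ClusterAssignment:
    labels: pd.Series        # 1..k per sample
    medoids: list            # sample ids, cluster i has medoid medoids[i-1]
    k: int
    cost: float              # total within-cluster dissimilarity

    def cluster_of(self, sample) -> int:
        return int(self.labels[sample])


def pairwise_distances(points: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    d = squareform(pdist(points.values.astype(float), metric=metric))
    return pd.DataFrame(d, index=points.index, columns=points.index)


def pam(data, k: int, metric: str = "euclidean", max_swaps: int = 10_000) -> ClusterAssignment:
    """k-medoids clustering of points (samples x features) or a distance matrix.

    A square symmetric DataFrame with zero diagonal is treated as a
    precomputed dissimilarity matrix; anything else as a point cloud.
    """
    if isinstance(data, pd.DataFrame) and data.shape[0] == data.shape[1] \
            and list(data.index) == list(data.columns) \
            and np.allclose(np.diag(data.values.astype(float)), 0):
        D = data.values.astype(float)
        ids = list(data.index)
    else:
        df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
        D = squareform(pdist(df.values.astype(float), metric=metric))
        ids = list(df.index)
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_nearest = D[:, medoids].min(axis=1)
        best_gain, best_cand = -np.inf, None
        for cand in range(n):
            if cand in medoids:
                continue
            gain = np.maximum(dist_to_nearest - D[:, cand], 0.0).sum()
            if gain > best_gain:
                best_gain, best_cand = gain, cand
        medoids.append(best_cand)

    def total_cost(meds):
        return D[:, meds].min(axis=1).sum()

    # SWAP: best-improvement until local optimum
    cost = total_cost(medoids)
    for _ in range(max_swaps):
        best_delta, best_pair = 0.0, None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + medoids[mi + 1:] + [h]
                delta = total_cost(trial) - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_pair = delta, (mi, h)
        if best_pair is None:
            break
        mi, h = best_pair
        medoids[mi] = h
        cost += best_delta

    medoids = sorted(medoids)
    assign = np.argmin(D[:, medoids], axis=1)
    # medoids must belong to their own clusters even under distance ties
    for i, m in enumerate(medoids):
        assign[m] = i
    labels = pd.Series(assign + 1, index=ids, name="cluster")
    cost = float(sum(D[j, medoids[assign[j]]] for j in range(n)))
    return ClusterAssignment(
        labels=labels, medoids=[ids[m] for m in medoids], k=k, cost=cost
    )
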