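"""Gene-set over-representation with a directional z-score.

The over-representation test is the hypergeometric upper tail on
(background size, term size within background, hit-list size, overlap), with
Benjamini-Hochberg control across terms and retention at FDR < 0.05.

The directional z-score summarises which population drives a term: with
``n_up_A`` term genes upregulated in population A and ``n_up_B`` in
population B,

    z = (n_up_A - n_up_B) / sqrt(n_up_A + n_up_B)

(0 when both counts are 0).  Positive z means the term's signal comes from
population A; the statistic is antisymmetric under swapping the populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "overrepresentation", "go_zscore", "attach_direction"]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame         # term, overlap, set_size, p_value, fdr [, n_up_A, n_up_B, z_score]
    background_size: int
    list_size: int
    fdr_threshold: float = 0.05

    def retained(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.fdr_threshold]


def go_zscore(n_up_a: int, n_up_b: int) -> float:
    """Directional term score: (n_up_A - n_up_B)/sqrt(n_up_A + n_up_B); 0 at (0, 0)."""
    if n_up_a < 0 or n_up_b < 0:
        raise ValueError("counts must be non-negative")
    total = n_up_a + n_up_b
    if total == 0:
        return 0.0
    return (n_up_a - n_up_b) / math.sqrt(total)


def overrepresentation(hits, background, sets: dict, fdr_threshold: float = 0.05) -> EnrichmentResult:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    ``hits`` must be a subset of ``background``; sets are intersected with
    the background before testing.  p is the upper tail P(X >= overlap).
    """
    hits = list(dict.fromkeys(hits))
    background = list(dict.fromkeys(background))
    bg = set(background)
    outside = [h for h in hits if h not in bg]
    if outside:
        raise ValueError(f"hit genes outside background: {outside[:10]}")
    hit_set = set(hits)
    M, N = len(bg), len(hits)

    rows = []
    for term, genes in sets.items():
        term_bg = set(genes) & bg
        n = len(term_bg)
        k = len(term_bg & hit_set)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append((term, k, n, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "overlap", "set_size", "p_value"])
    table = table.set_index("term")
    if len(table):
        table["fdr"] = multipletests(table["p_value"].values, method="fdr_bh")[1]
    else:
        table["fdr"] = []
    return EnrichmentResult(
        table=table, background_size=M, list_size=N, fdr_threshold=fdr_threshold
    )


def attach_direction(res: EnrichmentResult, sets: dict, up_in_a, up_in_b) -> EnrichmentResult:
    """Add per-term directional counts and the z-score to an enrichment table.

    ``up_in_a`` / ``up_in_b`` are the significantly upregulated gene lists of
    the two populations.
    """
    sa, sb = set(up_in_a), set(up_in_b)
    n_a, n_b, z = [], [], []
    for term in res.table.index:
        genes = set(sets.get(term, ()))
        a, b = len(genes & sa), len(genes & sb)
        n_a.append(a)
        n_b.append(b)
        z.append(go_zscore(a, b))
    out = res.table.copy()
    out["n_up_A"] = n_a
    out["n_up_B"] = n_b
    out["z_score"] = z
    return EnrichmentResult(
        table=out,
        background_size=res.background_size,
        list_size=res.list_size,
        fdr_threshold=res.fdr_threshold,
    )
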