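"""Marker-centric analyses: correlation profiles and expression overlap.

The correlation-of-correlations statistic asks whether two markers organise
the transcriptome in opposite directions: each marker's profile is its
Pearson correlation with every other expressed gene, and two profiles are
then correlated with each other (excluding the markers themselves).  A
strongly negative second-order correlation is the signature of two
anti-correlated expression programs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

__all__ = ["marker_correlations", "expression_overlap"]


def marker_correlations(nm: NormalizedMatrix, markers) -> tuple:
    """Per-marker gene-wise Pearson profiles and their pairwise correlations.

    Returns ``(profiles, profile_corr)`` where ``profiles`` is a genes x
    markers DataFrame of Pearson r values and ``profile_corr`` a markers x
    markers DataFrame correlating the profiles, excluding both markers' own
    rows from every pairwise comparison.
    """
    markers = list(markers)
    missing = [m for m in markers if m not in nm.genes]
    if missing:
        raise ValueError(f"markers absent from matrix: {missing}")
    X = nm.values
    sd = X.std(axis=1, ddof=1)
    for m in markers:
        if sd[m] == 0:
            raise ValueError(f"marker {m!r} has zero variance")

    Xc = X.sub(X.mean(axis=1), axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=1))
    profiles = pd.DataFrame(index=nm.genes, columns=markers, dtype=float)
    for m in markers:
        num = Xc @ Xc.loc[m]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / (denom * denom[m])
        profiles[m] = r.replace([np.inf, -np.inf], np.nan)

    profile_corr = pd.DataFrame(np.eye(len(markers)), index=markers, columns=markers)
    for a, b in itertools.combinations(markers, 2):
        keep = ~profiles.index.isin([a, b])
        pa, pb = profiles.loc[keep, a], profiles.loc[keep, b]
        ok = pa.notna() & pb.notna()
        r = float(np.corrcoef(pa[ok], pb[ok])[0, 1])
        profile_corr.loc[a, b] = profile_corr.loc[b, a] = r
    return profiles, profile_corr


def expression_overlap(values: pd.DataFrame, markers, threshold: float = 0.0) -> dict:
    """Count cells positive for every subset of ``markers``.

    A cell is positive for a marker when its value is strictly greater than
    ``threshold`` (zeros are treated as non-expression).  Returns a dict with
    the full 2^m contingency (keys = frozensets of positive markers), the
    per-marker positive and zero counts, and the all-positive count.
    """
    markers = list(markers)
    missing = [m for m in markers if m not in values.index]
    if missing:
        raise ValueError(f"markers absent from matrix: {missing}")
    pos = values.loc[markers] > threshold
    contingency: dict = {}
    for cell in values.columns:
        key = frozenset(m for m in markers if pos.loc[m, cell])
        contingency[key] = contingency.get(key, 0) + 1
    n_positive = {m: int(pos.loc[m].sum()) for m in markers}
    n_zero = {m: int((values.loc[m] <= threshold).sum()) for m in markers}
    n_all = sum(v for k, v in contingency.items() if len(k) == len(markers))
    return {
        "contingency": contingency,
        "n_positive": n_positive,
        "n_zero": n_zero,
        "n_all_positive": int(n_all),
        "n_cells": int(values.shape[1]),
    }
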