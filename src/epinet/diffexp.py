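"""Two-group differential expression on raw counts.

A deliberately transparent negative-binomial Wald test: median-of-ratios
size factors, per-gene method-of-moments dispersion with a small floor, and
a Wald statistic on the log fold change between groups.  No dispersion or
fold-change shrinkage is applied — the engine trades the power tweaks of the
large packages for a fully specifiable model, which is what the downstream
enrichment and network stages need.

Genes with base mean below a configurable floor are excluded before testing
(independent filtering), so they do not enter the Benjamini-Hochberg
denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

__all__ = ["DEResult", "size_factors", "de_test"]


@dataclass
class DEResult:
    table: pd.DataFrame     # gene, base_mean, log2_fold_change, p_value, adjusted_p, direction
    group_a: str
    group_b: str
    alpha: float

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t["direction"] != "ns"]

    def up_in(self, group: str) -> list:
        d = {self.group_a: "up_in_A", self.group_b: "up_in_B"}[group]
        return list(self.table.index[self.table["direction"] == d])


def size_factors(m) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes with a finite, nonzero geometric mean of
    count_gj / geomean_g.  Accepts a CountMatrix or a genes x samples frame.
    """
    counts = m.drop_ercc().counts if isinstance(m, CountMatrix) else pd.DataFrame(m)
    X = counts.values.astype(float)
    with np.errstate(divide="ignore"):
        logs = np.log(X)
    ok = np.isfinite(logs).all(axis=1)
    if ok.any():
        log_geo = logs[ok].mean(axis=1)
        ratios = np.exp(logs[ok] - log_geo[:, None])
        sf = np.median(ratios, axis=0)
    else:
        # sparse (dropout-heavy) matrices: geometric mean over positive
        # entries only, median of ratios over each sample's positive genes
        warnings.warn(
            "no gene has nonzero counts in every sample; "
            "using positive-count geometric means"
        )
        pos = X > 0
        frac_pos = pos.mean(axis=1)
        use = frac_pos >= 0.5
        if not use.any():
            raise ValueError("counts too sparse for size-factor estimation")
        lg = np.where(pos, logs, np.nan)
        log_geo = np.nanmean(lg[use], axis=1)
        ratios = np.exp(lg[use] - log_geo[:, None])
        sf = np.nanmedian(ratios, axis=0)
        if not np.isfinite(sf).all() or (sf <= 0).any():
            raise ValueError("size factors undefined for some samples")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _moment_dispersion(norm: np.ndarray, groups_idx, mu: np.ndarray,
                       floor: float = 1e-8) -> np.ndarray:
    """Per-gene NB dispersion by pooled within-group method of moments."""
    n = norm.shape[1]
    resid_var = np.zeros(norm.shape[0])
    mean_mu = np.zeros(norm.shape[0])
    for idx in groups_idx:
        sub = norm[:, idx]
        resid_var += sub.var(axis=1, ddof=1) * (len(idx) - 1)
        mean_mu += sub.mean(axis=1) * len(idx)
    resid_var /= max(n - len(groups_idx), 1)
    mean_mu /= n
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (resid_var - mean_mu) / mean_mu ** 2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return np.maximum(alpha, floor)


def de_test(m: CountMatrix, groups: pd.Series, alpha: float = 0.01,
            min_base_mean: float = 0.5, pseudo: float = 1e-8) -> DEResult:
    """Negative-binomial Wald test between two groups of samples.

    ``groups`` must take exactly two values over the matrix's samples, each
    with at least 2 members.  The log2 fold change is group A over group B
    where A is the lexicographically first level.  ``direction`` is assigned
    from the sign of the fold change for genes with adjusted p <= alpha.
    """
    groups = pd.Series(groups).loc[m.samples]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"groups must have exactly 2 levels, got {levels}")
    ga, gb = levels
    idx_a = np.flatnonzero((groups == ga).values)
    idx_b = np.flatnonzero((groups == gb).values)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    counts = m.drop_ercc().counts
    sf = size_factors(m)
    norm = counts.values.astype(float) / sf.values[None, :]
    base_mean = norm.mean(axis=1)

    tested = base_mean >= min_base_mean
    alpha_disp = _moment_dispersion(norm, (idx_a, idx_b), base_mean)

    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    log2fc = np.log2((mu_a + pseudo) / (mu_b + pseudo))

    # delta-method variance of log mean under NB(mu, alpha): (1/mu + alpha)/n
    with np.errstate(divide="ignore", invalid="ignore"):
        var_a = (1.0 / np.maximum(mu_a, pseudo) + alpha_disp) / len(idx_a)
        var_b = (1.0 / np.maximum(mu_b, pseudo) + alpha_disp) / len(idx_b)
        wald = (np.log(mu_a + pseudo) - np.log(mu_b + pseudo)) / np.sqrt(var_a + var_b)
    # t reference with the residual df: the moment dispersion estimate makes
    # the normal reference anticonservative at small n
    df_resid = len(idx_a) + len(idx_b) - 2
    pvals = 2.0 * stats.t.sf(np.abs(wald), df=df_resid)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    padj = np.full_like(pvals, np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    direction = np.full(len(counts), "ns", dtype=object)
    sig = tested & (padj <= alpha)
    direction[sig & (log2fc > 0)] = "up_in_A"
    direction[sig & (log2fc < 0)] = "up_in_B"

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": log2fc,
            "p_value": np.where(tested, pvals, np.nan),
            "adjusted_p": padj,
            "direction": direction,
        },
        index=counts.index,
    )
    return DEResult(table=table, group_a=ga, group_b=gb, alpha=alpha)
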