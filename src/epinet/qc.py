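"""Cell and gene quality control, library-size correction, variance
stabilisation and empirical-Bayes batch correction.

Cell filters follow the plate-based Smart-seq2 conventions: wells dominated by
ERCC spike-in reads are empty or degraded, wells with few reads in genes or
few detected genes are failed libraries, and low-depth cells (few total reads,
few genes) distort distance-based analyses.  Rules are applied in one fixed,
documented order and every removed cell is attributed to the FIRST rule it
violates:

    1. ercc_frac        ERCC reads / total reads > ercc_frac_max
    2. frac_in_genes    gene reads / total reads < min_frac_in_genes
    3. gene_frac        detected genes / total genes < min_genes_detected_frac
    4. min_reads        total reads < min_reads
    5. min_genes        detected genes < min_genes_detected

ERCC rows are excluded from the CPM numerator and denominator and from
"detected genes": spike-ins calibrate wells, they are not biology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_cells",
    "cpm",
    "filter_genes",
    "log_transform",
    "correct_batch",
    "RULE_ORDER",
]

RULE_ORDER = ("ercc_frac", "frac_in_genes", "gene_frac", "min_reads", "min_genes")


@dataclass(frozen=True)
class QCThresholds:
    """Cell-filter thresholds.

    Defaults are the standard plate-scale values: remove wells with > 97% of
    reads in ERCC spike-ins, < 80% of reads in genes, < 2% of genes detected,
    fewer than 500,000 total reads, or fewer than 7000 detected genes.
    """

    ercc_frac_max: float = 0.97
    min_frac_in_genes: float = 0.80
    min_genes_detected_frac: float = 0.02
    min_reads: int = 500_000
    min_genes_detected: int = 7000

    def __post_init__(self) -> None:
        for name in ("ercc_frac_max", "min_frac_in_genes", "min_genes_detected_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("min_reads", "min_genes_detected"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCReport:
    """Per-sample pass/fail bookkeeping for a cell-filter pass."""

    verdicts: pd.DataFrame      # index = samples; columns: passed, failed_rule
    kept: list
    removed_per_rule: dict

    def summary(self) -> dict:
        return {
            "n_input": int(len(self.verdicts)),
            "n_kept": int(len(self.kept)),
            "n_removed": int(len(self.verdicts) - len(self.kept)),
            "removed_per_rule": {k: int(v) for k, v in self.removed_per_rule.items()},
        }


def filter_cells(m: CountMatrix, t: QCThresholds | None = None):
    """Remove failing cells; return the filtered matrix and a reconciling report.

    Each removed sample is attributed to the first rule it violates in
    :data:`RULE_ORDER`.  A matrix with no ERCC rows skips the ERCC rule with a
    warning rather than erroring.
    """
    t = t or QCThresholds()
    total = m.total_reads()
    gene_reads = m.gene_reads()
    detected = m.detected_genes()
    n_genes = m.n_genes
    has_ercc = bool(m.is_ercc.any())
    if not has_ercc:
        logger.warning("no ERCC rows flagged; skipping the spike-in fraction rule")
        warnings.warn("no ERCC rows flagged; skipping the spike-in fraction rule")
        ercc_frac = pd.Series(0.0, index=m.samples)
    else:
        ercc_frac = m.ercc_reads() / total

    checks = {
        "ercc_frac": ercc_frac > t.ercc_frac_max,
        "frac_in_genes": gene_reads / total < t.min_frac_in_genes,
        "gene_frac": detected / n_genes < t.min_genes_detected_frac,
        "min_reads": total < t.min_reads,
        "min_genes": detected < t.min_genes_detected,
    }
    if not has_ercc:
        checks["ercc_frac"] = pd.Series(False, index=m.samples)

    failed_rule = pd.Series(pd.NA, index=m.samples, dtype="object")
    for rule in RULE_ORDER:
        mask = checks[rule] & failed_rule.isna()
        failed_rule[mask] = rule

    verdicts = pd.DataFrame(
        {"passed": failed_rule.isna(), "failed_rule": failed_rule}, index=m.samples
    )
    kept = list(m.samples[verdicts["passed"]])
    removed_per_rule = {
        rule: int((failed_rule == rule).sum()) for rule in RULE_ORDER
    }
    report = QCReport(verdicts=verdicts, kept=kept, removed_per_rule=removed_per_rule)
    assert len(report.kept) + int(verdicts["failed_rule"].notna().sum()) == len(m.samples)
    return m.subset_samples(kept), report


def cpm(m: CountMatrix) -> NormalizedMatrix:
    """Counts-per-million library-size correction over non-ERCC genes.

    Each column of the result sums to 1e6.  Spike-in rows are dropped from
    both numerator and denominator.
    """
    biol = m.drop_ercc()
    colsum = biol.counts.sum(axis=0).astype(float)
    bad = colsum[colsum <= 0]
    if len(bad):
        raise ValueError(f"zero-sum columns cannot be CPM-corrected: {list(bad.index)[:5]}")
    values = biol.counts.astype(float).div(colsum, axis=1) * 1e6
    return NormalizedMatrix(
        values=values, metadata=m.metadata.copy(), cpm_corrected=True, log_scale=False
    )


def filter_genes(nm: NormalizedMatrix, min_cpm: float = 1.0, min_fold: float = 2.0,
                 pseudo_count: float = 1.0) -> NormalizedMatrix:
    """Discard genes below ``min_cpm`` in every sample, and genes whose
    expression varies by less than ``min_fold`` across samples.

    The fold range is computed on CPM + ``pseudo_count`` so all-zero samples
    do not divide by zero.  Expects a linear-scale (CPM) matrix.
    """
    if nm.log_scale:
        raise ValueError("filter_genes expects a linear-scale (CPM) matrix")
    v = nm.values
    expressed = (v >= min_cpm).any(axis=1)
    shifted = v + pseudo_count
    fold = shifted.max(axis=1) / shifted.min(axis=1)
    variable = fold >= min_fold
    keep = expressed & variable
    if not keep.any():
        warnings.warn("gene filtering removed every gene")
    return nm.with_values(v.loc[keep].copy())


def log_transform(nm: NormalizedMatrix, pseudo_count: float = 1.0) -> NormalizedMatrix:
    """Shifted log2 variance-stabilising transform: log2(CPM + pseudo_count).

    A deliberate closed-form stand-in for regularised-log normalisation; it is
    monotone in the input, so rank-based downstream analyses are unaffected.
    """
    if nm.log_scale:
        raise ValueError("matrix is already log-scale")
    out = nm.with_values(np.log2(nm.values + pseudo_count), log_scale=True)
    out.pseudo_count = pseudo_count
    return out


def correct_batch(nm: NormalizedMatrix, batch: pd.Series | None = None,
                  max_iter: int = 200, tol: float = 1e-6) -> NormalizedMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene: standardise against the batch-size-weighted grand mean and
    pooled residual variance; estimate each batch's additive and
    multiplicative effect; shrink the effects across genes toward their
    batch-level means (normal prior for location, inverse-gamma for scale,
    hyperparameters by method of moments, estimates iterated to convergence);
    remove them; restore the grand mean and pooled scale.

    A single batch is returned unchanged; a batch with fewer than 2 samples is
    rejected.
    """
    if batch is None:
        if "batch" not in nm.metadata.columns:
            raise ValueError("no batch labels supplied and none in metadata")
        batch = nm.metadata["batch"]
    batch = pd.Series(batch, index=nm.samples).astype(str)
    levels = batch.unique()
    if len(levels) < 2:
        return nm.with_values(nm.values.copy(), batch_corrected=True)
    sizes = batch.value_counts()
    if (sizes < 2).any():
        small = list(sizes[sizes < 2].index)
        raise ValueError(f"each batch needs >= 2 samples; too small: {small}")

    X = nm.values.values.astype(float)
    n_genes, n_samples = X.shape
    masks = {b: (batch == b).values for b in levels}
    n_b = {b: int(masks[b].sum()) for b in levels}

    batch_means = np.column_stack([X[:, masks[b]].mean(axis=1) for b in levels])
    weights = np.array([n_b[b] / n_samples for b in levels])
    grand = batch_means @ weights                      # weighted grand mean per gene

    # pooled variance of residuals about each sample's batch mean
    resid = X.copy()
    for j, b in enumerate(levels):
        resid[:, masks[b]] -= batch_means[:, [j]]
    pooled_var = (resid ** 2).sum(axis=1) / n_samples
    sd = np.sqrt(pooled_var)
    ok = sd > 0                                         # constant genes pass through

    Z = np.zeros_like(X)
    Z[ok] = (X[ok] - grand[ok, None]) / sd[ok, None]

    Zc = Z.copy()
    for j, b in enumerate(levels):
        mb = masks[b]
        gamma_hat = Z[ok][:, mb].mean(axis=1)
        delta_hat = Z[ok][:, mb].var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m_d, v_d = delta_hat.mean(), delta_hat.var(ddof=1)
        if v_d <= 0:
            lam, theta = 2.0, m_d  # flat-ish prior fallback for degenerate spread
        else:
            lam = (2 * v_d + m_d ** 2) / v_d
            theta = (m_d * v_d + m_d ** 3) / v_d

        g_star = gamma_hat.copy()
        d_star = delta_hat.copy()
        Zb = Z[ok][:, mb]
        nb = n_b[b]
        for _ in range(max_iter):
            g_new = (nb * tau2 * gamma_hat + d_star * gamma_bar) / (nb * tau2 + d_star)
            ss = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * ss) / (nb / 2 + lam - 1)
            if (np.max(np.abs(g_new - g_star)) < tol
                    and np.max(np.abs(d_new - d_star)) < tol):
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new

        adj = (Zb - g_star[:, None]) / np.sqrt(np.maximum(d_star, 1e-12))[:, None]
        block = Zc[ok]
        block[:, mb] = adj
        Zc[ok] = block

    out = X.copy()
    out[ok] = Zc[ok] * sd[ok, None] + grand[ok, None]
    values = pd.DataFrame(out, index=nm.genes, columns=nm.samples)
    return nm.with_values(values, batch_corrected=True)
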