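"""Synthetic single-cell and bulk-network data with ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`simulate_sc_counts` emulates a plate-based Smart-seq2 single-cell
  experiment on an epicardium-like culture: two subpopulations defined by
  anti-correlated marker programs, a small mitotic subset overexpressing a
  proliferation program, ERCC spike-in rows, log-normal library-size
  variation, two culture batches with a log-scale shift, Bernoulli dropout
  zeros, and optionally planted cells that each violate one QC rule.

* :func:`simulate_grn_expression` emulates bulk transcription-factor
  expression across developmental stages, generated from a known acyclic
  directed network by a linear-Gaussian structural model.  One hub TF with a
  large out-degree plays the "master regulator"; a terminal sink TF (in-edges
  only) is planted as its directional foil.  The generating graph is returned
  as ground truth for edge- and direction-recovery tests.

Count noise model: Poisson sampling around per-cell x per-gene means that
carry a log-normal noise layer, so marginal counts are overdispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountMatrix
from .qc import QCThresholds

__all__ = [
    "SCSimConfig",
    "GRNSimConfig",
    "GRNTruth",
    "simulate_sc_counts",
    "simulate_grn_expression",
    "make_gene_sets",
]

def sim_qc_thresholds(n_genes: int = 2000) -> QCThresholds:
    """QC thresholds coherent with the generator's desk scale.

    The absolute plate-scale cutoffs (500k reads, 7000 genes) assume a real
    transcriptome; at a simulated size of ``n_genes`` the generator plants
    its violations against read/gene cutoffs scaled to its own expected
    depth (~36 expected counts per gene per cell).  Fractional rules keep
    their plate-scale values.
    """
    return QCThresholds(
        ercc_frac_max=0.97,
        min_frac_in_genes=0.80,
        min_genes_detected_frac=0.02,
        min_reads=max(1000, 5 * n_genes),
        min_genes_detected=max(40, n_genes // 4),
    )


SIM_QC_THRESHOLDS = sim_qc_thresholds()

_BAD_CLASSES = ("ercc_frac", "min_reads", "min_genes")


@dataclass(frozen=True)
class SCSimConfig:
    """Configuration for the single-cell count simulator.

    Population sizes default to the observed cluster sizes of the system this
    emulates (146 / 62 / 24 cells).  ``marker_fold`` is the pre-noise ratio of
    a marker's mean between its own and the other population.  ``batch_shift``
    is a natural-log additive offset applied to the second batch's gene means.
    ``lognoise_sd`` is the sd of the log-normal layer that overdisperses the
    Poisson counts; 0 switches biological noise off.
    """

    n_cells_popA: int = 146
    n_cells_popB: int = 62
    n_mitotic: int = 24
    n_genes: int = 2000
    n_markers_per_pop: int = 250
    marker_fold: float = 8.0
    dropout_rate: float = 0.3
    ercc_frac_mean: float = 0.05
    n_bad_cells: int = 0
    libsize_log_sd: float = 0.4
    n_batches: int = 2
    batch_shift: float = 0.4
    seed: int = 0
    # secondary knobs
    n_prolif_genes: int = 30
    prolif_fold: float = 6.0
    lognoise_sd: float = 0.3
    n_ercc: int = 20
    base_mean_log_mu: float = float(np.log(10.0))
    base_mean_log_sd: float = 1.6
    marker_base_log_mu: float = float(np.log(60.0))
    marker_base_log_sd: float = 0.5
    qc_thresholds: QCThresholds | None = None

    def __post_init__(self) -> None:
        if self.qc_thresholds is None:
            object.__setattr__(self, "qc_thresholds", sim_qc_thresholds(self.n_genes))
        for name in ("n_cells_popA", "n_cells_popB", "n_mitotic", "n_genes",
                     "n_markers_per_pop", "n_bad_cells", "n_batches",
                     "n_prolif_genes", "n_ercc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if not 0.0 <= self.ercc_frac_mean < 1.0:
            raise ValueError("ercc_frac_mean must lie in [0, 1)")
        if self.libsize_log_sd < 0:
            raise ValueError("libsize_log_sd must be >= 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        reserved = 2 * self.n_markers_per_pop + self.n_prolif_genes
        if reserved > self.n_genes:
            raise ValueError(
                "n_markers_per_pop and n_prolif_genes reserve "
                f"{reserved} genes but n_genes is only {self.n_genes}"
            )
        if self.marker_fold <= 0 or self.prolif_fold <= 0:
            raise ValueError("marker_fold and prolif_fold must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_cells_popA + self.n_cells_popB + self.n_mitotic + self.n_bad_cells

    @property
    def popA_markers(self) -> list:
        return [f"MARKA{i:04d}" for i in range(self.n_markers_per_pop)]

    @property
    def popB_markers(self) -> list:
        return [f"MARKB{i:04d}" for i in range(self.n_markers_per_pop)]

    @property
    def prolif_genes(self) -> list:
        return [f"PRLF{i:04d}" for i in range(self.n_prolif_genes)]

    @property
    def gene_names(self) -> list:
        n_bg = self.n_genes - 2 * self.n_markers_per_pop - self.n_prolif_genes
        return (self.popA_markers + self.popB_markers + self.prolif_genes
                + [f"GENE{i:04d}" for i in range(n_bg)])

    @property
    def ercc_names(self) -> list:
        return [f"ERCC-{i:05d}" for i in range(self.n_ercc)]


def _sc_mean_matrix(cfg: SCSimConfig, rng: np.random.Generator):
    """Pre-noise per-(gene, cell) Poisson means, plus cell bookkeeping.

    Returns (gene log-means matrix incl. ERCC rows, labels, batches,
    bad-cell classes dict).
    """
    genes = cfg.gene_names
    n_cells = cfg.n_cells
    labels = (["popA"] * cfg.n_cells_popA + ["popB"] * cfg.n_cells_popB
              + ["mitotic"] * cfg.n_mitotic + ["bad"] * cfg.n_bad_cells)

    # skewed background expression; marker/proliferation programs sit in the
    # moderately-high expression range where a program is detectable
    base = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, size=cfg.n_genes)
    n_prog = 2 * cfg.n_markers_per_pop + cfg.n_prolif_genes
    base[:n_prog] = rng.lognormal(cfg.marker_base_log_mu, cfg.marker_base_log_sd, size=n_prog)
    log_mu = np.tile(np.log(base)[:, None], (1, n_cells))

    gidx = {g: i for i, g in enumerate(genes)}
    a_rows = [gidx[g] for g in cfg.popA_markers]
    b_rows = [gidx[g] for g in cfg.popB_markers]
    p_rows = [gidx[g] for g in cfg.prolif_genes]

    lf = np.log(cfg.marker_fold)
    # mitotic cells inherit a marker program from a randomly drawn parent population
    mito_parent = rng.choice(["popA", "popB"], size=cfg.n_mitotic)
    mito_i = 0
    for c, lab in enumerate(labels):
        prog = lab
        if lab == "mitotic":
            prog = mito_parent[mito_i]
            mito_i += 1
            log_mu[p_rows, c] += np.log(cfg.prolif_fold)
        elif lab == "bad":
            prog = rng.choice(["popA", "popB"])
        if prog == "popA":
            log_mu[np.array(a_rows), c] += lf
        else:
            log_mu[np.array(b_rows), c] += lf

    batches = np.array([f"batch{c % cfg.n_batches}" for c in range(n_cells)])
    for b in range(1, cfg.n_batches):
        log_mu[:, batches == f"batch{b}"] += b * cfg.batch_shift

    libsize = rng.normal(0.0, cfg.libsize_log_sd, size=n_cells)
    log_mu += libsize[None, :]

    # ERCC spike-ins scale with depth but not with biology
    gene_tot = np.exp(log_mu).sum(axis=0)
    ercc_tot = cfg.ercc_frac_mean / max(1e-12, 1.0 - cfg.ercc_frac_mean) * gene_tot
    conc = rng.dirichlet(np.full(cfg.n_ercc, 5.0)) if cfg.n_ercc else np.zeros(0)
    ercc_mu = conc[:, None] * ercc_tot[None, :]

    # plant QC violators, cycling through the three rule classes
    t = cfg.qc_thresholds
    bad_classes: dict = {}
    bad_cols = [c for c, lab in enumerate(labels) if lab == "bad"]
    for i, c in enumerate(bad_cols):
        cls = _BAD_CLASSES[i % len(_BAD_CLASSES)]
        bad_classes[c] = cls
        if cls == "ercc_frac":
            # empty well: spike-ins swamp the library
            ercc_mu[:, c] *= 60.0 * (1.0 - cfg.ercc_frac_mean) / max(cfg.ercc_frac_mean, 1e-6)
        elif cls == "min_reads":
            target = 0.25 * t.min_reads
            scale = target / max(gene_tot[c], 1.0)
            log_mu[:, c] += np.log(scale)
            ercc_mu[:, c] *= scale
        elif cls == "min_genes":
            keep_n = max(1, int(0.4 * t.min_genes_detected))
            keep = rng.choice(cfg.n_genes, size=keep_n, replace=False)
            mask = np.ones(cfg.n_genes, bool)
            mask[keep] = False
            col_tot = np.exp(log_mu[:, c]).sum()
            log_mu[mask, c] = -np.inf
            kept_tot = np.exp(log_mu[keep, c]).sum()
            log_mu[keep, c] += np.log(col_tot / max(kept_tot, 1e-12))

    return log_mu, ercc_mu, labels, batches, bad_classes


def simulate_sc_counts(cfg: SCSimConfig, return_means: bool = False):
    """Simulate a single-cell count matrix; returns (CountMatrix, labels).

    With ``return_means=True`` a third element carries the pre-sampling
    Poisson mean matrix (biological genes only, before the log-normal noise
    layer), used by tests of the construction.
    """
    rng = np.random.default_rng(cfg.seed)
    log_mu, ercc_mu, labels, batches, bad_classes = _sc_mean_matrix(cfg, rng)
    clean_mu = np.exp(log_mu)

    if cfg.lognoise_sd > 0:
        noise = rng.normal(0.0, cfg.lognoise_sd, size=log_mu.shape)
        mu = np.exp(log_mu + noise)
    else:
        mu = clean_mu

    counts = rng.poisson(mu).astype(np.int64)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts = counts * keep

    ercc_counts = rng.poisson(ercc_mu).astype(np.int64)

    genes = cfg.gene_names + cfg.ercc_names
    cells = [f"cell{c:04d}" for c in range(cfg.n_cells)]
    mat = pd.DataFrame(np.vstack([counts, ercc_counts]), index=genes, columns=cells)
    is_ercc = pd.Series([False] * cfg.n_genes + [True] * cfg.n_ercc, index=genes)
    meta = pd.DataFrame(
        {
            "batch": batches,
            "stage": "hPSC-epi",
            "true_label": labels,
            "bad_class": [bad_classes.get(c, "") for c in range(cfg.n_cells)],
        },
        index=cells,
    )
    cm = CountMatrix(counts=mat, is_ercc=is_ercc, metadata=meta)
    true_labels = pd.Series(labels, index=cells, name="true_label")
    if return_means:
        means = pd.DataFrame(clean_mu, index=cfg.gene_names, columns=cells)
        return cm, true_labels, means
    return cm, true_labels


# ----------------------------------------------------------------- GRN -----

@dataclass(frozen=True)
class GRNSimConfig:
    """Configuration for the bulk TF-network simulator.

    ``edge_weight_range`` gives the magnitude interval for edge weights
    (signs are drawn at random), so 0 is excluded.  ``stage_sd`` is the sd of
    the stage-specific intercepts placed on root TFs — the between-stage
    variation that drives the system, standing in for samples taken along a
    differentiation time course.
    """

    n_tfs: int = 60
    hub_out_degree: int = 20
    background_out_degree_mean: float = 1.5
    n_samples: int = 24
    n_stages: int = 4
    edge_weight_range: tuple = (0.4, 1.0)
    noise_sd: float = 0.3
    seed: int = 0
    stage_sd: float = 2.0
    plant_sink: bool = True
    sink_in_degree: int = 3

    def __post_init__(self) -> None:
        if self.hub_out_degree >= self.n_tfs:
            raise ValueError("hub_out_degree must be < n_tfs")
        if self.n_samples < self.n_stages:
            raise ValueError("n_samples must be >= n_stages")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.edge_weight_range
        if not (0 < lo <= hi):
            raise ValueError("edge_weight_range must be a positive interval excluding 0")
        if self.n_tfs < 5:
            raise ValueError("n_tfs must be >= 5")


@dataclass
class GRNTruth:
    """Ground-truth directed network behind a simulated expression matrix."""

    genes: list
    adjacency: list          # (regulator, target, weight) triples
    hub_gene: str
    sink_gene: str | None = None

    def edge_set(self) -> set:
        return {(r, t) for r, t, _ in self.adjacency}

    def undirected_edge_set(self) -> set:
        return {frozenset((r, t)) for r, t, _ in self.adjacency}

    def out_degree(self, gene: str) -> int:
        return sum(1 for r, _, _ in self.adjacency if r == gene)

    def in_degree(self, gene: str) -> int:
        return sum(1 for _, t, _ in self.adjacency if t == gene)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_weighted_edges_from(self.adjacency)
        return g

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.adjacency, columns=["regulator", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )


def _build_grn(cfg: GRNSimConfig, rng: np.random.Generator) -> GRNTruth:
    n = cfg.n_tfs
    genes = [f"TF{i + 1:03d}" for i in range(n)]
    order = list(rng.permutation(n))       # order[k] = gene index at topo rank k

    # the hub sits at the top of a cascade: its direct targets are the next
    # topological ranks, so its influence propagates through the background
    # edges to most of the network -- the master-regulator structure
    hub_rank = 0
    hub = genes[order[hub_rank]]
    sink = genes[order[-1]] if cfg.plant_sink else None

    lo, hi = cfg.edge_weight_range
    edges: dict = {}

    def add_edge(r, t):
        if (r, t) in edges or r == t:
            return False
        w = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
        edges[(r, t)] = w
        return True

    in_deg = {g: 0 for g in genes}

    # hub out-edges: the immediately downstream ranks
    for k in range(hub_rank + 1, hub_rank + 1 + cfg.hub_out_degree):
        if add_edge(hub, genes[order[k]]):
            in_deg[genes[order[k]]] += 1

    # hub in-edges: at most 2, from upstream
    if hub_rank > 0:
        n_in = int(rng.integers(0, min(2, hub_rank) + 1))
        ups = rng.choice(hub_rank, size=n_in, replace=False)
        for k in ups:
            if add_edge(genes[order[k]], hub):
                in_deg[hub] += 1

    # background edges in topological order; hub in-degree stays <= 2
    for rank in range(n - 1):
        src = genes[order[rank]]
        if src == sink:
            continue
        k_out = int(rng.poisson(cfg.background_out_degree_mean))
        if src == hub or k_out == 0:
            continue
        cands = [genes[order[j]] for j in range(rank + 1, n)
                 if not (genes[order[j]] == hub and in_deg[hub] >= 2)]
        if not cands:
            continue
        pick = rng.choice(len(cands), size=min(k_out, len(cands)), replace=False)
        for j in pick:
            if add_edge(src, cands[j]):
                in_deg[cands[j]] += 1

    # guarantee the sink has in-edges (it can have no out-edges by position)
    if sink is not None:
        while in_deg[sink] < cfg.sink_in_degree:
            rank = int(rng.integers(0, n - 1))
            src = genes[order[rank]]
            if src == sink:
                continue
            if add_edge(src, sink):
                in_deg[sink] += 1

    adjacency = [(r, t, w) for (r, t), w in edges.items()]
    return GRNTruth(genes=genes, adjacency=adjacency, hub_gene=hub, sink_gene=sink)


def simulate_grn_expression(cfg: GRNSimConfig, max_attempts: int = 5):
    """Simulate bulk TF expression from a known directed network.

    Returns ``(expression DataFrame [TF x sample], GRNTruth)``.  Expression is
    generated by evaluating a linear-Gaussian structural model in topological
    order: root TFs get stage-specific intercepts, every TF adds the weighted
    sum of its parents plus Gaussian noise.  Samples are assigned to stages
    round-robin.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = None
    for _ in range(max_attempts):
        cand = _build_grn(cfg, rng)
        if nx.is_directed_acyclic_graph(cand.to_graph()):
            truth = cand
            break
    if truth is None:  # unreachable with forward-only edges; contract kept
        raise RuntimeError(f"could not generate an acyclic network in {max_attempts} attempts")

    g = truth.to_graph()
    topo = list(nx.topological_sort(g))
    stages = [f"stage{j % cfg.n_stages}" for j in range(cfg.n_samples)]
    samples = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
    stage_levels = sorted(set(stages))

    roots = [gname for gname in truth.genes if g.in_degree(gname) == 0]
    intercepts = {
        (gname, st): rng.normal(0.0, cfg.stage_sd)
        for gname in roots for st in stage_levels
    }

    X = pd.DataFrame(0.0, index=truth.genes, columns=samples)
    stage_of = dict(zip(samples, stages))
    for gname in topo:
        base = np.zeros(cfg.n_samples)
        if gname in roots:
            base += np.array([intercepts[(gname, stage_of[s])] for s in samples])
        for parent in g.predecessors(gname):
            base += g[parent][gname]["weight"] * X.loc[parent].values
        noise = rng.normal(0.0, cfg.noise_sd, cfg.n_samples) if cfg.noise_sd > 0 else 0.0
        X.loc[gname] = base + noise

    X.attrs["stage"] = stage_of
    return X, truth


def simulate_nb_counts(
    n_genes: int = 200,
    n_per_group: int = 20,
    n_de: int = 0,
    fold: float = 4.0,
    dispersion: float = 0.1,
    mean_log_mu: float = float(np.log(100.0)),
    mean_log_sd: float = 1.0,
    seed: int = 0,
):
    """Negative-binomial two-group counts with optionally planted fold changes.

    The first ``n_de`` genes carry a ``fold``-times higher mean in group A.
    Returns (CountMatrix, Series of group labels, list of DE gene names).
    Used by the differential-expression calibration and power analyses.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"A{j}" for j in range(n_per_group)] + [f"B{j}" for j in range(n_per_group)]
    base = rng.lognormal(mean_log_mu, mean_log_sd, size=n_genes)
    mu = np.tile(base[:, None], (1, 2 * n_per_group))
    mu[:n_de, :n_per_group] *= fold
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    is_ercc = pd.Series(False, index=df.index)
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples)
    meta = pd.DataFrame({"batch": "batch0", "stage": "bulk", "group": groups}, index=samples)
    cm = CountMatrix(counts=df, is_ercc=is_ercc, metadata=meta)
    return cm, groups, genes[:n_de]


def make_gene_sets(assignments: dict) -> dict:
    """Turn {gene: iterable of set names} into a GMT-ready {set: [genes]}.

    Set order follows first appearance; gene order within a set follows the
    assignment order.  Overlaps are preserved.
    """
    if not assignments:
        raise ValueError("assignments must be non-empty")
    sets: dict = {}
    for gene, names in assignments.items():
        for name in names:
            if not str(name):
                raise ValueError(f"empty set name for gene {gene!r}")
            sets.setdefault(str(name), []).append(str(gene))
    return sets
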