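"""Parameter-recovery analyses on synthetic data.

These are the package's benchmark surfaces: each function simulates data
under the generator's study conditions, runs the corresponding pipeline
stages, and measures how well the known ground truth is recovered.  They are
used by the acceptance analyses, the numbered analysis scripts and the test
suite.

Problem sizes: the network recovery runs 60 TFs x 24 samples with 200 trees
per target (the tree ensemble's importance ranking is stable well below the
1000-tree default at 59 regulators); the clustering recovery runs 150 cells
x 2000 genes with 5 embedding seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import pam
from .diffexp import de_test
from .dimred import tsne_sweep
from .evaluate import edge_density, undirected_aupr
from .network import clr, combine, directionality_stats, mutual_information, seed_subnetwork, tree_importances
from .qc import correct_batch, cpm, filter_cells, filter_genes, log_transform
from .simulate import GRNSimConfig, SCSimConfig, simulate_grn_expression, simulate_nb_counts, simulate_sc_counts

__all__ = [
    "qc_fixture_analysis",
    "clustering_recovery",
    "de_null_calibration",
    "de_power_analysis",
    "grn_recovery",
]


def qc_fixture_analysis(seed: int = 11) -> dict:
    """60-cell fixture with 6 planted violators (2 per rule class):
    reapply the cell filter and reconcile the report with the plant."""
    cfg = SCSimConfig(n_cells_popA=30, n_cells_popB=24, n_mitotic=0,
                      n_bad_cells=6, seed=seed)
    cm, labels = simulate_sc_counts(cfg)
    _, report = filter_cells(cm, cfg.qc_thresholds)
    planted = cm.metadata.query("true_label == 'bad'")["bad_class"]
    attributed = report.verdicts.loc[planted.index, "failed_rule"]
    return {
        "n_cells": int(len(cm.samples)),
        "n_removed": int(report.summary()["n_removed"]),
        "removed_per_rule": report.removed_per_rule,
        "attribution_correct": bool((attributed == planted).all()),
    }


def _preprocess_sc(cfg: SCSimConfig):
    cm, labels = simulate_sc_counts(cfg)
    filtered, _ = filter_cells(cm, cfg.qc_thresholds)
    nm = log_transform(filter_genes(cpm(filtered)))
    if filtered.metadata["batch"].nunique() > 1:
        nm = correct_batch(nm)
    return nm, labels[nm.samples]


def clustering_recovery(sim_seed: int = 0, tsne_seeds=(0, 1, 2, 3, 4),
                        perplexity: float = 30.0, max_iter: int = 2000) -> dict:
    """Two populations (90/60 cells), dropout 0.3, batch-corrected: PAM k=2
    on each t-SNE embedding scored against the true labels."""
    cfg = SCSimConfig(n_cells_popA=90, n_cells_popB=60, n_mitotic=0,
                      n_bad_cells=0, dropout_rate=0.3, seed=sim_seed)
    nm, labels = _preprocess_sc(cfg)
    aris, kls = [], []
    for s in tsne_seeds:
        best, _ = tsne_sweep(nm, perplexities=[perplexity], seeds=[s],
                             max_iter=max_iter)
        ca = pam(best.coords, k=2)
        aris.append(float(adjusted_rand_score(labels, ca.labels)))
        kls.append(best.kl_divergence)
    return {"aris": aris, "min_ari": float(min(aris)),
            "mean_ari": float(np.mean(aris)), "kl_divergences": kls}


def de_null_calibration(seed: int = 31, n_reps: int = 5,
                        n_genes: int = 200, n_per_group: int = 20) -> dict:
    """Type-I error: permuted labels of one homogeneous population; the
    fraction of raw p-values below 0.05 averaged over permutation draws."""
    cm, groups, _ = simulate_nb_counts(n_genes=n_genes, n_per_group=n_per_group,
                                       n_de=0, seed=seed)
    fracs = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed * 1000 + rep)
        perm = pd.Series(rng.permutation(groups.values), index=groups.index)
        p = de_test(cm, perm).table["p_value"].dropna()
        fracs.append(float((p < 0.05).mean()))
    return {"fractions": fracs, "mean_fraction": float(np.mean(fracs))}


def de_power_analysis(seed: int = 7, n_de: int = 50, fold: float = 4.0,
                      dispersion: float = 0.1, n_per_group: int = 20) -> dict:
    """Planted fold-change recovery at adjusted p < 0.01."""
    cm, groups, de_genes = simulate_nb_counts(
        n_genes=200, n_per_group=n_per_group, n_de=n_de, fold=fold,
        dispersion=dispersion, seed=seed)
    res = de_test(cm, groups, alpha=0.01)
    t = res.table.loc[de_genes]
    power = float((t["adjusted_p"] < 0.01).mean())
    return {"power": power, "n_planted": n_de}


def grn_recovery(seeds=(0, 1, 2, 3, 4), n_trees: int = 200,
                 top_n: int = 100) -> dict:
    """Directed-network recovery at the benchmark conditions: 60 TFs, hub
    out-degree 20, 24 samples over 4 stages, noise sd 0.3.

    Per seed: AUPR of the combined undirected ranking vs the density
    baseline, and the hub's / sink's outgoing fraction among their retained
    top-N edges (also among their 50 strongest, where the truncation is
    sharper)."""
    per_seed = []
    for seed in seeds:
        cfg = GRNSimConfig(seed=seed)
        X, truth = simulate_grn_expression(cfg)
        scores = clr(mutual_information(X))
        imp = tree_importances(X, n_trees=n_trees, seed=seed)
        edges = combine(scores, imp)
        sub = seed_subnetwork(edges, [truth.hub_gene, truth.sink_gene], top_n=top_n)
        _, _, hub_frac = directionality_stats(sub, truth.hub_gene)
        _, _, sink_frac = directionality_stats(sub, truth.sink_gene)
        _, _, hub50 = directionality_stats(sub, truth.hub_gene, top_k=50)
        _, _, sink50 = directionality_stats(sub, truth.sink_gene, top_k=50)
        per_seed.append({
            "seed": int(seed),
            "aupr": undirected_aupr(edges, truth),
            "density": edge_density(truth),
            "hub_outgoing_fraction": hub_frac,
            "sink_outgoing_fraction": sink_frac,
            "hub_outgoing_fraction_top50": hub50,
            "sink_outgoing_fraction_top50": sink50,
            "n_edges": len(edges),
        })
    auprs = [r["aupr"] for r in per_seed]
    dens = [r["density"] for r in per_seed]
    return {
        "per_seed": per_seed,
        "mean_aupr": float(np.mean(auprs)),
        "mean_density": float(np.mean(dens)),
        "aupr_density_ratio": float(np.mean(auprs) / np.mean(dens)),
        "hub_gt_half": sum(r["hub_outgoing_fraction"] > 0.5 for r in per_seed),
        "sink_lt_half": sum(r["sink_outgoing_fraction"] < 0.5 for r in per_seed),
    }
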