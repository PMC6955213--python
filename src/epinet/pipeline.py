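"""Stage orchestration: file-level wiring of the analysis stages.

Each stage reads only its declared inputs, writes plain-text outputs into the
output directory, and drops a JSON provenance sidecar (package version,
config hash, seed, timestamp) next to its primary output.  TSV outputs carry
no timestamps, so reruns with identical config and seed are byte-identical.

Stage order for a full run: qc -> cluster -> diffexp -> enrich -> network.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix, NormalizedMatrix, read_gene_list, read_gmt, write_gene_list, write_gmt
from .cluster import pam
from .diffexp import de_test
from .dimred import components_for_variance, pca, tsne_sweep
from .enrichment import attach_direction, overrepresentation
from .network import clr, combine, directionality_stats, export_network, mutual_information, seed_subnetwork, tree_importances
from .qc import QCThresholds, correct_batch, cpm, filter_cells, filter_genes, log_transform
from .simulate import GRNSimConfig, SCSimConfig, make_gene_sets, simulate_grn_expression, simulate_sc_counts

DEFAULT_CONFIG = {
    "qc": {},                      # QCThresholds field overrides
    "genes": {"min_cpm": 1.0, "min_fold": 2.0, "pseudo_count": 1.0},
    "dimred": {"perplexities": [30.0], "n_tsne_seeds": 5, "max_iter": 2000,
               "theta": 0.0, "pca_dims": 50},
    "cluster": {"k": 2},
    "de": {"alpha": 0.01, "min_base_mean": 0.5},
    "enrich": {"fdr": 0.05},
    "network": {"n_bins": None, "n_trees": 1000, "k_features": "sqrt",
                "top_n": 100, "seeds": None},
    "seed": 0,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _provenance(stage: str, cfg: dict, seed: int, path: Path) -> None:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    rec = {
        "stage": stage,
        "version": __version__,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": int(seed),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path.write_text(json.dumps(rec, indent=2) + "\n")


def _require(path: Path, producer: str):
    if not Path(path).exists():
        raise FileNotFoundError(
            f"missing input {path}; run the '{producer}' stage first"
        )


def stage_simulate_sc(outdir, cfg: dict, sim_config: SCSimConfig | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = sim_config or SCSimConfig(seed=cfg.get("seed", 0))
    cm, labels = simulate_sc_counts(sim)
    cm.to_tsv(outdir / "sc_counts.tsv", outdir / "sc_metadata.tsv")
    # marker programs double as demo gene sets for the enrichment stage
    assignments = {g: ["program_popA"] for g in sim.popA_markers}
    assignments.update({g: ["program_popB"] for g in sim.popB_markers})
    assignments.update({g: ["program_mitosis"] for g in sim.prolif_genes})
    write_gmt(make_gene_sets(assignments), outdir / "gene_sets.gmt")
    # the thresholds the generator's planted violations reference; the qc
    # stage picks these up unless the user config overrides them
    (outdir / "sim_qc_thresholds.json").write_text(
        json.dumps(asdict(sim.qc_thresholds), indent=2) + "\n")
    _provenance("simulate-sc", cfg, sim.seed, outdir / "sc_counts.prov.json")
    return {"counts": outdir / "sc_counts.tsv", "metadata": outdir / "sc_metadata.tsv",
            "gmt": outdir / "gene_sets.gmt"}


def stage_simulate_grn(outdir, cfg: dict, sim_config: GRNSimConfig | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = sim_config or GRNSimConfig(seed=cfg.get("seed", 0))
    X, truth = simulate_grn_expression(sim)
    X.to_csv(outdir / "grn_expression.tsv", sep="\t", float_format="%.8g")
    truth.to_tsv(outdir / "grn_truth.tsv")
    write_gene_list(truth.genes, outdir / "tf_list.txt")
    (outdir / "grn_seeds.txt").write_text(f"{truth.hub_gene}\n{truth.sink_gene}\n")
    _provenance("simulate-grn", cfg, sim.seed, outdir / "grn_expression.prov.json")
    return {"expression": outdir / "grn_expression.tsv", "truth": outdir / "grn_truth.tsv",
            "tf_list": outdir / "tf_list.txt"}


def stage_qc(counts_path, metadata_path, outdir, cfg: dict) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _require(counts_path, "simulate-sc")
    cm = CountMatrix.from_tsv(counts_path, metadata_path)
    qc_cfg = dict(cfg.get("qc", {}))
    sim_thresh = Path(counts_path).parent / "sim_qc_thresholds.json"
    if not qc_cfg and sim_thresh.exists():
        qc_cfg = json.loads(sim_thresh.read_text())
    thresholds = QCThresholds(**qc_cfg)
    filtered, report = filter_cells(cm, thresholds)
    report.verdicts.to_csv(outdir / "qc_report.tsv", sep="\t")
    (outdir / "qc_summary.json").write_text(json.dumps(report.summary(), indent=2) + "\n")
    filtered.to_tsv(outdir / "filtered_counts.tsv", outdir / "filtered_metadata.tsv")

    g = cfg["genes"]
    nm = log_transform(
        filter_genes(cpm(filtered), g["min_cpm"], g["min_fold"], g["pseudo_count"]),
        g["pseudo_count"],
    )
    if filtered.metadata["batch"].nunique() > 1:
        nm = correct_batch(nm)
    nm.to_tsv(outdir / "normalized.tsv")
    _provenance("qc", cfg, cfg.get("seed", 0), outdir / "normalized.prov.json")
    return {"filtered_counts": outdir / "filtered_counts.tsv",
            "filtered_metadata": outdir / "filtered_metadata.tsv",
            "normalized": outdir / "normalized.tsv"}


def stage_cluster(normalized_path, metadata_path, outdir, cfg: dict) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _require(normalized_path, "qc")
    nm = NormalizedMatrix.from_tsv(normalized_path, metadata_path, log_scale=True)
    d = cfg["dimred"]
    seed0 = int(cfg.get("seed", 0))
    p = pca(nm)
    p.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", float_format="%.8g")
    p.loadings.iloc[:, : min(20, p.n_components)].to_csv(
        outdir / "pca_loadings.tsv", sep="\t", float_format="%.8g")
    pd.DataFrame({"fraction": p.variance_fractions}).to_csv(
        outdir / "pca_variance.tsv", sep="\t", float_format="%.8g")
    best, _ = tsne_sweep(
        nm, perplexities=d["perplexities"],
        seeds=[seed0 + i for i in range(d["n_tsne_seeds"])],
        max_iter=d["max_iter"], theta=d["theta"], pca_dims=d["pca_dims"],
    )
    ca = pam(best.coords, k=cfg["cluster"]["k"])
    out = best.coords.copy()
    out["kl"] = best.kl_divergence
    out["cluster"] = ca.labels
    out["is_medoid"] = out.index.isin(ca.medoids)
    out.index.name = "sample"
    out.to_csv(outdir / "embedding_clusters.tsv", sep="\t", float_format="%.8g")
    _provenance("cluster", cfg, seed0, outdir / "embedding_clusters.prov.json")
    return {"embedding": outdir / "embedding_clusters.tsv",
            "n90": components_for_variance(p, 0.9)}


def stage_diffexp(filtered_counts, filtered_metadata, clusters_path, outdir, cfg: dict) -> dict:
    """DE between the two largest clusters (the smallest, mitotic-like cluster
    is set aside, as the upstream analysis does)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _require(clusters_path, "cluster")
    cm = CountMatrix.from_tsv(filtered_counts, filtered_metadata)
    emb = pd.read_csv(clusters_path, sep="\t", index_col=0)
    sizes = emb["cluster"].value_counts()
    main = sizes.index[:2]
    keep = emb.index[emb["cluster"].isin(main)]
    sub = cm.subset_samples(keep)
    groups = emb.loc[keep, "cluster"].map(
        {main[0]: "cluster_major", main[1]: "cluster_minor"})
    res = de_test(sub, groups, alpha=cfg["de"]["alpha"],
                  min_base_mean=cfg["de"]["min_base_mean"])
    t = res.table.copy()
    t.index.name = "gene"
    t.to_csv(outdir / "de_results.tsv", sep="\t", float_format="%.8g")
    _provenance("diffexp", cfg, cfg.get("seed", 0), outdir / "de_results.prov.json")
    return {"de": outdir / "de_results.tsv"}


def stage_enrich(de_path, gmt_path, outdir, cfg: dict) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _require(de_path, "diffexp")
    _require(gmt_path, "simulate-sc")
    de = pd.read_csv(de_path, sep="\t", index_col=0)
    sets = read_gmt(gmt_path)
    background = list(de.index[de["base_mean"] > 0])
    up_a = list(de.index[de["direction"] == "up_in_A"])
    up_b = list(de.index[de["direction"] == "up_in_B"])
    hits = up_a + up_b
    res = overrepresentation(hits, background, sets, fdr_threshold=cfg["enrich"]["fdr"])
    res = attach_direction(res, sets, up_a, up_b)
    t = res.table.copy()
    t.index.name = "term"
    t.to_csv(outdir / "enrichment.tsv", sep="\t", float_format="%.8g")
    _provenance("enrich", cfg, cfg.get("seed", 0), outdir / "enrichment.prov.json")
    return {"enrichment": outdir / "enrichment.tsv"}


def stage_network(expression_path, tf_list_path, outdir, cfg: dict, seeds=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _require(expression_path, "simulate-grn")
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    tfs = read_gene_list(tf_list_path) if Path(tf_list_path).exists() else list(expr.index)
    expr = expr.loc[[g for g in expr.index if g in set(tfs)]]
    n = cfg["network"]
    mi = mutual_information(expr, n_bins=n["n_bins"])
    scores = clr(mi)
    imp = tree_importances(expr, n_trees=n["n_trees"], k_features=n["k_features"],
                           seed=int(cfg.get("seed", 0)))
    edges = combine(scores, imp)
    edges.to_tsv(outdir / "ranked_edges.tsv")
    export_network(edges, outdir / "network.graphml", fmt="graphml")
    export_network(edges, outdir / "network.sif", fmt="sif")
    seeds = seeds or n.get("seeds") or []
    result = {"edges": outdir / "ranked_edges.tsv"}
    if seeds:
        sub = seed_subnetwork(edges, seeds, top_n=n["top_n"])
        sub.tallies.to_csv(outdir / "seed_tallies.tsv", sep="\t", float_format="%.8g")
        sub.edges.to_csv(outdir / "seed_subnetwork.tsv", sep="\t", index=False,
                         float_format="%.10g")
        export_network(sub, outdir / "seed_subnetwork.graphml", fmt="graphml")
        result["subnetwork"] = outdir / "seed_subnetwork.tsv"
    _provenance("network", cfg, cfg.get("seed", 0), outdir / "ranked_edges.prov.json")
    return result


def stage_report(outdir, cfg: dict, genes=()) -> dict:
    """Static report: embedding coloured by cluster and requested genes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    emb_path = outdir / "embedding_clusters.tsv"
    _require(emb_path, "cluster")
    emb = pd.read_csv(emb_path, sep="\t", index_col=0)
    nm_path = outdir / "normalized.tsv"
    fig, ax = plt.subplots(figsize=(5, 4))
    for cl, grp in emb.groupby("cluster"):
        ax.scatter(grp["x"], grp["y"], s=12, label=f"cluster {cl}")
    ax.legend(frameon=False)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(outdir / "embedding.png", dpi=120)
    plt.close(fig)

    html = ["<html><body><h1>Pipeline report</h1>",
            f"<p>{len(emb)} cells, {emb['cluster'].nunique()} clusters, "
            f"KL divergence {emb['kl'].iloc[0]:.4f}</p>",
            '<img src="embedding.png" width="480">']
    if nm_path.exists() and genes:
        nm = NormalizedMatrix.from_tsv(nm_path, log_scale=True)
        for g in genes:
            if g in nm.genes:
                fig, ax = plt.subplots(figsize=(5, 4))
                v = nm.values.loc[g, emb.index]
                sc = ax.scatter(emb["x"], emb["y"], c=v, s=12, cmap="viridis")
                fig.colorbar(sc, label=f"log2 expression {g}")
                fig.tight_layout()
                fig.savefig(outdir / f"embedding_{g}.png", dpi=120)
                plt.close(fig)
                html.append(f"<h2>{g}</h2><img src='embedding_{g}.png' width='480'>")
    html.append("</body></html>")
    (outdir / "report.html").write_text("\n".join(html))
    return {"report": outdir / "report.html"}


def run_all(outdir, cfg: dict) -> dict:
    """simulate (if needed) -> qc -> cluster -> diffexp -> enrich -> network."""
    outdir = Path(outdir)
    produced = {}
    if not (outdir / "sc_counts.tsv").exists():
        produced.update(stage_simulate_sc(outdir, cfg))
    if not (outdir / "grn_expression.tsv").exists():
        produced.update(stage_simulate_grn(outdir, cfg))
    produced.update(stage_qc(outdir / "sc_counts.tsv", outdir / "sc_metadata.tsv", outdir, cfg))
    produced.update(stage_cluster(outdir / "normalized.tsv", outdir / "filtered_metadata.tsv", outdir, cfg))
    produced.update(stage_diffexp(outdir / "filtered_counts.tsv", outdir / "filtered_metadata.tsv",
                                  outdir / "embedding_clusters.tsv", outdir, cfg))
    produced.update(stage_enrich(outdir / "de_results.tsv", outdir / "gene_sets.gmt", outdir, cfg))
    seeds = read_gene_list(outdir / "grn_seeds.txt") if (outdir / "grn_seeds.txt").exists() else None
    produced.update(stage_network(outdir / "grn_expression.tsv", outdir / "tf_list.txt",
                                  outdir, cfg, seeds=seeds))
    return produced
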