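#!/usr/bin/env python
"""Cell/gene QC, normalisation, embedding and clustering.

Filters the simulated cells with the scaled QC thresholds, produces the
CPM -> gene-filter -> log2 -> batch-corrected matrix, then PCA, a seeded
t-SNE sweep selected by KL divergence, and PAM clustering.  Reports how the
clusters line up with the generator's true population labels.
"""

import argparse
import json
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from epinet.pipeline import load_config, stage_cluster, stage_qc

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--datadir", type=Path, default=Path("results/data"))
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

cfg = load_config(overrides={"seed": args.seed})
qc_out = stage_qc(args.datadir / "sc_counts.tsv", args.datadir / "sc_metadata.tsv",
                  args.outdir, cfg)
summary = json.loads((args.outdir / "qc_summary.json").read_text())
print(f"QC: kept {summary['n_kept']}/{summary['n_input']} cells "
      f"(removed per rule: {summary['removed_per_rule']})")

clu = stage_cluster(qc_out["normalized"], qc_out["filtered_metadata"],
                    args.outdir, cfg)
emb = pd.read_csv(clu["embedding"], sep="\t", index_col=0)
md = pd.read_csv(qc_out["filtered_metadata"], sep="\t", index_col=0)
truth = md.loc[emb.index, "true_label"]
ari = adjusted_rand_score(truth[truth != "mitotic"],
                          emb.loc[truth != "mitotic", "cluster"])
pca_var = pd.read_csv(args.outdir / "pca_variance.tsv", sep="\t")

print(f"t-SNE best KL divergence: {emb['kl'].iloc[0]:.4f}")
print(f"PC1/PC2 variance fractions: {pca_var['fraction'][0]:.3f} / "
      f"{pca_var['fraction'][1]:.3f}; {clu['n90']} components absorb 90%")
print(f"PAM clusters vs true populations (mitotic cells set aside): ARI {ari:.3f}")
print(pd.crosstab(emb["cluster"], truth).to_string())
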