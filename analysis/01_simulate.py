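#!/usr/bin/env python
"""Generate the study's synthetic datasets.

Writes a single-cell count matrix (two populations with anti-correlated
marker programs, a mitotic subset, two culture batches, ERCC spike-ins and
dropout zeros) and a bulk TF expression matrix generated from a known
directed network with a hub ("master") regulator, plus all ground truth,
under results/data/.
"""

import argparse
from pathlib import Path

from epinet.pipeline import load_config, stage_simulate_grn, stage_simulate_sc
from epinet.simulate import GRNSimConfig, SCSimConfig

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--outdir", type=Path, default=Path("results/data"))
args = ap.parse_args()

cfg = load_config(overrides={"seed": args.seed})
sc = SCSimConfig(seed=args.seed)
out1 = stage_simulate_sc(args.outdir, cfg, sc)
out2 = stage_simulate_grn(args.outdir, cfg, GRNSimConfig(seed=args.seed))

print(f"single-cell: {sc.n_cells} cells ({sc.n_cells_popA} popA, "
      f"{sc.n_cells_popB} popB, {sc.n_mitotic} mitotic) x {sc.n_genes} genes "
      f"+ {sc.n_ercc} ERCC rows -> {out1['counts']}")
print(f"bulk GRN: 60 TFs x 24 samples over 4 stages -> {out2['expression']}")
print(f"ground truth: {out2['truth']}")
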