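# epinet

Single-cell transcriptomic QC/clustering and directed transcription-factor
network inference for studying heterogeneity in stem-cell-derived
epicardium — as a tested, reusable pipeline with synthetic-data generators
that make every stage verifiable offline.

Human pluripotent-stem-cell-derived epicardial cultures (hPSC-epi) are not
homogeneous: subpopulations marked by the transcription factors BNC1 and
TCF21 express anti-correlated gene programs, and the regulatory wiring
around BNC1/TCF21/WT1 behaves like a directed network with a "master"
regulator at the top.  This package implements the computational route to
those observations, from a raw gene-by-sample count matrix to a ranked
directed TF network:

1. **QC** — plate-based cell filters (ERCC spike-in fraction, reads in
   genes, detected genes, depth), CPM library-size correction, gene
   filters, shifted-log transform, empirical-Bayes (ComBat-style) batch
   correction.
2. **Embedding & clustering** — PCA with variance-absorption accounting, a
   seeded t-SNE sweep selected by Kullback–Leibler divergence, and PAM
   (partitioning around medoids) clustering; marker correlation-of-
   correlations and expression-overlap counting.
3. **Differential expression & enrichment** — a negative-binomial Wald test
   (median-of-ratios size factors, moment dispersion), Benjamini–Hochberg
   control, hypergeometric gene-set over-representation, and the
   directional term score z = (n_upA − n_upB)/√(n_upA + n_upB).
4. **Network inference** — the core: pairwise mutual information on
   equal-frequency bins with CLR background correction
   (z_i(j) = max(0, (MI_ij − μ_i)/σ_i), score = √(z_i² + z_j²); undirected,
   mirrored), intersected with per-target random-forest importances
   (directed); edges survive only with both scores positive and are ranked
   by their product.  Seed subnetworks keep each seed's top-100 incident
   edges; the share of edges pointing *away* from a seed (its outgoing
   fraction) is the master-regulator signal.
5. **Synthetic data** — generators for single-cell counts (two marker
   programs, mitotic subset, batches, ERCC rows, dropout, plantable QC
   violators) and bulk TF expression from a known hub-topped DAG via a
   linear-Gaussian structural model, with full ground truth.

## Worked example

The whole pipeline on synthetic data, one command:

```bash
epinet all --outdir demo --seed 0
```

or stage by stage through the numbered analysis scripts:

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_qc_cluster.py --seed 0
python analysis/03_diffexp_enrichment.py --seed 0
python analysis/04_network_inference.py --seed 0
python analysis/05_recovery_benchmarks.py --seed 0
```

which prints, at seed 0:

```
single-cell: 232 cells (146 popA, 62 popB, 24 mitotic) x 2000 genes + 20 ERCC rows
QC: kept 232/232 cells
t-SNE best KL divergence: 1.2123
PC1/PC2 variance fractions: 0.022 / 0.008; 185 components absorb 90%
PAM clusters vs true populations (mitotic cells set aside): ARI 0.942
DE genes at adjusted p < 0.01: 503 (252 up in the larger cluster, 251 in the smaller)
enrichment: program_popA z = +15.81, program_popB z = −15.81, program_mitosis ns
2252 directed edges survive the CLR x tree intersection
undirected AUPR 0.200 vs density baseline 0.072 (2.8x random)
```

Reading this: the embedding is high-dimensional and weakly structured (the
leading principal component absorbs only ~2% of variance, ~185 components
are needed for 90% — the same character as real single-cell data), yet PAM
on the t-SNE embedding recovers the two simulated populations almost
perfectly (adjusted Rand 0.94).  Differential expression between the two
clusters finds the planted programs, and the directional z-score assigns
each program to its population at the extremes of the scale.  On the bulk
side, the combined CLR × tree ranking concentrates the true regulatory
edges ~3–4× better than chance.

Every stage is also a library call (`epinet.filter_cells`, `epinet.cpm`,
`epinet.tsne_sweep`, `epinet.pam`, `epinet.de_test`,
`epinet.overrepresentation`, `epinet.mutual_information`, `epinet.clr`,
`epinet.tree_importances`, `epinet.combine`, `epinet.seed_subnetwork`, ...)
operating on plain pandas structures, with TSV/MatrixMarket/GMT/GraphML IO.

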