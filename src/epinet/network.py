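"""Directed TF-TF network inference by combining two complementary methods.

The first method scores association by mutual information with a background
correction in the style of the context likelihood of relatedness (CLR): each
pair's MI is z-scored against both genes' MI distributions and the two
rectified z-scores are combined as sqrt(z_i^2 + z_j^2).  MI is estimated by
the plug-in estimator on equal-frequency bins, which makes the whole score
invariant to any strictly monotone transform of each gene's expression.  CLR
edges are undirected; they are mirrored into both directions with the same
score.

The second method is tree-ensemble regression: for every target TF a random
forest is fit on all other TFs, and a regulator's importance for the target
is its (normalised) share of the ensemble's variance reduction.  These edges
are directed.

The combination keeps a directed edge only when BOTH methods support it
(CLR score > 0 and tree importance > 0) and ranks the survivors by the
product of the two scores, so an edge needs either an extreme score with one
method or consistent support from both.  Seed subnetworks keep each seed
gene's top-N incident edges; the share of a seed's edges that point away
from it (its outgoing fraction) is the operational master-regulator signal.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "mutual_information",
    "clr",
    "tree_importances",
    "combine",
    "RankedEdgeList",
    "SeedSubnetwork",
    "seed_subnetwork",
    "directionality_stats",
    "export_network",
    "import_graphml",
]


# ------------------------------------------------------------------- MI -----

def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign ranks to bins of (near-)equal occupancy; stable under ties."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())


def mutual_information(expr: pd.DataFrame, n_bins: int | None = None) -> pd.DataFrame:
    """Pairwise plug-in MI (nats) on equal-frequency bins; genes x genes, symmetric.

    ``expr`` is genes x samples.  ``n_bins`` defaults to ceil(sqrt(n_samples)).
    Constant genes get MI 0 against everything, with a warning.
    """
    n_samples = expr.shape[1]
    if n_samples < 8:
        raise ValueError("mutual information needs at least 8 samples")
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(n_samples)))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    genes = list(expr.index)
    X = expr.values.astype(float)
    constant = X.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s); their MI is set to 0"
        )
    bins = np.vstack([_equal_frequency_bins(X[i], n_bins) for i in range(len(genes))])

    m = len(genes)
    out = np.zeros((m, m))
    for i in range(m):
        if constant[i]:
            continue
        for j in range(i + 1, m):
            if constant[j]:
                continue
            out[i, j] = out[j, i] = _mi_from_bins(bins[i], bins[j], n_bins)
    return pd.DataFrame(out, index=genes, columns=genes)


def clr(mi: pd.DataFrame) -> pd.DataFrame:
    """Background-corrected association scores from an MI matrix.

    z_i(j) = max(0, (MI_ij - mean_i)/sd_i) over gene i's off-diagonal MI
    values; score_ij = sqrt(z_i(j)^2 + z_j(i)^2).  A gene whose MI background
    has zero spread contributes z = 0.
    """
    M = mi.values.astype(float)
    m = M.shape[0]
    if not np.allclose(M, M.T):
        raise ValueError("MI matrix must be symmetric")
    off = ~np.eye(m, dtype=bool)
    means = np.array([M[i, off[i]].mean() for i in range(m)])
    sds = np.array([M[i, off[i]].std(ddof=0) for i in range(m)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (M - means[:, None]) / sds[:, None]
    z[sds == 0, :] = 0.0
    z = np.maximum(z, 0.0)
    np.fill_diagonal(z, 0.0)
    score = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(score, 0.0)
    return pd.DataFrame(score, index=mi.index, columns=mi.columns)


# ---------------------------------------------------------- tree ensemble ---

def _target_seed(master_seed: int, target: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{target}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def tree_importances(
    expr: pd.DataFrame,
    regulators=None,
    n_trees: int = 1000,
    k_features="sqrt",
    seed: int = 0,
) -> pd.DataFrame:
    """Directed regulator-importance matrix from per-target random forests.

    For every target gene an ensemble of ``n_trees`` regression trees is fit
    on all other regulators (``k_features`` candidates per split, "sqrt" by
    default); importance[r, t] is r's normalised variance-reduction share.
    Regulator columns are sorted by name internally and each target draws an
    independent seed from (master seed, target name), so results do not
    depend on the order genes arrive in.  A constant target yields a zero
    importance column.
    """
    genes = list(expr.index)
    regulators = sorted(regulators) if regulators is not None else sorted(genes)
    missing = [r for r in regulators if r not in expr.index]
    if missing:
        raise ValueError(f"regulators absent from expression: {missing[:5]}")
    if len(regulators) < 2:
        raise ValueError("need at least 2 regulators")

    imp = pd.DataFrame(0.0, index=regulators, columns=genes)
    Xall = expr.T  # samples x genes
    for target in sorted(genes):
        feats = [r for r in regulators if r != target]
        y = Xall[target].values
        if np.std(y) == 0:
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=k_features,
            random_state=_target_seed(seed, target),
            n_jobs=1,
        )
        rf.fit(Xall[feats].values, y)
        imp.loc[feats, target] = rf.feature_importances_
    common = [g for g in regulators if g in imp.columns]
    # a gene never predicts itself
    for g in common:
        imp.loc[g, g] = 0.0
    return imp


# ------------------------------------------------------------ combination ---

@dataclass
class RankedEdgeList:
    """Directed edges surviving the CLR x tree-ensemble intersection.

    ``edges`` columns: source, target, clr_score, tree_score, combined, rank —
    sorted by combined descending, ties broken lexicographically by
    (source, target); ranks are 1-based and unique.
    """

    edges: pd.DataFrame

    def __len__(self) -> int:
        return len(self.edges)

    def incident(self, gene: str) -> pd.DataFrame:
        e = self.edges
        return e[(e["source"] == gene) | (e["target"] == gene)]

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "RankedEdgeList":
        return cls(pd.read_csv(path, sep="\t"))


def combine(clr_scores: pd.DataFrame, importances: pd.DataFrame) -> RankedEdgeList:
    """Intersect mirrored CLR edges with positive tree-ensemble edges.

    A directed edge (r, t) survives iff clr_score(r, t) > 0 AND
    importance[r, t] > 0; its combined score is the product.
    """
    genes = sorted(clr_scores.index)
    if sorted(importances.index) != genes or sorted(importances.columns) != genes:
        raise ValueError("CLR and importance matrices must cover the same genes")
    C = clr_scores.loc[genes, genes].values
    I = importances.loc[genes, genes].values
    rows = []
    for i, r in enumerate(genes):
        for j, t in enumerate(genes):
            if i == j:
                continue
            c, w = C[i, j], I[i, j]
            if c > 0 and w > 0:
                rows.append((r, t, c, w, c * w))
    df = pd.DataFrame(rows, columns=["source", "target", "clr_score", "tree_score", "combined"])
    df = df.sort_values(
        ["combined", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedEdgeList(df)


# --------------------------------------------------------- seed networks ----

@dataclass
class SeedSubnetwork:
    seeds: list
    edges: pd.DataFrame                  # union of per-seed retained edges
    per_seed_edges: dict                 # seed -> DataFrame of its retained edges
    tallies: pd.DataFrame                # seed, n_outgoing, n_incoming, outgoing_fraction
    shared_interactors: dict             # frozenset of seeds -> count

    def neighbours(self, seed: str) -> set:
        e = self.per_seed_edges.get(seed)
        if e is None or e.empty:
            return set()
        return set(e["source"]).union(e["target"]) - {seed}


def seed_subnetwork(edges: RankedEdgeList, seeds, top_n: int = 100,
                    min_combined: float | None = None) -> SeedSubnetwork:
    """First-neighbour subnetwork around seed genes.

    For each seed, its ``top_n`` highest-ranked incident edges (either
    direction) are retained; an optional absolute combined-score threshold is
    applied first.  The union over seeds forms the subnetwork.  Shared
    interactors are intersections of the seeds' neighbour sets (for every
    pair and for the full seed set).
    """
    seeds = list(seeds)
    df = edges.edges
    if min_combined is not None:
        df = df[df["combined"] >= min_combined]
    present = set(df["source"]).union(df["target"])

    per_seed = {}
    rows = []
    for s in seeds:
        if s not in present:
            warnings.warn(f"seed {s!r} absent from the edge list; empty entry")
            per_seed[s] = df.iloc[0:0]
            rows.append((s, 0, 0, np.nan))
            continue
        inc = df[(df["source"] == s) | (df["target"] == s)]
        inc = inc.sort_values("rank").head(top_n)
        per_seed[s] = inc.reset_index(drop=True)
        n_out = int((inc["source"] == s).sum())
        n_in = int((inc["target"] == s).sum())
        frac = n_out / (n_out + n_in) if (n_out + n_in) else np.nan
        rows.append((s, n_out, n_in, frac))

    union = (
        pd.concat([per_seed[s] for s in seeds], ignore_index=True)
        .drop_duplicates(subset=["source", "target"])
        .sort_values("rank")
        .reset_index(drop=True)
        if seeds else df.iloc[0:0]
    )
    tallies = pd.DataFrame(
        rows, columns=["seed", "n_outgoing", "n_incoming", "outgoing_fraction"]
    ).set_index("seed")

    sub = SeedSubnetwork(
        seeds=seeds, edges=union, per_seed_edges=per_seed, tallies=tallies,
        shared_interactors={},
    )
    shared = {}
    import itertools
    for a, b in itertools.combinations(seeds, 2):
        shared[frozenset((a, b))] = len(sub.neighbours(a) & sub.neighbours(b))
    if len(seeds) > 2:
        inter = sub.neighbours(seeds[0])
        for s in seeds[1:]:
            inter &= sub.neighbours(s)
        shared[frozenset(seeds)] = len(inter)
    sub.shared_interactors = shared
    return sub


def directionality_stats(sub: SeedSubnetwork, seed: str, top_k: int | None = None):
    """(n_outgoing, n_incoming, outgoing_fraction) for a seed's retained edges.

    ``top_k`` optionally restricts to the seed's strongest edges by rank.
    An empty edge set yields fraction ``None``.
    """
    e = sub.per_seed_edges.get(seed)
    if e is None:
        raise KeyError(f"{seed!r} is not a seed of this subnetwork")
    if top_k is not None:
        e = e.sort_values("rank").head(top_k)
    n_out = int((e["source"] == seed).sum())
    n_in = int((e["target"] == seed).sum())
    frac = n_out / (n_out + n_in) if (n_out + n_in) else None
    return n_out, n_in, frac


# ---------------------------------------------------------------- export ----

def _to_graph(obj, seeds=(), node_attrs: dict | None = None) -> nx.DiGraph:
    df = obj.edges if isinstance(obj, (RankedEdgeList, SeedSubnetwork)) else obj
    g = nx.DiGraph()
    for _, row in df.iterrows():
        g.add_edge(
            row["source"], row["target"],
            clr=float(row["clr_score"]), tree=float(row["tree_score"]),
            combined=float(row["combined"]), rank=int(row["rank"]),
        )
    seeds = set(seeds) | (set(obj.seeds) if isinstance(obj, SeedSubnetwork) else set())
    for n in g.nodes:
        g.nodes[n]["is_seed"] = n in seeds
        if node_attrs and n in node_attrs:
            g.nodes[n]["relative_expression"] = float(node_attrs[n])
    return g


def export_network(obj, path, fmt: str = "graphml", seeds=(), node_attrs=None) -> None:
    """Write a ranked edge list or seed subnetwork as GraphML, SIF or TSV."""
    if fmt == "graphml":
        nx.write_graphml(_to_graph(obj, seeds, node_attrs), path)
    elif fmt == "sif":
        df = obj.edges if isinstance(obj, (RankedEdgeList, SeedSubnetwork)) else obj
        with open(path, "w") as fh:
            for _, row in df.iterrows():
                fh.write(f"{row['source']}\tregulates\t{row['target']}\n")
    elif fmt == "tsv":
        df = obj.edges if isinstance(obj, (RankedEdgeList, SeedSubnetwork)) else obj
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown format {fmt!r}; use graphml, sif or tsv")


def import_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(path)
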