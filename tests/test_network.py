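"""Mutual information, CLR scoring, tree importances, edge combination,
seed subnetworks and network export."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from epinet.network import (
    RankedEdgeList,
    clr,
    combine,
    directionality_stats,
    export_network,
    import_graphml,
    mutual_information,
    seed_subnetwork,
    tree_importances,
)


def _expr(X, genes=None):
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    return pd.DataFrame(X, index=genes,
                        columns=[f"s{j}" for j in range(X.shape[1])])


class TestMutualInformation:
    def test_identical_pair_gives_log_nbins(self, rng):
        x = rng.normal(size=16)
        mi = mutual_information(_expr(np.vstack([x, x])), n_bins=4)
        assert mi.iloc[0, 1] == pytest.approx(math.log(4), abs=1e-12)

    def test_independent_uniform_pair_near_zero(self, rng):
        X = rng.uniform(size=(2, 1000))
        mi = mutual_information(_expr(X), n_bins=4)
        assert mi.iloc[0, 1] < 0.05

    def test_matches_joint_histogram_brute_force(self, rng):
        """Bit-for-bit oracle: MI recomputed from the raw joint histogram of
        the equal-frequency bin assignments on a 12-sample toy."""
        X = rng.normal(size=(4, 12))
        n_bins = 3
        mi = mutual_information(_expr(X), n_bins=n_bins)

        def bins_of(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v), dtype=int)
            r[order] = np.arange(len(v))
            return (r * n_bins) // len(v)

        for i, j in itertools.combinations(range(4), 2):
            bi, bj = bins_of(X[i]), bins_of(X[j])
            total = 0.0
            n = len(bi)
            for a in range(n_bins):
                for b in range(n_bins):
                    pxy = np.mean((bi == a) & (bj == b))
                    if pxy > 0:
                        px, py = np.mean(bi == a), np.mean(bj == b)
                        total += pxy * math.log(pxy / (px * py))
            assert mi.iloc[i, j] == pytest.approx(total, abs=1e-12)

    def test_symmetric_and_nonnegative(self, rng):
        mi = mutual_information(_expr(rng.normal(size=(5, 40))))
        assert np.allclose(mi.values, mi.values.T)
        assert (mi.values >= 0).all()

    def test_constant_gene_zeroed_with_warning(self, rng):
        X = np.vstack([np.full(20, 2.0), rng.normal(size=20)])
        with pytest.warns(UserWarning, match="constant"):
            mi = mutual_information(_expr(X), n_bins=4)
        assert (mi.iloc[0] == 0).all()

    def test_invariant_under_monotone_transforms(self, rng):
        """Equal-frequency binning makes MI invariant to strictly monotone
        per-gene transforms."""
        X = rng.normal(size=(4, 32))
        mi1 = mutual_information(_expr(X), n_bins=4)
        Y = np.vstack([np.exp(X[0]), X[1] ** 3, 5 * X[2] - 1, np.tanh(X[3])])
        mi2 = mutual_information(_expr(Y), n_bins=4)
        assert np.allclose(mi1.values, mi2.values)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="8 samples"):
            mutual_information(_expr(rng.normal(size=(3, 6))))


class TestCLR:
    def test_uniform_mi_gives_zero_scores(self):
        M = pd.DataFrame(np.full((4, 4), 0.3) - 0.3 * np.eye(4))
        M.values[np.diag_indices(4)] = 0
        out = clr(M)
        assert np.allclose(out.values, 0.0)

    def test_matches_hand_computation_on_4_gene_matrix(self):
        """Spreadsheet-style oracle: z-scores and the quadrature combination
        recomputed by hand loops."""
        vals = np.array([
            [0.0, 0.9, 0.2, 0.1],
            [0.9, 0.0, 0.4, 0.3],
            [0.2, 0.4, 0.0, 0.6],
            [0.1, 0.3, 0.6, 0.0],
        ])
        M = pd.DataFrame(vals, index=list("abcd"), columns=list("abcd"))
        out = clr(M)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                row_i = [vals[i, k] for k in range(4) if k != i]
                row_j = [vals[j, k] for k in range(4) if k != j]
                zi = max(0.0, (vals[i, j] - np.mean(row_i)) / np.std(row_i))
                zj = max(0.0, (vals[j, i] - np.mean(row_j)) / np.std(row_j))
                assert out.iloc[i, j] == pytest.approx(
                    math.sqrt(zi ** 2 + zj ** 2), abs=1e-10)

    def test_symmetric_output(self, rng):
        A = rng.uniform(size=(6, 6))
        M = pd.DataFrame((A + A.T) / 2)
        M.values[np.diag_indices(6)] = 0
        out = clr(M)
        assert np.allclose(out.values, out.values.T)

    def test_zero_spread_gene_contributes_zero_z(self):
        M = pd.DataFrame([
            [0.0, 0.5, 0.5],
            [0.5, 0.0, 0.9],
            [0.5, 0.9, 0.0],
        ])
        out = clr(M)    # gene 0's background has zero sd
        assert np.isfinite(out.values).all()

    def test_asymmetric_input_rejected(self):
        M = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            clr(M)


class TestTreeImportances:
    def test_copied_regulator_dominates(self, rng):
        X = rng.normal(size=(11, 200))
        X[10] = X[0]          # target g10 copies regulator g0
        expr = _expr(X)
        imp = tree_importances(expr, regulators=[f"g{i}" for i in range(10)],
                               n_trees=50, seed=1)
        assert imp["g10"].idxmax() == "g0"
        assert imp.loc["g0", "g10"] > 0.5

    def test_constant_target_zero_importances(self, rng):
        X = rng.normal(size=(4, 50))
        X[3] = 1.0
        imp = tree_importances(_expr(X), n_trees=20, seed=0)
        assert (imp["g3"] == 0).all()

    def test_diagonal_zero(self, rng):
        imp = tree_importances(_expr(rng.normal(size=(5, 30))), n_trees=20, seed=0)
        assert (np.diag(imp.loc[imp.columns, imp.columns].values) == 0).all()

    def test_invariant_to_gene_order(self, rng):
        X = rng.normal(size=(6, 40))
        expr = _expr(X)
        perm = expr.iloc[[3, 1, 5, 0, 4, 2]]
        a = tree_importances(expr, n_trees=30, seed=7)
        b = tree_importances(perm, n_trees=30, seed=7)
        b = b.loc[a.index, a.columns]
        assert np.allclose(a.values, b.values)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(5, 30))
        a = tree_importances(_expr(X), n_trees=25, seed=3)
        b = tree_importances(_expr(X), n_trees=25, seed=3)
        assert (a.values == b.values).all()

    def test_fewer_than_two_regulators_rejected(self, rng):
        with pytest.raises(ValueError, match="2 regulators"):
            tree_importances(_expr(rng.normal(size=(3, 20))), regulators=["g0"])


def _toy_pair():
    genes = ["A", "B"]
    C = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=genes, columns=genes)
    I = pd.DataFrame([[0.0, 0.5], [0.1, 0.0]], index=genes, columns=genes)
    return C, I


class TestCombine:
    def test_hand_toy_products_and_ranks(self):
        C, I = _toy_pair()
        edges = combine(C, I).edges
        assert len(edges) == 2
        first, second = edges.iloc[0], edges.iloc[1]
        assert (first["source"], first["target"]) == ("A", "B")
        assert first["combined"] == pytest.approx(1.0)
        assert second["combined"] == pytest.approx(0.2)
        assert list(edges["rank"]) == [1, 2]

    def test_zero_clr_edge_absent_despite_tree_score(self):
        C, I = _toy_pair()
        C.loc["A", "B"] = C.loc["B", "A"] = 0.0
        assert len(combine(C, I)) == 0

    def test_zero_tree_edge_absent(self):
        C, I = _toy_pair()
        I.loc["B", "A"] = 0.0
        edges = combine(C, I).edges
        assert len(edges) == 1
        assert edges.iloc[0]["source"] == "A"

    def test_gene_mismatch_rejected(self):
        C, I = _toy_pair()
        I.index = ["A", "X"]
        I.columns = ["A", "X"]
        with pytest.raises(ValueError, match="same genes"):
            combine(C, I)

    def test_output_subset_of_positive_intersection_and_monotone(self, rng):
        n = 8
        A = rng.uniform(size=(n, n))
        C = pd.DataFrame((A + A.T) / 2)
        C.values[np.diag_indices(n)] = 0
        C.values[C.values < 0.5] = 0.0
        I = pd.DataFrame(rng.uniform(size=(n, n)))
        I.values[np.diag_indices(n)] = 0
        I.values[I.values < 0.3] = 0.0
        edges = combine(C, I).edges
        for _, row in edges.iterrows():
            assert C.loc[row["source"], row["target"]] > 0
            assert I.loc[row["source"], row["target"]] > 0
            assert row["combined"] == pytest.approx(
                C.loc[row["source"], row["target"]] * I.loc[row["source"], row["target"]])
        assert (np.diff(edges["combined"].values) <= 1e-12).all()
        assert list(edges["rank"]) == list(range(1, len(edges) + 1))


def _edge_list(rows):
    df = pd.DataFrame(rows, columns=["source", "target", "clr_score",
                                     "tree_score", "combined"])
    df = df.sort_values(["combined", "source", "target"],
                        ascending=[False, True, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedEdgeList(df)


class TestSeedSubnetwork:
    EDGES = _edge_list([
        ("S1", "X", 1.0, 0.9, 0.9),
        ("X", "S1", 1.0, 0.6, 0.6),
        ("S1", "Y", 1.0, 0.5, 0.5),
        ("Z", "S1", 1.0, 0.4, 0.4),
        ("S2", "X", 1.0, 0.35, 0.35),
        ("Y", "S2", 1.0, 0.3, 0.3),
        ("W", "V", 1.0, 0.99, 0.99),
    ])

    def test_topn_large_retains_all_neighbours(self):
        sub = seed_subnetwork(self.EDGES, ["S1"], top_n=100)
        assert sub.neighbours("S1") == {"X", "Y", "Z"}
        assert len(sub.per_seed_edges["S1"]) == 4

    def test_hand_enumeration_of_two_seeds(self):
        sub = seed_subnetwork(self.EDGES, ["S1", "S2"], top_n=100)
        assert sub.neighbours("S1") == {"X", "Y", "Z"}
        assert sub.neighbours("S2") == {"X", "Y"}
        assert sub.shared_interactors[frozenset(("S1", "S2"))] == 2
        assert len(sub.edges) == 6          # W->V untouched by any seed
        t = sub.tallies
        assert t.loc["S1", "n_outgoing"] == 2 and t.loc["S1", "n_incoming"] == 2
        assert t.loc["S2", "n_outgoing"] == 1 and t.loc["S2", "n_incoming"] == 1

    def test_topn_truncates_by_rank(self):
        sub = seed_subnetwork(self.EDGES, ["S1"], top_n=2)
        assert len(sub.per_seed_edges["S1"]) == 2
        assert set(sub.per_seed_edges["S1"]["combined"]) == {0.9, 0.6}

    def test_absent_seed_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="absent"):
            sub = seed_subnetwork(self.EDGES, ["GHOST"], top_n=10)
        assert sub.neighbours("GHOST") == set()
        assert np.isnan(sub.tallies.loc["GHOST", "outgoing_fraction"])

    def test_triple_shared_interactors(self):
        edges = _edge_list([
            ("S1", "N", 1, .9, .9), ("S2", "N", 1, .8, .8), ("N", "S3", 1, .7, .7),
            ("S1", "M", 1, .6, .6), ("S2", "M", 1, .5, .5),
        ])
        sub = seed_subnetwork(edges, ["S1", "S2", "S3"], top_n=10)
        assert sub.shared_interactors[frozenset(("S1", "S2", "S3"))] == 1
        assert sub.shared_interactors[frozenset(("S1", "S2"))] == 2


class TestDirectionality:
    def test_all_outgoing_fraction_one(self):
        edges = _edge_list([("S", "X", 1, .9, .9), ("S", "Y", 1, .8, .8)])
        sub = seed_subnetwork(edges, ["S"], top_n=10)
        assert directionality_stats(sub, "S") == (2, 0, 1.0)

    def test_three_out_two_in(self):
        edges = _edge_list([
            ("S", "A", 1, .9, .9), ("S", "B", 1, .8, .8), ("S", "C", 1, .7, .7),
            ("A", "S", 1, .6, .6), ("B", "S", 1, .5, .5),
        ])
        sub = seed_subnetwork(edges, ["S"], top_n=10)
        assert directionality_stats(sub, "S") == (3, 2, 0.6)

    def test_top_k_restriction(self):
        edges = _edge_list([
            ("S", "A", 1, .9, .9), ("A", "S", 1, .8, .8), ("B", "S", 1, .7, .7),
        ])
        sub = seed_subnetwork(edges, ["S"], top_n=10)
        assert directionality_stats(sub, "S", top_k=2) == (1, 1, 0.5)

    def test_empty_edge_set_fraction_absent(self):
        edges = _edge_list([("W", "V", 1, .9, .9)])
        with pytest.warns(UserWarning):
            sub = seed_subnetwork(edges, ["S"], top_n=10)
        n_out, n_in, frac = directionality_stats(sub, "S")
        assert (n_out, n_in, frac) == (0, 0, None)

    def test_unknown_seed_rejected(self):
        sub = seed_subnetwork(_edge_list([("A", "B", 1, .9, .9)]), ["A"], top_n=5)
        with pytest.raises(KeyError):
            directionality_stats(sub, "B")


class TestExport:
    def test_graphml_roundtrip_preserves_attributes(self, tmp_path):
        edges = _edge_list([("A", "B", 2.0, 0.5, 1.0), ("B", "C", 1.5, 0.2, 0.3)])
        export_network(edges, tmp_path / "n.graphml", fmt="graphml", seeds=["A"])
        g = import_graphml(tmp_path / "n.graphml")
        assert set(g.edges) == {("A", "B"), ("B", "C")}
        assert g["A"]["B"]["clr"] == pytest.approx(2.0)
        assert g["A"]["B"]["tree"] == pytest.approx(0.5)
        assert g["A"]["B"]["combined"] == pytest.approx(1.0)
        assert g["A"]["B"]["rank"] == 1
        assert g.nodes["A"]["is_seed"] and not g.nodes["B"]["is_seed"]

    def test_empty_network_valid_document(self, tmp_path):
        empty = RankedEdgeList(pd.DataFrame(
            columns=["source", "target", "clr_score", "tree_score", "combined", "rank"]))
        export_network(empty, tmp_path / "e.graphml", fmt="graphml")
        g = import_graphml(tmp_path / "e.graphml")
        assert len(g.edges) == 0

    def test_sif_and_tsv(self, tmp_path):
        edges = _edge_list([("A", "B", 2.0, 0.5, 1.0)])
        export_network(edges, tmp_path / "n.sif", fmt="sif")
        assert (tmp_path / "n.sif").read_text() == "A\tregulates\tB\n"
        export_network(edges, tmp_path / "n.tsv", fmt="tsv")
        back = RankedEdgeList.from_tsv(tmp_path / "n.tsv")
        assert np.allclose(back.edges["combined"], edges.edges["combined"])

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            export_network(_edge_list([("A", "B", 1, 1, 1)]), tmp_path / "x", fmt="xml")
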