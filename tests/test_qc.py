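"""Cell/gene filters, CPM, log transform and batch correction."""

import numpy as np
import pandas as pd
import pytest

from epinet.containers import CountMatrix, NormalizedMatrix
from epinet.qc import (
    QCThresholds, correct_batch, cpm, filter_cells, filter_genes, log_transform,
)
from epinet.simulate import SCSimConfig, simulate_sc_counts

from conftest import make_normalized


def _matrix(counts: dict, ercc=(), total_reads=None, index=None):
    df = pd.DataFrame(counts)
    if index is not None:
        df.index = index
    is_ercc = pd.Series([g in ercc for g in df.index], index=df.index)
    md = pd.DataFrame({"batch": "b0", "stage": "st"}, index=df.columns)
    if total_reads is not None:
        md["total_reads"] = total_reads
    return CountMatrix(counts=df, is_ercc=is_ercc, metadata=md)


class TestFilterCells:
    def test_defaults_are_the_standard_thresholds(self):
        t = QCThresholds()
        assert (t.ercc_frac_max, t.min_frac_in_genes, t.min_genes_detected_frac,
                t.min_reads, t.min_genes_detected) == (0.97, 0.80, 0.02, 500_000, 7000)

    def test_all_passing_matrix_is_identity(self):
        cfg = SCSimConfig(n_cells_popA=20, n_cells_popB=10, n_mitotic=0,
                          n_bad_cells=0, n_genes=400, n_markers_per_pop=40,
                          n_prolif_genes=10, seed=0)
        cm, _ = simulate_sc_counts(cfg)
        kept, report = filter_cells(cm, cfg.qc_thresholds)
        assert list(kept.samples) == list(cm.samples)
        assert report.summary()["n_removed"] == 0

    def test_planted_violators_attributed_to_their_rules(self):
        """Six planted violators (two per rule class) among 60 cells are all
        removed and attributed to the class they were planted for."""
        cfg = SCSimConfig(n_cells_popA=30, n_cells_popB=24, n_mitotic=0,
                          n_bad_cells=6, seed=11)
        cm, _ = simulate_sc_counts(cfg)
        kept, report = filter_cells(cm, cfg.qc_thresholds)
        assert len(report.kept) == 54
        assert report.removed_per_rule == {
            "ercc_frac": 2, "frac_in_genes": 0, "gene_frac": 0,
            "min_reads": 2, "min_genes": 2,
        }
        planted = cm.metadata.query("true_label == 'bad'")["bad_class"]
        attributed = report.verdicts.loc[planted.index, "failed_rule"]
        assert (attributed == planted).all()

    def test_verdict_independent_of_other_samples(self):
        """Removing one cell never changes another cell's verdict."""
        cfg = SCSimConfig(n_cells_popA=20, n_cells_popB=10, n_mitotic=0,
                          n_bad_cells=3, seed=4)
        cm, _ = simulate_sc_counts(cfg)
        _, full_report = filter_cells(cm, cfg.qc_thresholds)
        some = list(cm.samples[5:])
        _, sub_report = filter_cells(cm.subset_samples(some), cfg.qc_thresholds)
        pd.testing.assert_series_equal(
            full_report.verdicts.loc[some, "passed"],
            sub_report.verdicts["passed"],
        )

    def test_no_ercc_rows_skips_rule_with_warning(self):
        m = _matrix({"s1": [100, 200], "s2": [150, 50]})
        with pytest.warns(UserWarning, match="ERCC"):
            kept, report = filter_cells(
                m, QCThresholds(min_reads=10, min_genes_detected=1))
        assert len(report.kept) == 2

    def test_frac_in_genes_rule_uses_external_total(self):
        # 100 gene reads of 1000 total -> only 10% in genes
        m = _matrix({"s1": [60, 40]}, total_reads=[1000])
        _, report = filter_cells(
            m, QCThresholds(min_reads=10, min_genes_detected=1))
        assert report.verdicts.loc["s1", "failed_rule"] == "frac_in_genes"


class TestCPM:
    def test_single_gene_full_column(self):
        m = _matrix({"s1": [10]})
        assert cpm(m).values.iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_million(self, small_counts):
        assert np.allclose(cpm(small_counts).values.sum(axis=0), 1e6)

    def test_scale_invariance_under_doubling(self, small_counts):
        doubled = CountMatrix(counts=small_counts.counts * 2,
                              is_ercc=small_counts.is_ercc,
                              metadata=small_counts.metadata)
        pd.testing.assert_frame_equal(cpm(small_counts).values, cpm(doubled).values)

    def test_matches_elementwise_oracle(self, small_counts):
        got = cpm(small_counts).values
        raw = small_counts.counts
        for g in raw.index:
            for s in raw.columns:
                assert got.loc[g, s] == pytest.approx(
                    raw.loc[g, s] / raw[s].sum() * 1e6)

    def test_ercc_rows_excluded_from_numerator_and_denominator(self):
        m = _matrix({"s1": [90, 10]}, ercc=["e1"], index=["g1", "e1"])
        out = cpm(m)
        assert list(out.genes) == ["g1"]
        assert out.values.iloc[0, 0] == pytest.approx(1e6)

    def test_zero_sum_column_rejected(self):
        m = _matrix({"s1": [0, 0]})
        with pytest.raises(ValueError, match="zero-sum"):
            cpm(m)

    def test_idempotent_on_already_normalized_columns(self):
        # a column already summing to 1e6 is left unchanged
        m = _matrix({"s1": [250_000, 750_000]})
        out = cpm(m)
        assert np.allclose(out.values["s1"], [250_000, 750_000])


class TestFilterGenes:
    def test_low_everywhere_removed(self):
        nm = make_normalized(np.full((1, 4), 0.5), log_scale=False)
        assert len(filter_genes(nm).genes) == 0

    def test_constant_high_removed(self):
        nm = make_normalized(np.full((1, 4), 100.0), log_scale=False)
        assert len(filter_genes(nm).genes) == 0

    def test_low_but_variable_kept(self):
        nm = make_normalized(np.array([[1.0, 3.0]]), log_scale=False)
        assert len(filter_genes(nm).genes) == 1

    def test_applied_twice_equals_once(self, rng):
        nm = make_normalized(rng.gamma(1.0, 5.0, size=(50, 6)), log_scale=False)
        once = filter_genes(nm)
        twice = filter_genes(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestLogTransform:
    def test_zero_maps_to_log_pseudocount(self):
        nm = make_normalized(np.zeros((1, 2)), log_scale=False)
        assert log_transform(nm, pseudo_count=1.0).values.iloc[0, 0] == 0.0
        nm2 = make_normalized(np.zeros((1, 2)), log_scale=False)
        assert log_transform(nm2, pseudo_count=0.5).values.iloc[0, 0] == -1.0

    def test_1023_with_pseudocount_1_gives_10(self):
        nm = make_normalized(np.array([[1023.0]]), log_scale=False)
        assert log_transform(nm).values.iloc[0, 0] == pytest.approx(10.0)

    def test_monotone_in_input(self, rng):
        vals = rng.gamma(2.0, 50.0, size=(30, 1))
        nm = make_normalized(vals, log_scale=False)
        out = log_transform(nm).values.values.ravel()
        assert (np.argsort(out) == np.argsort(vals.ravel())).all()


class TestBatchCorrection:
    def test_single_batch_identity(self, rng):
        nm = make_normalized(rng.normal(5, 1, size=(30, 8)), batch=["b"] * 8)
        out = correct_batch(nm)
        pd.testing.assert_frame_equal(out.values, nm.values)
        assert out.batch_corrected

    def test_pure_shifts_removed_in_no_shrinkage_limit(self, rng):
        """Per-gene batch shifts large relative to within-batch noise are
        removed to numerical precision once many genes inform the prior."""
        n_genes, per = 500, 12
        noise = rng.normal(0, 1e-3, size=(n_genes, 2 * per))
        base = rng.normal(8, 2, size=n_genes)[:, None]
        shifts = rng.normal(0, 10, size=n_genes)[:, None]
        X = base + noise
        X[:, per:] += shifts
        nm = make_normalized(X, batch=["b1"] * per + ["b2"] * per)
        out = correct_batch(nm)
        diff = (out.values.iloc[:, :per].mean(axis=1)
                - out.values.iloc[:, per:].mean(axis=1))
        assert np.abs(diff).max() < 1e-6

    def test_idempotent_within_tolerance(self, rng):
        n_genes, per = 500, 12
        X = rng.normal(0, 1e-3, size=(n_genes, 2 * per)) + rng.normal(8, 2, size=n_genes)[:, None]
        X[:, per:] += rng.normal(0, 10, size=n_genes)[:, None]
        nm = make_normalized(X, batch=["b1"] * per + ["b2"] * per)
        once = correct_batch(nm)
        twice = correct_batch(once)
        assert np.abs(twice.values.values - once.values.values).max() < 1e-3

    def test_grand_mean_preserved(self, rng):
        X = rng.normal(5, 2, size=(400, 20))
        X[:, 10:] += rng.normal(0, 1, size=400)[:, None]
        nm = make_normalized(X, batch=["b1"] * 10 + ["b2"] * 10)
        out = correct_batch(nm)
        drift = (out.values.mean(axis=1) - nm.values.mean(axis=1)).abs().max()
        assert drift < 0.05

    def test_matches_reference_combat(self, rng):
        """Independent oracle: the empirical-Bayes adjustment agrees with
        scanpy's ComBat implementation."""
        scanpy = pytest.importorskip("scanpy")
        anndata = pytest.importorskip("anndata")
        X = rng.normal(5, 2, size=(300, 24))
        X[:, 12:] += rng.normal(0, 1, size=300)[:, None]
        batch = ["b1"] * 12 + ["b2"] * 12
        nm = make_normalized(X, batch=batch)
        ours = correct_batch(nm).values.values
        A = anndata.AnnData(
            X=nm.values.T.values.copy(),
            obs=pd.DataFrame({"batch": batch}, index=nm.samples),
        )
        scanpy.pp.combat(A, key="batch")
        assert np.abs(A.X.T - ours).max() < 5e-3

    def test_single_sample_batch_rejected(self, rng):
        nm = make_normalized(rng.normal(size=(10, 3)), batch=["b1", "b1", "b2"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            correct_batch(nm)

    def test_missing_batch_labels_rejected(self, rng):
        nm = make_normalized(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="batch"):
            correct_batch(nm)
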