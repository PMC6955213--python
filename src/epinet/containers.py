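"""Core data containers and plain-text IO.

The pipeline's universal input is a gene-by-sample integer count matrix with
ERCC spike-in rows flagged and per-sample metadata (culture batch, lineage
stage, optionally the sequencer's total read count when it exceeds the reads
assigned to genes).  Downstream stages operate on :class:`NormalizedMatrix`,
a filtered log2-scale expression matrix that remembers how it was produced.

All on-disk formats are plain text: TSV (genes in rows, header = sample ids),
MatrixMarket, metadata TSV, GMT gene sets and one-id-per-line gene lists.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
]


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts with ERCC flags and sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes in rows, samples in columns.
    is_ercc
        Boolean Series indexed like ``counts.index`` flagging spike-in rows.
    metadata
        DataFrame indexed like ``counts.columns``; expected columns are
        ``batch`` and ``stage``; an optional ``total_reads`` column records
        per-sample sequencing depth (defaults to the column sum when absent).
    """

    counts: pd.DataFrame
    is_ercc: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("sample identifiers must be unique")
        self.is_ercc = self.is_ercc.reindex(self.counts.index)
        if self.is_ercc.isna().any():
            raise ValueError("is_ercc must flag every gene")
        self.is_ercc = self.is_ercc.astype(bool)
        missing = self.counts.columns.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"metadata missing for samples: {list(missing)[:5]}")
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return int((~self.is_ercc).sum())

    def total_reads(self) -> pd.Series:
        """Per-sample total reads: metadata ``total_reads`` if present, else column sums."""
        if "total_reads" in self.metadata.columns:
            tot = self.metadata["total_reads"].astype(float)
            if tot.notna().all():
                return tot
        return self.counts.sum(axis=0).astype(float)

    def ercc_reads(self) -> pd.Series:
        return self.counts.loc[self.is_ercc].sum(axis=0).astype(float)

    def gene_reads(self) -> pd.Series:
        return self.counts.loc[~self.is_ercc].sum(axis=0).astype(float)

    def detected_genes(self) -> pd.Series:
        """Number of non-ERCC genes with count > 0 per sample."""
        return (self.counts.loc[~self.is_ercc] > 0).sum(axis=0)

    def subset_samples(self, samples) -> "CountMatrix":
        samples = pd.Index(samples)
        return CountMatrix(
            counts=self.counts[samples].copy(),
            is_ercc=self.is_ercc.copy(),
            metadata=self.metadata.loc[samples].copy(),
        )

    def drop_ercc(self) -> "CountMatrix":
        keep = ~self.is_ercc
        return CountMatrix(
            counts=self.counts.loc[keep].copy(),
            is_ercc=self.is_ercc.loc[keep].copy(),
            metadata=self.metadata.copy(),
        )

    # ---------------------------------------------------------------- IO ----
    def to_tsv(self, counts_path, metadata_path=None) -> None:
        df = self.counts.copy()
        df.index.name = "gene"
        df.to_csv(counts_path, sep="\t")
        if metadata_path is not None:
            md = self.metadata.copy()
            md.index.name = "sample"
            md.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path=None, ercc_prefix="ERCC-") -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        df.columns = df.columns.astype(str)
        df.index.name = None
        is_ercc = pd.Series(
            df.index.astype(str).str.startswith(ercc_prefix), index=df.index
        )
        if metadata_path is not None:
            md = pd.read_csv(metadata_path, sep="\t", index_col=0)
            md.index = md.index.astype(str)
        else:
            md = pd.DataFrame(index=df.columns)
            md["batch"] = "batch0"
            md["stage"] = "stage0"
        return cls(counts=df, is_ercc=is_ercc, metadata=md)

    def to_mtx(self, mtx_path, genes_path, samples_path) -> None:
        scipy.io.mmwrite(str(mtx_path), scipy.sparse.csr_matrix(self.counts.values))
        Path(genes_path).write_text("".join(f"{g}\n" for g in self.counts.index))
        Path(samples_path).write_text("".join(f"{s}\n" for s in self.counts.columns))

    @classmethod
    def from_mtx(cls, mtx_path, genes_path, samples_path, metadata_path=None,
                 ercc_prefix="ERCC-") -> "CountMatrix":
        mat = scipy.io.mmread(str(mtx_path)).toarray().astype(int)
        genes = read_gene_list(genes_path)
        samples = read_gene_list(samples_path)
        df = pd.DataFrame(mat, index=genes, columns=samples)
        is_ercc = pd.Series(df.index.str.startswith(ercc_prefix), index=df.index)
        if metadata_path is not None:
            md = pd.read_csv(metadata_path, sep="\t", index_col=0)
            md.index = md.index.astype(str)
        else:
            md = pd.DataFrame({"batch": "batch0", "stage": "stage0"}, index=df.columns)
        return cls(counts=df, is_ercc=is_ercc, metadata=md)


@dataclass
class NormalizedMatrix:
    """Filtered expression matrix on a linear (CPM) or log2 scale.

    Carries provenance flags so downstream stages can assert the input they
    need: ``cpm_corrected`` after library-size correction, ``log_scale`` after
    the shifted-log transform, ``batch_corrected`` after empirical-Bayes
    batch adjustment.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    cpm_corrected: bool = False
    log_scale: bool = False
    batch_corrected: bool = False
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("normalized values must be finite")
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, **flags) -> "NormalizedMatrix":
        out = replace(self, values=values)
        for k, v in flags.items():
            setattr(out, k, v)
        return out

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, metadata_path=None, **flags) -> "NormalizedMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(str)
        if metadata_path is not None:
            md = pd.read_csv(metadata_path, sep="\t", index_col=0)
            md.index = md.index.astype(str)
            md = md.loc[df.columns]
        else:
            md = pd.DataFrame(index=df.columns)
        return cls(values=df, metadata=md, **flags)


# -------------------------------------------------------------- gene sets ----

def write_gmt(sets: dict, path) -> None:
    """Write gene sets as GMT: name <tab> description <tab> member genes.

    ``sets`` maps set name to an ordered iterable of gene ids.  Overlapping
    sets are written as-is; no deduplication across sets.
    """
    lines = []
    for name, genes in sets.items():
        if not str(name):
            raise ValueError("empty gene-set name")
        genes = list(genes)
        lines.append("\t".join([str(name), "na", *map(str, genes)]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_gmt(path) -> dict:
    """Read a GMT file into {set name: [genes]} preserving order."""
    sets: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def read_gene_list(path) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
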