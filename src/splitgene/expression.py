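"""Exon-level read counts -> per-gene, per-library normalized expression.

Counts come from HTSeq-style per-exon counting against each annotation's
representative transcripts.  Exons shorter than 50 bp are dropped (short
exons cannot be mapped reliably with 50 bp reads), each library is
TPM-normalized over all retained exons, and a gene's expression in a
library is the arithmetic mean of its exons' TPM.  A gene counts as
expressed when its mean expression over libraries is at least 0.01 TPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import Annotation

MIN_EXON_LEN = 50
EXPRESSION_FLOOR = 0.01

LIBRARY_COLUMNS = ["library_id", "genotype", "tissue", "replicate"]


def read_library_sheet(path: str) -> pd.DataFrame:
    """Read the library sheet TSV (library_id, genotype, tissue, replicate)."""
    libs = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    missing = set(LIBRARY_COLUMNS) - set(libs.columns)
    if missing:
        raise ValueError(f"library sheet {path}: missing columns {sorted(missing)}")
    dup = libs.duplicated(subset=["genotype", "tissue", "replicate"])
    if dup.any():
        raise ValueError(f"library sheet {path}: duplicate genotype/tissue/replicate rows")
    return libs.set_index("library_id", drop=False)


@dataclass
class ExonCountMatrix:
    """Per-exon read counts (rows: exons, columns: libraries) with metadata.

    ``exons`` carries one row per exon id with columns gene_id and length
    (bp); ``libraries`` is the library sheet indexed by library_id.
    """

    counts: pd.DataFrame
    exons: pd.DataFrame
    libraries: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.exons.index):
            self.exons = self.exons.loc[self.counts.index]
        if (self.exons["length"] < 1).any():
            bad = self.exons.index[self.exons["length"] < 1][:5].tolist()
            raise ValueError(f"exon lengths must be >= 1 (offending: {bad})")
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        extra = set(self.counts.columns) - set(self.libraries.index)
        if extra:
            raise ValueError(f"count columns without library metadata: {sorted(extra)}")

    @classmethod
    def from_annotation(
        cls, ann: Annotation, counts: pd.DataFrame, libraries: pd.DataFrame
    ) -> "ExonCountMatrix":
        """Build exon metadata from an annotation; count index is
        ``<gene_id>:<exon ordinal>`` over representative-transcript exons."""
        rows = []
        for chrom in sorted(ann.by_chrom):
            for gid in ann.by_chrom[chrom]:
                for i, (s, e) in enumerate(ann[gid].exons, 1):
                    rows.append((f"{gid}:{i}", gid, e - s))
        exons = pd.DataFrame(rows, columns=["exon_id", "gene_id", "length"]).set_index("exon_id")
        return cls(counts.loc[exons.index.intersection(counts.index)], exons, libraries)

    @classmethod
    def from_tsv(cls, counts_path: str, library_sheet_path: str) -> "ExonCountMatrix":
        """Read a wide matrix TSV: exon_id, gene_id, length, then one column
        per library."""
        df = pd.read_csv(counts_path, sep="\t").set_index("exon_id")
        libs = read_library_sheet(library_sheet_path)
        meta = df[["gene_id", "length"]]
        counts = df.drop(columns=["gene_id", "length"])
        return cls(counts, meta, libs)

    def to_tsv(self, path: str) -> None:
        out = pd.concat([self.exons[["gene_id", "length"]], self.counts], axis=1)
        out.to_csv(path, sep="\t", index_label="exon_id")


@dataclass
class GeneExpressionMatrix:
    """Gene x library mean-exon TPM with library metadata."""

    values: pd.DataFrame  # rows: gene_id, columns: library_id
    libraries: pd.DataFrame
    min_exon_len: int = MIN_EXON_LEN
    expression_floor: float = EXPRESSION_FLOOR

    def select_genotype(self, genotype: str) -> list[str]:
        """Library ids belonging to one genotype, in sheet order."""
        sel = self.libraries[self.libraries["genotype"] == genotype]
        return [l for l in sel["library_id"] if l in self.values.columns]

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def filter_short_exons(m: ExonCountMatrix, min_len: int = MIN_EXON_LEN) -> ExonCountMatrix:
    """Drop exons shorter than ``min_len`` bp (strict: length 50 is kept)."""
    keep = m.exons["length"] >= min_len
    return ExonCountMatrix(m.counts.loc[keep.values], m.exons.loc[keep.values], m.libraries)


def tpm(m: ExonCountMatrix) -> pd.DataFrame:
    """Per-exon TPM per library: length-normalized rates scaled to sum 1e6.

    A library with zero total counts yields all-zero TPM rather than NaN.
    """
    lengths = m.exons["length"].to_numpy(dtype=float)
    rates = m.counts.to_numpy(dtype=float) / lengths[:, None]
    totals = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, rates / totals * 1e6, 0.0)
    return pd.DataFrame(scaled, index=m.counts.index, columns=m.counts.columns)


def gene_expression(
    tpm_matrix: pd.DataFrame, exon_meta: pd.DataFrame, libraries: pd.DataFrame
) -> GeneExpressionMatrix:
    """Average each gene's retained exon TPMs per library.

    Genes whose exons were all length-filtered simply have no row: they are
    missing and excluded downstream.
    """
    gene_ids = exon_meta.loc[tpm_matrix.index, "gene_id"]
    values = tpm_matrix.groupby(gene_ids.values).mean()
    values.index.name = "gene_id"
    return GeneExpressionMatrix(values=values, libraries=libraries)


def expressed_genes(
    g: GeneExpressionMatrix,
    floor: float = EXPRESSION_FLOOR,
    libraries: list[str] | None = None,
) -> set[str]:
    """Genes whose mean expression over the selected libraries is >= floor.

    The floor is strict on the low side: a mean of exactly ``floor`` counts
    as expressed ("less than 0.01" is filtered).
    """
    vals = g.values if libraries is None else g.values[libraries]
    means = vals.mean(axis=1)
    return set(means.index[means >= floor])


def gene_expression_from_counts(
    m: ExonCountMatrix, min_exon_len: int = MIN_EXON_LEN
) -> tuple[GeneExpressionMatrix, pd.DataFrame]:
    """Convenience: filter short exons, TPM-normalize, aggregate to genes.

    Returns the gene matrix and the per-exon TPM matrix (the latter is
    reused by the split-null simulation, which averages exon TPMs over
    each artificial half-gene).
    """
    filtered = filter_short_exons(m, min_exon_len)
    exon_tpm = tpm(filtered)
    gem = gene_expression(exon_tpm, filtered.exons, filtered.libraries)
    gem.min_exon_len = min_exon_len
    return gem, exon_tpm
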