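"""Parsing of genome annotations and alignment/hit tables into domain objects.

All genomic intervals are 0-based half-open internally.  GFF3 (1-based,
closed) coordinates are converted at the boundary, as are BLAST subject
coordinates.  Each gene is reduced to a single representative transcript —
the one with the longest total CDS — so that downstream homology and
expression steps operate on one exon chain per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Malformed annotation or hit-table input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with the exon chain of its representative transcript.

    ``span`` and every exon are 0-based half-open base-pair intervals.
    Exons are sorted by start, pairwise non-overlapping and contained in
    the span.  ``cds_length`` is the total CDS length (bp) of the
    representative transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    span: Interval
    exons: tuple[Interval, ...]
    cds_length: int
    transcript_id: str = ""

    def __post_init__(self) -> None:
        start, end = self.span
        if start >= end:
            raise AnnotationError(f"{self.gene_id}: empty span {self.span}")
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e - s < 1:
                raise AnnotationError(f"{self.gene_id}: empty exon ({s},{e})")
            if s < start or e > end:
                raise AnnotationError(f"{self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def overlaps(self, other: "GeneModel") -> bool:
        return (
            self.chrom == other.chrom
            and self.span[0] < other.span[1]
            and other.span[0] < self.span[1]
        )


class Annotation:
    """A named set of gene models with a per-chromosome rank order.

    Rank is the dense 0-based ordering of genes along each chromosome by
    start coordinate; it is the canonical proximity measure used for the
    adjacency window in homology classification and for picking upstream
    neighbours in the merged-null simulation.
    """

    def __init__(self, genotype_label: str, genes: list[GeneModel]):
        self.genotype_label = genotype_label
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        # rank ties broken by gene id for determinism
        self.rank: dict[str, int] = {}
        self.by_chrom: dict[str, list[str]] = {}
        for chrom in sorted({g.chrom for g in genes}):
            ordered = sorted(
                (g for g in genes if g.chrom == chrom),
                key=lambda g: (g.span[0], g.gene_id),
            )
            self.by_chrom[chrom] = [g.gene_id for g in ordered]
            for i, g in enumerate(ordered):
                self.rank[g.gene_id] = i

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def upstream_neighbor(self, gene_id: str) -> str | None:
        """Gene of next-lower rank on the same chromosome, or None at rank 0."""
        g = self.genes[gene_id]
        r = self.rank[gene_id]
        if r == 0:
            return None
        return self.by_chrom[g.chrom][r - 1]

    def transcript_to_gene(self) -> dict[str, str]:
        """Map representative transcript IDs to gene IDs."""
        return {g.transcript_id: g.gene_id for g in self.genes.values() if g.transcript_id}


@dataclass(frozen=True)
class SyntenicBlock:
    """One whole-genome-alignment block (nucmer), both sides normalized start < end."""

    ref_chrom: str
    ref_interval: Interval
    qry_chrom: str
    qry_interval: Interval
    orientation: str  # "same" | "inverted"

    def flipped(self) -> "SyntenicBlock":
        """Same block viewed from the query genome's side."""
        return SyntenicBlock(
            self.qry_chrom, self.qry_interval, self.ref_chrom, self.ref_interval, self.orientation
        )


@dataclass(frozen=True)
class BlastHit:
    """A gene-level blastn hit; subject_interval is on the subject transcript."""

    query_gene: str
    subject_gene: str
    evalue: float
    match_length: int
    subject_interval: Interval


def _transcript_cds_lengths(db: gffutils.FeatureDB, gene) -> dict[str, int]:
    out: dict[str, int] = {}
    for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
        total = 0
        for cds in db.children(mrna, featuretype="CDS"):
            total += cds.end - cds.start + 1
        out[mrna.id] = total
    return out


def read_gff3(path: str, genotype_label: str | None = None) -> Annotation:
    """Read a GFF3 annotation into an :class:`Annotation`.

    For each gene the representative transcript is the one with the
    longest total CDS (ties broken by lexicographically smallest
    transcript ID).  Genes with no CDS on any transcript are skipped with
    a warning.  An exon whose Parent is not an mRNA of a gene is a hard
    error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    # orphan exon check: every exon must hang off an mRNA/transcript
    mrna_ids = {f.id for f in db.features_of_type(("mRNA", "transcript"))}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise AnnotationError(
                f"exon {exon.id!r} at {exon.seqid}:{exon.start}-{exon.end} "
                "has no parent mRNA"
            )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds_by_tx = _transcript_cds_lengths(db, gene)
        cds_by_tx = {t: l for t, l in cds_by_tx.items() if l > 0}
        if not cds_by_tx:
            logger.warning("gene %s has no CDS on any transcript; skipped", gene.id)
            continue
        # longest CDS; ties -> lexicographically smallest transcript id
        rep = min(cds_by_tx, key=lambda t: (-cds_by_tx[t], t))
        exons = sorted(
            (e.start - 1, e.end)
            for e in db.children(rep, featuretype="exon")
        )
        if not exons:
            # single-feature transcripts: fall back to CDS intervals as exons
            exons = sorted((c.start - 1, c.end) for c in db.children(rep, featuretype="CDS"))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                span=(gene.start - 1, gene.end),
                exons=tuple(exons),
                cds_length=cds_by_tx[rep],
                transcript_id=rep,
            )
        )
    return Annotation(genotype_label or str(path), genes)


def write_gff3(ann: Annotation, path: str) -> None:
    """Write an Annotation (representative transcripts only) back to GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.by_chrom):
            for gid in ann.by_chrom[chrom]:
                g = ann.genes[gid]
                tx = g.transcript_id or f"{gid}.t1"
                s, e = g.span
                fh.write(
                    f"{g.chrom}\t.\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={gid}\n"
                )
                fh.write(
                    f"{g.chrom}\t.\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tx};Parent={gid}\n"
                )
                for i, (xs, xe) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\t.\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                        f"ID={tx}.exon{i};Parent={tx}\n"
                    )
                    fh.write(
                        f"{g.chrom}\t.\tCDS\t{xs + 1}\t{xe}\t.\t{g.strand}\t0\t"
                        f"ID={tx}.cds{i};Parent={tx}\n"
                    )


def read_show_coords(path: str) -> list[SyntenicBlock]:
    """Parse nucmer ``show-coords`` tabular output into syntenic blocks.

    Accepts both plain ``show-coords`` output (header + ``=====`` separator)
    and headerless ``-T -H`` style tables.  A row whose query start exceeds
    its end is an inverted alignment; its interval is normalized and the
    block flagged ``inverted``.
    """
    blocks: list[SyntenicBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("=") or line.startswith("/") or line.startswith("NUCMER"):
                continue
            fields = [f for f in line.replace("|", " ").split() if f]
            if len(fields) < 4:
                continue
            try:
                s1, e1, s2, e2 = (int(fields[i]) for i in range(4))
            except ValueError:
                # header line (e.g. "[S1] [E1] ...") is non-numeric: skip if bracketed
                if fields[0].startswith("["):
                    continue
                raise AnnotationError(
                    f"{path}:{lineno}: non-numeric coordinate fields in {line!r}"
                )
            ref_chrom, qry_chrom = fields[-2], fields[-1]
            orientation = "same"
            if s2 > e2:
                s2, e2 = e2, s2
                orientation = "inverted"
            if s1 > e1:
                s1, e1 = e1, s1
                orientation = "inverted"
            blocks.append(
                SyntenicBlock(
                    ref_chrom=ref_chrom,
                    ref_interval=(s1 - 1, e1),
                    qry_chrom=qry_chrom,
                    qry_interval=(s2 - 1, e2),
                    orientation=orientation,
                )
            )
    return blocks


#: column names of BLAST tabular output (-outfmt 6)
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path: str, transcript_to_gene: dict[str, str]) -> list[BlastHit]:
    """Read 12-column BLAST tabular hits and re-key transcripts to genes.

    Subject coordinates (1-based, possibly reversed for minus-strand
    alignments) are normalized to 0-based half-open with start < end.
    Any transcript ID missing from the mapping is a hard error.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    ids = pd.unique(pd.concat([df["qseqid"], df["sseqid"]]).astype(str))
    missing = sorted(i for i in ids if i not in transcript_to_gene)
    if missing:
        raise AnnotationError(
            f"{path}: transcript IDs absent from mapping: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    hits = []
    for row in df.itertuples(index=False):
        s, e = int(row.sstart), int(row.send)
        if s > e:
            s, e = e, s
        hits.append(
            BlastHit(
                query_gene=transcript_to_gene[str(row.qseqid)],
                subject_gene=transcript_to_gene[str(row.sseqid)],
                evalue=float(row.evalue),
                match_length=int(row.length),
                subject_interval=(s - 1, e),
            )
        )
    return hits
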