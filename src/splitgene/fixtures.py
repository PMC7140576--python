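"""Synthetic paired annotations, homology tables and exon counts with known truth.

The generator emulates the statistical situation the pipeline is built
for: two annotations of closely related genotypes sharing a syntenic
chromosome, containing

* one-to-one loci — the same true gene annotated once in each annotation
  (background for the null simulations);
* true_merged loci — one true gene, correctly annotated as a single gene
  in annotation A but wrongly split into two fragments in B;
* true_split loci — two distinct true genes, wrongly merged into one
  gene in A but correctly annotated separately in B;
* tandem loci — two B genes whose BLAST hits overlap on the A subject
  transcript (tandem duplicates, excluded by the L1/L2 filter);
* strand-fail and overlap-fail loci — two B genes on opposite strands,
  or with overlapping spans, excluded by the corresponding filters.

Expression: every true gene carries a per-tissue log2 profile; exons
inherit the gene's rate scaled by exon length, and read counts are drawn
negative-binomial.  Distinct true genes at one locus differ by
independent per-tissue log2 effects of standard deviation ``sigma``, so
true_split candidates diverge while true_merged fragments track exactly.
All randomness flows through one numpy Generator: a fixed seed
reproduces every file bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import Annotation, BlastHit, GeneModel, SyntenicBlock
from .expression import ExonCountMatrix, LIBRARY_COLUMNS

CANDIDATE_CLASSES = ("true_merged", "true_split", "tandem", "strand_fail", "overlap_fail")


@dataclass
class FixtureConfig:
    n_one_to_one: int = 20
    n_tandem: int = 0
    n_true_split: int = 0
    n_true_merged: int = 0
    n_strand_fail: int = 0
    n_overlap_fail: int = 0
    n_tissues: int = 10
    n_replicates: int = 2
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len: int = 200
    intergenic_gap: int = 3000
    within_locus_gap: int = 1000
    mean_expression: float = 50.0  # expected reads per mean-length exon per library
    profile_sd: float = 1.0  # per-tissue log2 spread of locus expression
    dispersion: float = 0.1  # NB dispersion; 0 -> deterministic expected counts
    sigma: float = 1.0  # log2 sd of per-tissue divergence between distinct genes
    genotype_a: str = "A"
    genotype_b: str = "B"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_one_to_one", "n_tandem", "n_true_split", "n_true_merged",
                     "n_strand_fail", "n_overlap_fail"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma < 0 or self.dispersion < 0:
            raise ValueError("sigma and dispersion must be >= 0")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need >= 2 exons")


def _exon_chain(rng, cfg, start: int) -> tuple[list[tuple[int, int]], int]:
    """Random exon chain beginning at ``start``; returns (exons, end)."""
    n = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exons = []
    pos = start
    for _ in range(n):
        length = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
        exons.append((pos, pos + length))
        pos += length + cfg.intron_len
    return exons, exons[-1][1]


def _tx_len(exons) -> int:
    return sum(e - s for s, e in exons)


def generate_annotation_pair(
    cfg: FixtureConfig, rng: np.random.Generator
) -> tuple[Annotation, Annotation, pd.DataFrame, list[BlastHit], list[BlastHit], list[SyntenicBlock]]:
    """Build the paired annotations, truth table, BLAST-like hits and blocks.

    Loci are laid out along one chromosome: one-to-one background genes
    first (so the merged-null simulation finds adjacent non-candidate
    pairs), then the candidate classes.  Hits carry perfect e-values
    (1e-50) and subject intervals in representative-transcript
    coordinates; truly split/merged loci tile the subject transcript
    disjointly (tandem ratio 0) while tandem loci overlap by 30%.
    """
    chrom = "chr1"
    genes_a: list[GeneModel] = []
    genes_b: list[GeneModel] = []
    hits_ab: list[BlastHit] = []  # queries in A, subjects in B
    hits_ba: list[BlastHit] = []  # queries in B, subjects in A
    truth_rows = []
    cursor = 1000
    counter = {"a": 0, "b": 0}

    def next_id(side: str) -> str:
        counter[side] += 1
        return f"G{side.upper()}{counter[side]:05d}"

    def add_one_to_one(case_idx: int) -> None:
        nonlocal cursor
        exons, end = _exon_chain(rng, cfg, cursor)
        ga, gb = next_id("a"), next_id("b")
        span = (exons[0][0], end)
        for gid, bucket in ((ga, genes_a), (gb, genes_b)):
            bucket.append(
                GeneModel(gid, chrom, "+", span, tuple(exons), _tx_len(exons), f"{gid}.t1")
            )
        L = _tx_len(exons)
        hits_ab.append(BlastHit(ga, gb, 1e-50, L, (0, L)))
        hits_ba.append(BlastHit(gb, ga, 1e-50, L, (0, L)))
        truth_rows.append(
            dict(case_id=f"o2o_{case_idx:05d}", case_class="one_to_one",
                 gene_a=ga, genes_b=gb, expected_testable=False, expected_call="")
        )
        cursor = end + cfg.intergenic_gap

    def add_candidate(case_class: str, case_idx: int) -> None:
        nonlocal cursor
        exons1, end1 = _exon_chain(rng, cfg, cursor)
        gap_start = end1 + cfg.within_locus_gap
        exons2, end2 = _exon_chain(rng, cfg, gap_start)
        ga = next_id("a")
        gb1, gb2 = next_id("b"), next_id("b")
        merged_exons = tuple(exons1 + exons2)
        genes_a.append(
            GeneModel(ga, chrom, "+", (exons1[0][0], end2), merged_exons,
                      _tx_len(merged_exons), f"{ga}.t1")
        )
        strand2 = "-" if case_class == "strand_fail" else "+"
        span1 = (exons1[0][0], end1)
        span2 = (exons2[0][0], end2)
        if case_class == "overlap_fail":
            # extend gene1's span (UTR-like) past gene2's start: spans overlap,
            # exons stay disjoint
            span1 = (exons1[0][0], exons2[0][0] + 10)
        genes_b.append(GeneModel(gb1, chrom, "+", span1, tuple(exons1), _tx_len(exons1), f"{gb1}.t1"))
        genes_b.append(GeneModel(gb2, chrom, strand2, span2, tuple(exons2), _tx_len(exons2), f"{gb2}.t1"))

        l1, l2 = _tx_len(exons1), _tx_len(exons2)
        L = l1 + l2
        if case_class == "tandem":
            # overlapping hits on the subject transcript: L1/L2 = 0.3
            a_end = int(0.65 * L)
            b_start = int(0.35 * L)
            hits_ba.append(BlastHit(gb1, ga, 1e-50, a_end, (0, a_end)))
            hits_ba.append(BlastHit(gb2, ga, 1e-50, L - b_start, (b_start, L)))
        else:
            hits_ba.append(BlastHit(gb1, ga, 1e-50, l1, (0, l1)))
            hits_ba.append(BlastHit(gb2, ga, 1e-50, l2, (l1, L)))
        hits_ab.append(BlastHit(ga, gb1, 1e-50, l1, (0, l1)))
        hits_ab.append(BlastHit(ga, gb2, 1e-50, l2, (0, l2)))

        testable = case_class in ("true_split", "true_merged")
        expected = {"true_split": "split_supported", "true_merged": "merge_supported"}.get(
            case_class, ""
        )
        truth_rows.append(
            dict(case_id=f"{case_class}_{case_idx:05d}", case_class=case_class,
                 gene_a=ga, genes_b=f"{gb1},{gb2}", expected_testable=testable,
                 expected_call=expected)
        )
        cursor = end2 + cfg.intergenic_gap

    for i in range(cfg.n_one_to_one):
        add_one_to_one(i)
    for cls, n in (("true_merged", cfg.n_true_merged), ("true_split", cfg.n_true_split),
                   ("tandem", cfg.n_tandem), ("strand_fail", cfg.n_strand_fail),
                   ("overlap_fail", cfg.n_overlap_fail)):
        for i in range(n):
            add_candidate(cls, i)

    ann_a = Annotation(cfg.genotype_a, genes_a)
    ann_b = Annotation(cfg.genotype_b, genes_b)
    blocks = [SyntenicBlock(chrom, (0, cursor + 1000), chrom, (0, cursor + 1000), "same")]
    truth = pd.DataFrame(truth_rows)
    return ann_a, ann_b, truth, hits_ab, hits_ba, blocks


def library_sheet(cfg: FixtureConfig) -> pd.DataFrame:
    rows = []
    for genotype in (cfg.genotype_a, cfg.genotype_b):
        for t in range(1, cfg.n_tissues + 1):
            for r in range(1, cfg.n_replicates + 1):
                rows.append((f"{genotype}_T{t:02d}_R{r}", genotype, f"tissue{t:02d}", r))
    libs = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
    return libs.set_index("library_id", drop=False)


def _true_gene_map(truth: pd.DataFrame, ann_b: Annotation) -> dict[tuple, str]:
    """Map each exon interval (by genomic coordinates) to its true gene id.

    One-to-one and true_merged loci have a single true gene; all other
    classes carry two distinct true genes, one per B gene.
    """
    exon_truth: dict[tuple, str] = {}
    for row in truth.itertuples(index=False):
        b_genes = row.genes_b.split(",")
        single = row.case_class in ("one_to_one", "true_merged")
        for k, gb in enumerate(b_genes):
            tg = row.case_id if single else f"{row.case_id}.g{k + 1}"
            for iv in ann_b[gb].exons:
                exon_truth[(ann_b[gb].chrom, iv)] = tg
    return exon_truth


@dataclass
class ExpressionTruth:
    """Stored generator parameters: per true-gene, per-tissue expected rates."""

    rates: pd.DataFrame  # true genes x tissues, expected reads per mean-length exon
    mean_exon_len: float


def generate_expression(
    truth: pd.DataFrame,
    annotations: tuple[Annotation, Annotation],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> tuple[ExonCountMatrix, ExonCountMatrix, ExpressionTruth]:
    """Draw exon count matrices for both annotations.

    Each true gene g has per-tissue rate
    ``mean_expression * 2**(u_t + d_{g,t})`` with locus profile
    u_t ~ N(0, profile_sd^2) and, when the locus holds two distinct true
    genes, per-gene offsets d ~ N(0, sigma^2 / 2) so the two genes'
    per-tissue log2 difference is N(0, sigma^2).  An exon's expected
    count is the gene rate scaled by exon length / mean exon length;
    counts are negative-binomial with the configured dispersion
    (dispersion 0 gives the deterministic expected counts).  Libraries of
    genotype A are generated against annotation A, genotype B against B.
    """
    ann_a, ann_b = annotations
    libs = library_sheet(cfg)
    exon_truth = _true_gene_map(truth, ann_b)
    mean_len = float(np.mean(cfg.exon_len_range))

    # per-true-gene per-tissue rates, in truth-table order for determinism
    rate_rows: dict[str, np.ndarray] = {}
    for row in truth.itertuples(index=False):
        u = rng.normal(0.0, cfg.profile_sd, size=cfg.n_tissues)
        single = row.case_class in ("one_to_one", "true_merged")
        n_true = 1 if single else 2
        for k in range(n_true):
            tg = row.case_id if single else f"{row.case_id}.g{k + 1}"
            delta = (
                np.zeros(cfg.n_tissues)
                if single or cfg.sigma == 0
                else rng.normal(0.0, cfg.sigma / np.sqrt(2.0), size=cfg.n_tissues)
            )
            rate_rows[tg] = cfg.mean_expression * np.exp2(u + delta)
    tissues = [f"tissue{t:02d}" for t in range(1, cfg.n_tissues + 1)]
    rates = pd.DataFrame.from_dict(rate_rows, orient="index", columns=tissues)

    def counts_for(ann: Annotation, genotype: str) -> ExonCountMatrix:
        lib_sel = libs[libs["genotype"] == genotype]
        exon_ids, gene_ids, lengths, mu_rows = [], [], [], []
        for chrom in sorted(ann.by_chrom):
            for gid in ann.by_chrom[chrom]:
                g = ann[gid]
                for i, iv in enumerate(g.exons, 1):
                    tg = exon_truth[(g.chrom, iv)]
                    length = iv[1] - iv[0]
                    exon_ids.append(f"{gid}:{i}")
                    gene_ids.append(gid)
                    lengths.append(length)
                    mu_rows.append(rate_rows[tg] * (length / mean_len))
        mu_tissue = np.asarray(mu_rows)  # exons x tissues
        # expand tissues to libraries (replicates iid given tissue)
        t_index = [tissues.index(t) for t in lib_sel["tissue"]]
        mu = mu_tissue[:, t_index]
        if cfg.dispersion > 0:
            lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
            counts = rng.poisson(lam).astype(np.int64)
        else:
            counts = np.rint(mu).astype(np.int64)
        cdf = pd.DataFrame(counts, index=pd.Index(exon_ids, name="exon_id"),
                           columns=list(lib_sel["library_id"]))
        meta = pd.DataFrame(
            {"gene_id": gene_ids, "length": lengths},
            index=pd.Index(exon_ids, name="exon_id"),
        )
        return ExonCountMatrix(cdf, meta, libs)

    counts_a = counts_for(ann_a, cfg.genotype_a)
    counts_b = counts_for(ann_b, cfg.genotype_b)
    return counts_a, counts_b, ExpressionTruth(rates=rates, mean_exon_len=mean_len)


@dataclass
class Fixture:
    """Everything one generated study holds, plus its ground truth."""

    cfg: FixtureConfig
    ann_a: Annotation
    ann_b: Annotation
    truth: pd.DataFrame
    hits_ab: list[BlastHit]
    hits_ba: list[BlastHit]
    blocks: list[SyntenicBlock]
    counts_a: ExonCountMatrix
    counts_b: ExonCountMatrix
    expression_truth: ExpressionTruth

    @property
    def libraries(self) -> pd.DataFrame:
        return self.counts_a.libraries


def generate_fixture(cfg: FixtureConfig) -> Fixture:
    """One-call generation of the full study from a config (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    ann_a, ann_b, truth, hits_ab, hits_ba, blocks = generate_annotation_pair(cfg, rng)
    counts_a, counts_b, etruth = generate_expression(truth, (ann_a, ann_b), cfg, rng)
    return Fixture(cfg, ann_a, ann_b, truth, hits_ab, hits_ba, blocks,
                   counts_a, counts_b, etruth)


def write_fixture(fx: Fixture, outdir: str) -> dict[str, str]:
    """Write the fixture as the plain-text files the CLI pipeline consumes."""
    import os

    from .annotation_io import write_gff3

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gff_a": os.path.join(outdir, "annotation_A.gff3"),
        "gff_b": os.path.join(outdir, "annotation_B.gff3"),
        "hits_ab": os.path.join(outdir, "hits_A_vs_B.tsv"),
        "hits_ba": os.path.join(outdir, "hits_B_vs_A.tsv"),
        "coords": os.path.join(outdir, "blocks.coords"),
        "counts_a": os.path.join(outdir, "exon_counts_A.tsv"),
        "counts_b": os.path.join(outdir, "exon_counts_B.tsv"),
        "libraries": os.path.join(outdir, "libraries.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_gff3(fx.ann_a, paths["gff_a"])
    write_gff3(fx.ann_b, paths["gff_b"])

    def tx(ann: Annotation, gid: str) -> str:
        return ann[gid].transcript_id

    def write_hits(hits, q_ann, s_ann, path):
        with open(path, "w") as fh:
            for h in hits:
                s, e = h.subject_interval
                fh.write(
                    f"{tx(q_ann, h.query_gene)}\t{tx(s_ann, h.subject_gene)}\t100.00\t"
                    f"{h.match_length}\t0\t0\t1\t{h.match_length}\t{s + 1}\t{e}\t"
                    f"{h.evalue:g}\t{h.match_length * 2}\n"
                )

    write_hits(fx.hits_ab, fx.ann_a, fx.ann_b, paths["hits_ab"])
    write_hits(fx.hits_ba, fx.ann_b, fx.ann_a, paths["hits_ba"])
    with open(paths["coords"], "w") as fh:
        for b in fx.blocks:
            rs, re = b.ref_interval
            qs, qe = b.qry_interval
            if b.orientation == "inverted":
                qs, qe = qe, qs
            fh.write(
                f"{rs + 1}\t{re}\t{qs + 1}\t{qe}\t{re - rs}\t{abs(qe - qs)}\t100.00\t"
                f"{b.ref_chrom}\t{b.qry_chrom}\n"
            )
    fx.counts_a.to_tsv(paths["counts_a"])
    fx.counts_b.to_tsv(paths["counts_b"])
    fx.libraries.to_csv(paths["libraries"], sep="\t", index=False)
    fx.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
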