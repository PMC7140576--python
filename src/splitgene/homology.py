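"""Cross-annotation gene correspondence and split-gene candidate isolation.

Implements the second stage of the syntenic homology pipeline: BLAST hits
between two annotations are deduplicated per gene pair, restricted to
nucmer synteny blocks (+/- 500 kb margin), turned into per-gene
correspondence classes (none / single / multiple), resolved reciprocally,
and finally filtered into split-gene candidates — one "merged" gene in
one annotation matching an ordered set of >= 2 "split" genes in the other.

Candidates failing a filter (overlapping spans, opposite strands, tandem
duplication, unexpressed genes, non-proximal) are retained with their
failure reasons so exclusion statistics stay computable; only candidates
passing every filter are testable by the M2f classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .annotation_io import Annotation, BlastHit, GeneModel, SyntenicBlock

logger = logging.getLogger(__name__)

FILTER_NAMES = ("overlapping", "opposite_strand", "tandem", "unexpressed", "non_proximal")


@dataclass(frozen=True)
class Correspondence:
    """One query gene's set of surviving subject genes and its class."""

    query_gene: str
    subject_genes: frozenset[str]
    classification: str  # none | single | multiple
    proximal: bool

    def __post_init__(self):
        n = len(self.subject_genes)
        expected = "none" if n == 0 else ("single" if n == 1 else "multiple")
        if self.classification != expected:
            raise ValueError(
                f"{self.query_gene}: classification {self.classification!r} "
                f"inconsistent with {n} subject genes"
            )


@dataclass
class SplitCandidate:
    """A merged gene in one annotation vs >= 2 split genes in the other."""

    merged_annotation: str
    merged_gene: str
    split_annotation: str
    split_genes: list[str]  # sorted by genomic start
    tandem_ratio: float
    filters: dict[str, bool]  # filter name -> passed
    reasons: list[str] = field(default_factory=list)
    corroboration: str = "unset"  # corroborated | unique | unset

    @property
    def testable(self) -> bool:
        return all(self.filters.values())

    @property
    def candidate_id(self) -> str:
        return f"{self.merged_annotation}:{self.merged_gene}|{self.split_annotation}:" + "+".join(
            self.split_genes
        )


def best_hits(hits: list[BlastHit], max_evalue: float = 1e-4) -> list[BlastHit]:
    """Keep one best hit per (query, subject) gene pair below the e-value cutoff.

    Best = minimal e-value, ties broken by maximal aligned length (then by
    subject interval for full determinism).  The cutoff is strict: a hit
    at exactly ``max_evalue`` is removed.
    """
    best: dict[tuple[str, str], BlastHit] = {}
    for h in hits:
        if not h.evalue < max_evalue:
            continue
        key = (h.query_gene, h.subject_gene)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.match_length, h.subject_interval) < (
            cur.evalue,
            -cur.match_length,
            cur.subject_interval,
        ):
            best[key] = h
    return [best[k] for k in sorted(best)]


def filter_by_synteny(
    hits: list[BlastHit],
    blocks: list[SyntenicBlock],
    query_ann: Annotation,
    subject_ann: Annotation,
    margin_bp: int = 500_000,
) -> list[BlastHit]:
    """Keep hits whose query and subject genes fall in the same synteny block.

    A gene "falls in" a block side when its span overlaps the block
    interval extended by ``margin_bp`` on both ends, on the matching
    chromosome.  Both genes must satisfy this for one and the same block.
    Blocks are oriented with their reference side in the query annotation.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, b in enumerate(blocks):
        t = trees.setdefault(b.ref_chrom, IntervalTree())
        lo = max(0, b.ref_interval[0] - margin_bp)
        t.addi(lo, b.ref_interval[1] + margin_bp, idx)

    kept = []
    for h in hits:
        qg = query_ann[h.query_gene]
        sg = subject_ann[h.subject_gene]
        tree = trees.get(qg.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(*qg.span):
            b = blocks[iv.data]
            if b.qry_chrom != sg.chrom:
                continue
            lo = max(0, b.qry_interval[0] - margin_bp)
            hi = b.qry_interval[1] + margin_bp
            if sg.span[0] < hi and lo < sg.span[1]:
                kept.append(h)
                break
    return kept


def classify_correspondences(
    hits: list[BlastHit],
    subject_ann: Annotation,
    window: int = 5,
    query_ann: Annotation | None = None,
) -> list[Correspondence]:
    """Group surviving hits per query gene into none/single/multiple classes.

    ``proximal`` is true when all subject genes lie on one chromosome and
    their maximum pairwise rank difference is <= ``window`` gene models.
    When ``query_ann`` is given, its genes without any surviving hit are
    emitted with classification "none" (no corresponding gene in the
    alternative annotation); otherwise only genes with hits appear.
    """
    by_query: dict[str, set[str]] = {}
    for h in hits:
        by_query.setdefault(h.query_gene, set()).add(h.subject_gene)
    if query_ann is not None:
        for q in query_ann.genes:
            by_query.setdefault(q, set())
    out = []
    for q in sorted(by_query):
        subjects = by_query[q]
        n = len(subjects)
        if n == 0:
            out.append(Correspondence(q, frozenset(), "none", False))
            continue
        cls = "single" if n == 1 else "multiple"
        chroms = {subject_ann[s].chrom for s in subjects}
        if len(chroms) == 1:
            ranks = [subject_ann.rank[s] for s in subjects]
            proximal = max(ranks) - min(ranks) <= window
        else:
            proximal = False
        out.append(Correspondence(q, frozenset(subjects), cls, proximal))
    return out


def reciprocal_resolve(
    a_to_b: list[Correspondence], b_to_a: list[Correspondence]
) -> tuple[list[tuple[str, str]], list[tuple[str, frozenset[str]]]]:
    """Confirm relationships by overlap of the reciprocal BLAST directions.

    Returns ``(one_to_one, one_to_many)``:

    * one_to_one: pairs (g, h) where g -> {h} and h -> {g};
    * one_to_many: (g, {h1..hk}) where g -> {h1..hk} (k >= 2) and every
      hi maps back exclusively to {g}.

    Relationships failing exclusivity are dropped with a logged reason.
    """
    fwd = {c.query_gene: c.subject_genes for c in a_to_b}
    rev = {c.query_gene: c.subject_genes for c in b_to_a}

    one_to_one: list[tuple[str, str]] = []
    one_to_many: list[tuple[str, frozenset[str]]] = []
    for g in sorted(fwd):
        subjects = fwd[g]
        if len(subjects) == 1:
            (h,) = subjects
            if rev.get(h) == frozenset({g}):
                one_to_one.append((g, h))
        else:
            if all(rev.get(h) == frozenset({g}) for h in subjects):
                one_to_many.append((g, subjects))
            else:
                logger.info(
                    "dropped one-to-many %s -> %s: subjects not exclusive to %s",
                    g, sorted(subjects), g,
                )
    return one_to_one, one_to_many


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = None
    for s, e in sorted(intervals):
        if end is None or s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def tandem_ratio(subject_gene: GeneModel, query_hits: list[BlastHit]) -> float:
    """Proportion of the subject's aligned space covered by more than one query.

    L2 is the total length of the union of all query hits' subject
    intervals ("total aligned space"); L1 is the length of subject
    positions covered by hits from >= 2 distinct query genes.  Tandem
    duplicates overlap heavily on the subject transcript (ratio >= 0.1),
    genuine split genes tile it nearly disjointly (ratio ~ 0).
    """
    by_query: dict[str, list[tuple[int, int]]] = {}
    for h in query_hits:
        if h.subject_gene != subject_gene.gene_id:
            raise ValueError(
                f"hit subject {h.subject_gene!r} is not {subject_gene.gene_id!r}"
            )
        by_query.setdefault(h.query_gene, []).append(h.subject_interval)
    if len(by_query) < 2:
        raise ValueError("tandem_ratio needs hits from >= 2 distinct query genes")

    all_ivs = [iv for ivs in by_query.values() for iv in ivs]
    l2 = _union_length(all_ivs)
    if l2 == 0:
        raise ValueError(f"{subject_gene.gene_id}: no aligned bases (L2 = 0)")

    # L1: sweep over breakpoints, counting positions covered by >=2 queries
    bounds = sorted({x for iv in all_ivs for x in iv})
    l1 = 0
    for lo, hi in zip(bounds, bounds[1:]):
        covering = sum(
            1
            for q, ivs in by_query.items()
            if any(s <= lo and hi <= e for s, e in ivs)
        )
        if covering >= 2:
            l1 += hi - lo
    return l1 / l2


def build_split_candidates(
    one_to_many: list[tuple[str, frozenset[str]]],
    merged_ann: Annotation,
    split_ann: Annotation,
    expressed: set[str],
    hits_to_merged: list[BlastHit],
    window: int = 5,
    tandem_max: float = 0.1,
) -> list[SplitCandidate]:
    """Filter one-to-many relations into split-gene candidates.

    ``hits_to_merged`` are the (deduplicated, synteny-filtered) hits with
    the split genes as queries and the merged gene as subject; they supply
    the subject-transcript intervals for the tandem-duplication test.
    Every candidate is emitted with a pass/fail record per filter; a
    testable candidate passes all of: split genes pairwise non-overlapping,
    same strand, tandem ratio < ``tandem_max`` (strict), every involved
    gene expressed, split genes within the ``window``-gene rank window.
    """
    hits_by_subject: dict[str, list[BlastHit]] = {}
    for h in hits_to_merged:
        hits_by_subject.setdefault(h.subject_gene, []).append(h)

    out = []
    for merged_gene, split_set in one_to_many:
        missing = sorted(s for s in split_set if s not in split_ann)
        if missing:
            raise KeyError(
                f"split genes {missing} absent from annotation "
                f"{split_ann.genotype_label!r}"
            )
        split_genes = sorted(split_set, key=lambda s: (split_ann[s].chrom, split_ann[s].span[0], s))
        models = [split_ann[s] for s in split_genes]
        filters = dict.fromkeys(FILTER_NAMES, True)
        reasons = []

        if any(a.overlaps(b) for i, a in enumerate(models) for b in models[i + 1:]):
            filters["overlapping"] = False
            reasons.append("split genes have overlapping spans")
        if len({m.strand for m in models}) > 1:
            filters["opposite_strand"] = False
            reasons.append("split genes on opposite strands")

        relevant = [
            h for h in hits_by_subject.get(merged_gene, []) if h.query_gene in split_set
        ]
        try:
            ratio = tandem_ratio(merged_ann[merged_gene], relevant)
        except ValueError as exc:
            ratio = float("nan")
            filters["tandem"] = False
            reasons.append(f"tandem ratio unavailable: {exc}")
        else:
            if not ratio < tandem_max:
                filters["tandem"] = False
                reasons.append(f"tandem duplication (L1/L2 = {ratio:.3f} >= {tandem_max})")

        unexpr = [g for g in [merged_gene, *split_genes] if g not in expressed]
        if unexpr:
            filters["unexpressed"] = False
            reasons.append(f"not expressed: {', '.join(unexpr)}")

        chroms = {m.chrom for m in models}
        if len(chroms) > 1:
            filters["non_proximal"] = False
            reasons.append("split genes on different chromosomes")
        else:
            ranks = [split_ann.rank[s] for s in split_genes]
            if max(ranks) - min(ranks) > window:
                filters["non_proximal"] = False
                reasons.append(f"rank spread {max(ranks) - min(ranks)} > {window}")

        out.append(
            SplitCandidate(
                merged_annotation=merged_ann.genotype_label,
                merged_gene=merged_gene,
                split_annotation=split_ann.genotype_label,
                split_genes=split_genes,
                tandem_ratio=ratio,
                filters=filters,
                reasons=reasons,
            )
        )
    return out


def corroborate(
    candidates_ab: list[SplitCandidate], candidates_ac: list[SplitCandidate]
) -> tuple[list[SplitCandidate], list[SplitCandidate]]:
    """Mark candidates seen consistently in two pairwise comparisons.

    Both lists must share annotation A on one side.  A merged-side A gene
    that appears as ``merged_gene`` in both comparisons is corroborated;
    a split-side A gene set matching a single gene in both B and C is
    corroborated.  Everything else is unique.  Both lists are annotated
    in place and returned.
    """

    def labels(cands):
        out = set()
        for c in cands:
            out.update((c.merged_annotation, c.split_annotation))
        return out

    shared = labels(candidates_ab) & labels(candidates_ac)
    anchor = next(iter(shared)) if len(shared) == 1 else None

    def merged_keys(cands):
        return {c.merged_gene for c in cands if anchor is None or c.merged_annotation == anchor}

    def split_keys(cands):
        return {
            frozenset(c.split_genes)
            for c in cands
            if anchor is None or c.split_annotation == anchor
        }

    for mine, other in ((candidates_ab, candidates_ac), (candidates_ac, candidates_ab)):
        other_merged = merged_keys(other)
        other_split = split_keys(other)
        for c in mine:
            on_merged_side = anchor is None or c.merged_annotation == anchor
            on_split_side = anchor is None or c.split_annotation == anchor
            if (on_merged_side and c.merged_gene in other_merged) or (
                on_split_side and frozenset(c.split_genes) in other_split
            ):
                c.corroboration = "corroborated"
            else:
                c.corroboration = "unique"
    return candidates_ab, candidates_ac
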