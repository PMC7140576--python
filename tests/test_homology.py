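"""Correspondence classification, reciprocal resolution and candidate filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitgene import (
    best_hits,
    build_split_candidates,
    classify_correspondences,
    corroborate,
    filter_by_synteny,
    reciprocal_resolve,
    tandem_ratio,
)
from splitgene.annotation_io import Annotation, BlastHit, GeneModel, SyntenicBlock
from splitgene.homology import Correspondence


def hit(q, s, evalue=1e-50, length=100, interval=(0, 100)):
    return BlastHit(q, s, evalue, length, interval)


def gene(gid, start, end, chrom="chr1", strand="+", exons=None):
    return GeneModel(gid, chrom, strand, (start, end),
                     tuple(exons or [(start, end)]), end - start)


class TestBestHits:
    def test_lower_evalue_wins(self):
        hits = [hit("q", "s", 1e-5), hit("q", "s", 1e-10)]
        (kept,) = best_hits(hits)
        assert kept.evalue == 1e-10

    def test_evalue_tie_broken_by_match_length(self):
        hits = [hit("q", "s", 1e-20, length=150), hit("q", "s", 1e-20, length=200)]
        (kept,) = best_hits(hits)
        assert kept.match_length == 200

    @pytest.mark.parametrize("evalue,kept", [(1e-3, 0), (1e-4, 0), (9.9e-5, 1)])
    def test_cutoff_is_strict(self, evalue, kept):
        assert len(best_hits([hit("q", "s", evalue)])) == kept

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("abc"), st.sampled_from("xyz"),
                st.floats(1e-30, 1e-2), st.integers(1, 500),
            ),
            max_size=30,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_idempotent(self, raw):
        hits = [hit(q, s, e, l, (0, l)) for q, s, e, l in raw]
        once = best_hits(hits)
        assert best_hits(once) == once


class TestSynteny:
    BLOCK = SyntenicBlock("chr1", (1_000_000, 2_000_000), "chr1", (1_000_000, 2_000_000), "same")

    def run(self, q_start, q_end):
        qa = Annotation("A", [gene("q", q_start, q_end)])
        sa = Annotation("B", [gene("s", 1_500_000, 1_501_000)])
        return filter_by_synteny([hit("q", "s")], [self.BLOCK], qa, sa)

    def test_gene_within_margin_kept(self):
        assert len(self.run(2_300_000, 2_310_000)) == 1  # 300 kb past block end

    def test_gene_beyond_margin_removed(self):
        assert len(self.run(2_600_000, 2_610_000)) == 0  # 600 kb > 500 kb

    def test_chromosome_without_blocks_loses_all_hits(self):
        qa = Annotation("A", [gene("q", 0, 1000, chrom="chr9")])
        sa = Annotation("B", [gene("s", 1_500_000, 1_501_000)])
        assert filter_by_synteny([hit("q", "s")], [self.BLOCK], qa, sa) == []


class TestClassifyCorrespondences:
    def subject_ann(self, positions):
        return Annotation("B", [gene(f"s{i}", p, p + 100) for i, p in enumerate(positions)])

    def test_counts_map_to_classes(self):
        ann = self.subject_ann([0, 1000])
        hits = [hit("q1", "s0"), hit("q2", "s0"), hit("q2", "s1")]
        by_q = {c.query_gene: c for c in classify_correspondences(hits, ann)}
        assert by_q["q1"].classification == "single"
        assert by_q["q2"].classification == "multiple"
        assert "q3" not in by_q  # no hits -> no correspondence record

    def test_none_class_with_query_annotation(self):
        sub = self.subject_ann([0])
        qry = Annotation("A", [gene("q1", 0, 100), gene("q9", 500, 600)])
        by_q = {
            c.query_gene: c
            for c in classify_correspondences([hit("q1", "s0")], sub, query_ann=qry)
        }
        assert by_q["q9"].classification == "none"
        assert by_q["q9"].subject_genes == frozenset()

    def test_proximity_window(self):
        # ranks 10 and 12: proximal; ranks 10 and 40: not
        ann = self.subject_ann([i * 1000 for i in range(50)])
        near = classify_correspondences([hit("q", "s10"), hit("q", "s12")], ann)[0]
        far = classify_correspondences([hit("q", "s10"), hit("q", "s40")], ann)[0]
        assert near.proximal and not far.proximal


class TestReciprocalResolve:
    def corr(self, q, subjects):
        n = len(subjects)
        cls = "none" if n == 0 else ("single" if n == 1 else "multiple")
        return Correspondence(q, frozenset(subjects), cls, True)

    def test_symmetric_singleton_is_one_to_one(self):
        o2o, o2m = reciprocal_resolve([self.corr("g", {"h"})], [self.corr("h", {"g"})])
        assert o2o == [("g", "h")] and o2m == []

    def test_exclusive_multiple_is_one_to_many(self):
        o2o, o2m = reciprocal_resolve(
            [self.corr("g", {"h1", "h2"})],
            [self.corr("h1", {"g"}), self.corr("h2", {"g"})],
        )
        assert o2o == [] and o2m == [("g", frozenset({"h1", "h2"}))]

    def test_exclusivity_violation_dropped(self):
        o2o, o2m = reciprocal_resolve(
            [self.corr("g", {"h1", "h2"})],
            [self.corr("h1", {"g"}), self.corr("h2", {"g2"})],
        )
        assert o2o == [] and o2m == []

    def test_outputs_disjoint(self, toy_fixture):
        fx = toy_fixture
        corr_ab = classify_correspondences(fx.hits_ab, fx.ann_b)
        corr_ba = classify_correspondences(fx.hits_ba, fx.ann_a)
        o2o, o2m = reciprocal_resolve(corr_ab, corr_ba)
        flat_o2o = {g for pair in o2o for g in pair}
        flat_o2m = {g for g, many in o2m for g in [g, *many]}
        assert flat_o2o.isdisjoint(flat_o2m)


class TestTandemRatio:
    SUBJECT = gene("s", 0, 5000)

    def ratio(self, intervals):
        hits = [hit(f"q{i}", "s", interval=iv) for i, iv in enumerate(intervals)]
        return tandem_ratio(self.SUBJECT, hits)

    def test_disjoint_intervals_give_zero(self):
        assert self.ratio([(100, 500), (500, 900)]) == 0.0

    def test_overlapping_intervals(self):
        # union 900, double-covered 200
        assert self.ratio([(100, 600), (400, 1000)]) == pytest.approx(200 / 900)

    def test_identical_intervals_give_one(self):
        assert self.ratio([(100, 600), (100, 600)]) == 1.0

    def test_no_aligned_bases_is_error(self):
        with pytest.raises(ValueError):
            tandem_ratio(self.SUBJECT, [hit("q1", "s")])

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 300)), min_size=2, max_size=6
        ),
        st.integers(-10_000, 10_000),
    )
    @settings(deadline=None, derandomize=True)
    def test_translation_invariant_and_bounded(self, raw, shift):
        ivs = [(s, s + l) for s, l in raw]
        r0 = self.ratio(ivs)
        r1 = self.ratio([(s + shift + 10_000, e + shift + 10_000) for s, e in ivs])
        assert 0.0 <= r0 <= 1.0
        assert r0 == pytest.approx(r1)


class TestBuildSplitCandidates:
    def setup_pair(self, strand2="+", expressed=None, spans=None):
        spans = spans or [(0, 1000), (2000, 3000)]
        merged = Annotation("A", [gene("gA", 0, 3000)])
        split = Annotation(
            "B",
            [gene("b1", *spans[0]), gene("b2", *spans[1], strand=strand2)],
        )
        hits_to_merged = [
            hit("b1", "gA", interval=(0, 1000)),
            hit("b2", "gA", interval=(1000, 2000)),
        ]
        expressed = expressed if expressed is not None else {"gA", "b1", "b2"}
        return build_split_candidates(
            [("gA", frozenset({"b1", "b2"}))], merged, split, expressed, hits_to_merged
        )

    def test_all_filters_pass(self):
        (c,) = self.setup_pair()
        assert c.testable
        assert c.split_genes == ["b1", "b2"]
        assert c.tandem_ratio == 0.0

    def test_opposite_strand_fails(self):
        (c,) = self.setup_pair(strand2="-")
        assert not c.filters["opposite_strand"] and not c.testable

    def test_overlapping_spans_fail(self):
        (c,) = self.setup_pair(spans=[(0, 2500), (2000, 3000)])
        assert not c.filters["overlapping"]

    def test_unexpressed_gene_fails(self):
        (c,) = self.setup_pair(expressed={"gA", "b1"})
        assert not c.filters["unexpressed"]
        assert "b2" in ";".join(c.reasons)

    def test_tandem_boundary_is_strict(self):
        # L1/L2 exactly 0.1 must be excluded
        merged = Annotation("A", [gene("gA", 0, 3000)])
        split = Annotation("B", [gene("b1", 0, 1000), gene("b2", 2000, 3000)])
        hits_to_merged = [
            hit("b1", "gA", interval=(0, 500)),
            hit("b2", "gA", interval=(410, 900)),  # union 900, overlap 90
        ]
        (c,) = build_split_candidates(
            [("gA", frozenset({"b1", "b2"}))], merged, split,
            {"gA", "b1", "b2"}, hits_to_merged,
        )
        assert c.tandem_ratio == pytest.approx(0.1)
        assert not c.filters["tandem"]

    def test_missing_split_gene_is_hard_error(self):
        merged = Annotation("A", [gene("gA", 0, 3000)])
        split = Annotation("B", [gene("b1", 0, 1000)])
        with pytest.raises(KeyError):
            build_split_candidates(
                [("gA", frozenset({"b1", "bX"}))], merged, split, set(), []
            )


class TestCorroborate:
    def cand(self, merged_ann, merged_gene, split_ann, split_genes):
        from splitgene.homology import FILTER_NAMES, SplitCandidate

        return SplitCandidate(
            merged_annotation=merged_ann, merged_gene=merged_gene,
            split_annotation=split_ann, split_genes=list(split_genes),
            tandem_ratio=0.0, filters=dict.fromkeys(FILTER_NAMES, True),
        )

    def test_merged_gene_in_both_lists_corroborated(self):
        ab = [self.cand("A", "g", "B", ["b1", "b2"])]
        ac = [self.cand("A", "g", "C", ["c1", "c2"])]
        corroborate(ab, ac)
        assert ab[0].corroboration == ac[0].corroboration == "corroborated"

    def test_split_set_seen_once_is_unique(self):
        ab = [self.cand("B", "b", "A", ["a1", "a2"])]
        ac = [self.cand("C", "c", "A", ["a3", "a4"])]
        corroborate(ab, ac)
        assert ab[0].corroboration == "unique"

    def test_empty_second_list_makes_all_unique(self):
        ab = [self.cand("A", "g", "B", ["b1", "b2"])]
        corroborate(ab, [])
        assert ab[0].corroboration == "unique"

    def test_split_side_set_match_corroborated(self):
        ab = [self.cand("B", "b", "A", ["a1", "a2"])]
        ac = [self.cand("C", "c", "A", ["a1", "a2"])]
        corroborate(ab, ac)
        assert ab[0].corroboration == "corroborated"
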