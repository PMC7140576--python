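"""Annotation, synteny-block and BLAST-table parsing."""

import textwrap

import pytest

from splitgene import read_blast_tab, read_gff3, read_show_coords, write_gff3
from splitgene.annotation_io import Annotation, AnnotationError, GeneModel

GFF = textwrap.dedent("""\
    ##gff-version 3
    chr1\t.\tgene\t101\t1000\t.\t+\t.\tID=g1
    chr1\t.\tmRNA\t101\t1000\t.\t+\t.\tID=g1.m1;Parent=g1
    chr1\t.\texon\t101\t200\t.\t+\t.\tID=g1.m1.e1;Parent=g1.m1
    chr1\t.\texon\t301\t500\t.\t+\t.\tID=g1.m1.e2;Parent=g1.m1
    chr1\t.\tCDS\t101\t200\t.\t+\t0\tID=g1.m1.c1;Parent=g1.m1
    chr1\t.\tCDS\t301\t500\t.\t+\t0\tID=g1.m1.c2;Parent=g1.m1
    chr1\t.\tmRNA\t101\t1000\t.\t+\t.\tID=g1.m2;Parent=g1
    chr1\t.\texon\t101\t550\t.\t+\t.\tID=g1.m2.e1;Parent=g1.m2
    chr1\t.\tCDS\t101\t550\t.\t+\t0\tID=g1.m2.c1;Parent=g1.m2
    chr1\t.\tgene\t2001\t3000\t.\t-\t.\tID=g2
    chr1\t.\tmRNA\t2001\t3000\t.\t-\t.\tID=g2.m1;Parent=g2
    chr1\t.\texon\t2001\t3000\t.\t-\t.\tID=g2.m1.e1;Parent=g2.m1
    chr1\t.\tCDS\t2001\t2600\t.\t-\t0\tID=g2.m1.c1;Parent=g2.m1
""")


@pytest.fixture()
def gff_path(tmp_path):
    p = tmp_path / "ann.gff3"
    p.write_text(GFF)
    return str(p)


class TestReadGff3:
    def test_representative_is_longest_cds(self, gff_path):
        # g1.m1 has 100+200=300 bp CDS, g1.m2 has 450 bp
        ann = read_gff3(gff_path, "X")
        assert ann["g1"].transcript_id == "g1.m2"
        assert ann["g1"].cds_length == 450

    def test_coordinates_become_zero_based_half_open(self, gff_path):
        ann = read_gff3(gff_path, "X")
        assert ann["g1"].span == (100, 1000)
        assert ann["g1"].exons == ((100, 550),)
        assert ann["g2"].exons[0] == (2000, 3000)
        assert ann["g2"].exons[0][1] - ann["g2"].exons[0][0] == 1000

    def test_cds_tie_broken_lexicographically(self, tmp_path):
        # equal CDS totals: "t10" < "t2" lexicographically, so t10 wins
        gff = textwrap.dedent("""\
            ##gff-version 3
            chr1\t.\tgene\t1\t500\t.\t+\t.\tID=g
            chr1\t.\tmRNA\t1\t500\t.\t+\t.\tID=t2;Parent=g
            chr1\t.\texon\t1\t300\t.\t+\t.\tID=t2.e;Parent=t2
            chr1\t.\tCDS\t1\t300\t.\t+\t0\tID=t2.c;Parent=t2
            chr1\t.\tmRNA\t1\t500\t.\t+\t.\tID=t10;Parent=g
            chr1\t.\texon\t101\t400\t.\t+\t.\tID=t10.e;Parent=t10
            chr1\t.\tCDS\t101\t400\t.\t+\t0\tID=t10.c;Parent=t10
        """)
        p = tmp_path / "tie.gff3"
        p.write_text(gff)
        ann = read_gff3(str(p))
        assert ann["g"].transcript_id == "t10"

    def test_gene_without_cds_skipped_with_warning(self, tmp_path, caplog):
        gff = GFF + textwrap.dedent("""\
            chr1\t.\tgene\t5001\t6000\t.\t+\t.\tID=g3
            chr1\t.\tmRNA\t5001\t6000\t.\t+\t.\tID=g3.m1;Parent=g3
            chr1\t.\texon\t5001\t6000\t.\t+\t.\tID=g3.m1.e1;Parent=g3.m1
        """)
        p = tmp_path / "nocds.gff3"
        p.write_text(gff)
        with caplog.at_level("WARNING"):
            ann = read_gff3(str(p))
        assert "g3" not in ann
        assert any("g3" in rec.message for rec in caplog.records)

    def test_orphan_exon_is_hard_error(self, tmp_path):
        gff = GFF + "chr1\t.\texon\t7001\t7100\t.\t+\t.\tID=stray;Parent=nothing\n"
        p = tmp_path / "orphan.gff3"
        p.write_text(gff)
        with pytest.raises(AnnotationError, match="stray"):
            read_gff3(str(p))

    def test_round_trip(self, gff_path, tmp_path):
        ann = read_gff3(gff_path, "X")
        out = tmp_path / "rt.gff3"
        write_gff3(ann, str(out))
        back = read_gff3(str(out), "X")
        assert set(back.genes) == set(ann.genes)
        for gid in ann.genes:
            assert back[gid].span == ann[gid].span
            assert back[gid].strand == ann[gid].strand
            assert back[gid].exons == ann[gid].exons


class TestAnnotationRank:
    def test_rank_dense_and_ordered(self, toy_fixture):
        for ann in (toy_fixture.ann_a, toy_fixture.ann_b):
            for chrom, ordered in ann.by_chrom.items():
                ranks = [ann.rank[g] for g in ordered]
                assert ranks == list(range(len(ordered)))
                starts = [ann[g].span[0] for g in ordered]
                assert starts == sorted(starts)

    def test_upstream_neighbor(self, toy_fixture):
        ann = toy_fixture.ann_b
        ordered = ann.by_chrom["chr1"]
        assert ann.upstream_neighbor(ordered[0]) is None
        assert ann.upstream_neighbor(ordered[7]) == ordered[6]

    def test_exon_invariants_enforced(self):
        with pytest.raises(AnnotationError):
            GeneModel("g", "chr1", "+", (0, 100), ((50, 40),), 10)
        with pytest.raises(AnnotationError):  # exon outside span
            GeneModel("g", "chr1", "+", (0, 100), ((50, 150),), 10)
        with pytest.raises(AnnotationError):  # overlapping exons
            GeneModel("g", "chr1", "+", (0, 200), ((0, 60), (50, 100)), 10)


class TestShowCoords:
    def test_field_mapping_and_inversion(self, tmp_path):
        text = (
            "1\t1000\t501\t1500\t1000\t1000\t99.0\tchrA\tchrB\n"
            "2001\t3000\t1500\t501\t1000\t1000\t98.0\tchrA\tchrB\n"
        )
        p = tmp_path / "x.coords"
        p.write_text(text)
        blocks = read_show_coords(str(p))
        assert blocks[0].ref_interval == (0, 1000)
        assert blocks[0].qry_interval == (500, 1500)
        assert blocks[0].orientation == "same"
        assert blocks[1].qry_interval == (500, 1500)
        assert blocks[1].orientation == "inverted"

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "h.coords"
        p.write_text("NUCMER\n\n[S1] [E1] [S2] [E2]\n===========\n")
        assert read_show_coords(str(p)) == []

    def test_non_numeric_row_is_error_with_line_number(self, tmp_path):
        p = tmp_path / "bad.coords"
        p.write_text("1\t1000\t501\t1500\t1\t1\t99\tA\tB\nfoo\tbar\tbaz\tqux\tx\n")
        with pytest.raises(AnnotationError, match=":2"):
            read_show_coords(str(p))


class TestBlastTab:
    MAP = {"tA": "geneA", "tB": "geneB"}

    def row(self, sstart, send, evalue="1e-50"):
        return f"tA\ttB\t99.0\t400\t1\t0\t1\t400\t{sstart}\t{send}\t{evalue}\t800\n"

    def test_field_mapping(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.row(10, 500))
        (hit,) = read_blast_tab(str(p), self.MAP)
        assert (hit.query_gene, hit.subject_gene) == ("geneA", "geneB")
        assert hit.subject_interval == (9, 500)

    def test_reversed_subject_coordinates_normalized(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.row(500, 10))
        (hit,) = read_blast_tab(str(p), self.MAP)
        assert hit.subject_interval == (9, 500)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert read_blast_tab(str(p), self.MAP) == []

    def test_unknown_transcript_is_error(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.row(10, 500).replace("tB", "tZ"))
        with pytest.raises(AnnotationError, match="tZ"):
            read_blast_tab(str(p), self.MAP)
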