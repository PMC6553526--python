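"""Coordinate conventions, parsers, isoform selection and liftover."""

import numpy as np
import pytest

from sixma import synthetic_data as sd
from sixma.core_io import (
    AlignmentBlock,
    AnnotationSet,
    GenomePosition,
    Interval,
    LiftoverMap,
    SiteSet,
    Transcript,
    read_annotations,
    read_gene_models,
    read_bed_intervals,
    read_position_table,
    select_longest_isoform,
    write_gff3,
    write_position_table,
)

HEADER = "contig\tpos\tstrand\tbase\tcoverage\tprm\n"


class TestPositionTable:
    def test_parses_basic_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(HEADER + "chr2L\t100\t+\tA\t25\t82.0\n")
        df = read_position_table(path)
        assert len(df) == 1
        assert df.loc[0, "pos"] == 100
        assert df.loc[0, "prm"] == pytest.approx(82.0)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(HEADER)
        assert len(read_position_table(path)) == 0

    @pytest.mark.parametrize(
        "row, fragment",
        [
            ("chr2L\t100\t+\tA\t25\t101", "prm"),
            ("chr2L\t-5\t+\tA\t25\t10", "pos"),
            ("chr2L\t100\t+\tG\t25\t10", "base"),
            ("chr2L\t100\t*\tA\t25\t10", "strand"),
            ("chr2L\t100\t+\tA\t-1\t10", "coverage"),
            ("chr2L\t100\t+\tA\t\t10", "missing"),
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, row, fragment):
        path = tmp_path / "t.tsv"
        path.write_text(HEADER + "chr2L\t1\t+\tA\t20\t5\n" + row + "\n")
        with pytest.raises(ValueError, match="line 3"):
            read_position_table(path)

    def test_round_trip_preserves_order_and_values(self, tmp_path, tables):
        rep1 = tables[0].head(500)
        path = tmp_path / "rt.tsv"
        write_position_table(rep1, path)
        back = read_position_table(path)
        assert list(back["pos"]) == list(rep1["pos"])
        np.testing.assert_allclose(back["prm"], rep1["prm"], rtol=1e-5)


def _t(tid, exons, strand="+", gene="g1"):
    return Transcript(id=tid, gene_id=gene, contig="c1", strand=strand,
                      exons=tuple(exons))


class TestIsoformSelection:
    def test_picks_greatest_summed_exon_length(self):
        short = _t("RA", [(0, 400), (500, 1000)])  # 900
        long = _t("RB", [(0, 600), (700, 1300)])  # 1200
        assert select_longest_isoform([short, long]) is long

    def test_single_isoform_is_itself(self):
        t = _t("RA", [(0, 100)])
        assert select_longest_isoform([t]) is t

    def test_tie_broken_by_smallest_id(self):
        ta = _t("RA", [(0, 100)])
        tb = _t("RB", [(50, 150)])
        assert select_longest_isoform([tb, ta]).id == "RA"

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            select_longest_isoform([])


GFF = """##gff-version 3
##sequence-region c1 1 10000
c1\tx\tgene\t1\t100\t.\t+\t.\tID=gplus
c1\tx\tmRNA\t1\t100\t.\t+\t.\tID=gplus.t1;Parent=gplus
c1\tx\texon\t1\t50\t.\t+\t.\tParent=gplus.t1
c1\tx\texon\t81\t100\t.\t+\t.\tParent=gplus.t1
c1\tx\tgene\t5000\t6000\t.\t-\t.\tID=gminus
c1\tx\tmRNA\t5000\t6000\t.\t-\t.\tID=gminus.t1;Parent=gminus
c1\tx\texon\t5000\t6000\t.\t-\t.\tParent=gminus.t1
"""


class TestGffConventions:
    def test_one_based_closed_to_half_open(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF)
        ann = read_annotations(path)
        assert ann.genes["gplus"].start == 0
        assert ann.genes["gplus"].end == 100
        assert ann.contig_lengths == {"c1": 10000}

    def test_intron_is_gap_between_exons(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF)
        ann = read_annotations(path)
        introns = [
            (iv.start, iv.end) for iv in ann.intervals("intron") if iv.strand == "+"
        ]
        assert introns == [(50, 80)]

    def test_minus_strand_upstream_window(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF)
        ann = read_annotations(path)
        ups = [
            (iv.start, iv.end)
            for iv in ann.intervals("upstream1kb")
            if iv.strand == "-"
        ]
        assert ups == [(6000, 7000)]

    def test_upstream_clipped_at_contig_edges(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF)
        ann = read_annotations(path)
        ups = [
            (iv.start, iv.end)
            for iv in ann.intervals("upstream1kb")
            if iv.strand == "+"
        ]
        assert ups == []  # TSS at 0: window would be empty after clipping

    def test_end_before_start_errors(self, tmp_path):
        bad = GFF + "c1\tx\tgene\t50\t40\t.\t+\t.\tID=bad\n"
        path = tmp_path / "bad.gff3"
        path.write_text(bad)
        with pytest.raises((ValueError, Exception)):
            ann = read_annotations(path)
            assert "bad" not in ann.genes  # either parse error or rejected

    def test_write_read_round_trip(self, tmp_path, genome):
        ann, lengths = genome
        path = tmp_path / "rt.gff3"
        write_gff3(ann.gene_models, lengths, path)
        models, lengths_back = read_gene_models(path)
        assert lengths_back == lengths
        orig = {gm.gene_id: gm for gm in ann.gene_models}
        assert set(orig) == {gm.gene_id for gm in models}
        for gm in models:
            t_orig = orig[gm.gene_id].transcripts[0]
            t_back = gm.transcripts[0]
            assert t_back.exons == t_orig.exons
            assert t_back.cds == t_orig.cds
            assert t_back.strand == t_orig.strand

    def test_exons_and_introns_partition_span(self, genome):
        ann, _ = genome
        for gm in ann.gene_models:
            t = gm.transcripts[0]
            pieces = sorted([*t.exons, *t.introns()])
            assert pieces[0][0] == t.span[0] and pieces[-1][1] == t.span[1]
            for (s0, e0), (s1, e1) in zip(pieces, pieces[1:]):
                assert e0 == s1  # no gap, no overlap


class TestBed:
    def test_unknown_contig_errors(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("nowhere\t10\t20\n")
        with pytest.raises(ValueError, match="unknown contig"):
            read_bed_intervals(path, "simple_repeat", {"c1": 100})

    def test_siteset_bed_round_trip(self, tmp_path):
        sites = SiteSet.from_records(
            ["c1", "c1", "c2"], [5, 17, 3], ["+", "-", "+"]
        )
        path = tmp_path / "s.bed"
        sites.to_bed(path)
        back = SiteSet.read_bed(path)
        assert len(back) == 3
        assert ("c1", 17) in back and ("c2", 3) in back

    def test_siteset_identity_is_contig_pos(self):
        sites = SiteSet.from_records(["c1", "c1"], [5, 5], ["+", "-"])
        assert len(sites) == 1  # A/+ and T/- at one coordinate are one site


class TestAnnotationSetQueries:
    def test_point_query_agrees_with_vectorized_membership(self, genome):
        ann, lengths = genome
        rng = np.random.default_rng(0)
        contig = sorted(lengths)[0]
        pos = rng.integers(0, lengths[contig], 300)
        for category in ("CDS", "intron", "TE", "simple_repeat"):
            member = ann.membership(
                category, np.full(300, contig, dtype=object), pos
            )
            for p, m in zip(pos[:50], member[:50]):
                assert bool(ann.overlapping(contig, int(p), category)) == bool(m)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Interval("c1", 10, 10, "CDS")
        with pytest.raises(ValueError):
            Interval("c1", -1, 5, "CDS")
        with pytest.raises(ValueError):
            Interval("c1", 0, 5, "not_a_category")

    def test_unknown_contig_interval_rejected(self):
        ann = AnnotationSet(contig_lengths={"c1": 100})
        with pytest.raises(KeyError):
            ann.add(Interval("c9", 0, 10, "CDS"))


class TestLiftover:
    def _map(self):
        return LiftoverMap(
            [
                AlignmentBlock("c1", 100, 200, "s1", 1000, 1100, "same"),
                AlignmentBlock("c1", 300, 400, "s1", 2000, 2100, "flipped"),
            ]
        )

    def test_same_orientation_offset(self):
        q = self._map().map_position(GenomePosition("c1", 150))
        assert (q.contig, q.pos, q.strand) == ("s1", 1050, "+")

    def test_flipped_block_reverses_and_inverts_strand(self):
        m = LiftoverMap([AlignmentBlock("c1", 100, 200, "s1", 1000, 1100, "flipped")])
        q = m.map_position(GenomePosition("c1", 150, "+"))
        assert (q.contig, q.pos, q.strand) == ("s1", 1049, "-")
        # bijectivity: the 100 source positions map onto exactly [1000, 1100)
        images = {m.map_position(GenomePosition("c1", p)).pos for p in range(100, 200)}
        assert images == set(range(1000, 1100))

    def test_outside_any_block_is_absent(self):
        assert self._map().map_position(GenomePosition("c1", 250)) is None
        assert self._map().map_position(GenomePosition("c9", 150)) is None

    def test_round_trip_is_identity(self):
        m = self._map()
        inv = m.inverted()
        for p in [100, 150, 199, 300, 355, 399]:
            q = m.map_position(GenomePosition("c1", p, "+"))
            back = inv.map_position(q)
            assert (back.contig, back.pos, back.strand) == ("c1", p, "+")

    def test_simulated_map_round_trip(self, small_cfg):
        lengths = {"c1": 150_000}
        m = sd.simulate_liftover_map(lengths, small_cfg)
        inv = m.inverted()
        rng = np.random.default_rng(1)
        for p in rng.integers(0, 150_000, 500):
            q = m.map_position(GenomePosition("c1", int(p)))
            assert q is not None  # source fully covered
            back = inv.map_position(q)
            assert (back.contig, back.pos) == ("c1", int(p))

    def test_overlapping_source_blocks_rejected(self):
        with pytest.raises(ValueError):
            LiftoverMap(
                [
                    AlignmentBlock("c1", 0, 100, "s1", 0, 100, "same"),
                    AlignmentBlock("c1", 50, 150, "s1", 200, 300, "same"),
                ]
            )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            AlignmentBlock("c1", 0, 100, "s1", 0, 99, "same")

    def test_tsv_round_trip(self, tmp_path):
        m = self._map()
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = LiftoverMap.read_tsv(path)
        assert back.blocks == m.blocks
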