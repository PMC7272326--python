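"""Junction table parsing, abnormal-junction thresholds, and PSI."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicedx.junction_analysis import (
    JunctionParseError,
    JunctionRecord,
    call_abnormal_junctions,
    compute_psi,
    read_junctions,
)


class TestReaders:
    def test_star_row_maps_to_inclusive_intron(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t101\t200\t1\t1\t1\t7\t0\t30\n")
        (rec,) = read_junctions(p, "star_sj")
        assert (rec.chrom, rec.intron_start, rec.intron_end) == ("chr1", 101, 200)
        assert rec.unique_reads == 7 and rec.strand == "+" and rec.annotated

    def test_bed12_gap_equals_star_intron(self, tmp_path):
        """The same junction in both dialects yields identical records."""
        star = tmp_path / "sj.tab"
        star.write_text("chr1\t101\t200\t0\t0\t0\t7\t0\t30\n")
        bed = tmp_path / "j.bed"
        bed.write_text(
            "chr1\t0\t300\tjx\t7\t.\t0\t300\t0\t2\t100,100,\t0,200,\n"
        )
        assert read_junctions(star, "star_sj") == read_junctions(bed, "junction_bed")

    def test_multi_block_bed_emits_every_gap(self, tmp_path):
        bed = tmp_path / "j.bed"
        bed.write_text("chr2\t1000\t1600\tjx\t12\t+\t1000\t1600\t0\t3\t100,100,100\t0,250,500\n")
        recs = read_junctions(bed, "junction_bed")
        assert [(r.intron_start, r.intron_end) for r in recs] == [(1101, 1250), (1351, 1500)]
        assert all(r.unique_reads == 12 for r in recs)

    def test_empty_file_returns_empty_list(self, tmp_path):
        p = tmp_path / "empty.tab"
        p.write_text("")
        assert read_junctions(p, "star_sj") == []

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t101\t200\t1\t1\t1\t7\t0",            # 8 columns
            "chr1\tx\t200\t1\t1\t1\t7\t0\t30",          # non-integer
            "chr1\t300\t200\t1\t1\t1\t7\t0\t30",        # end < start
            "chr1\t101\t200\t9\t1\t1\t7\t0\t30",        # bad strand code
        ],
    )
    def test_malformed_star_line_numbered_error(self, tmp_path, line):
        p = tmp_path / "bad.tab"
        p.write_text(line + "\n")
        with pytest.raises(JunctionParseError, match=r":1:"):
            read_junctions(p, "star_sj")


def _ann_junctions(tm, reads=100):
    return [
        JunctionRecord(tm.chrom, min(lo, hi), max(lo, hi), tm.strand, reads, annotated=True)
        for lo, hi in tm.introns()
    ]


class TestAbnormalCalling:
    def _novel(self, tm, shift, reads):
        lo, hi = sorted(tm.introns()[0])
        return JunctionRecord(tm.chrom, lo + shift, hi, tm.strand, reads)

    def test_below_read_threshold_fails(self, toy_plus):
        calls = call_abnormal_junctions(
            _ann_junctions(toy_plus, 100) + [self._novel(toy_plus, 11, 2)], toy_plus
        )
        (c,) = calls
        assert not c.passes and c.junction.unique_reads == 2

    def test_below_relative_support_fails(self, toy_plus):
        # 4 / (4 + 100) = 0.0385 < 5%
        calls = call_abnormal_junctions(
            _ann_junctions(toy_plus, 100) + [self._novel(toy_plus, 11, 4)], toy_plus
        )
        (c,) = calls
        assert c.relative_support == pytest.approx(4 / 104)
        assert not c.passes

    def test_passing_call(self, toy_plus):
        # 3 / (3 + 10) = 0.231 >= 5% and 3 reads exactly at the threshold
        calls = call_abnormal_junctions(
            _ann_junctions(toy_plus, 10) + [self._novel(toy_plus, 11, 3)], toy_plus
        )
        (c,) = calls
        assert c.relative_support == pytest.approx(3 / 13)
        assert c.passes

    def test_boundaries_are_inclusive(self, toy_plus):
        # exactly 3 reads and exactly 5% relative support both pass
        novel = self._novel(toy_plus, 11, 3)
        ann = _ann_junctions(toy_plus, 57)  # 3/60 = 0.05
        (c,) = call_abnormal_junctions(ann + [novel], toy_plus)
        assert c.relative_support == pytest.approx(0.05)
        assert c.passes

    def test_partner_shares_donor_before_acceptor(self, toy_plus):
        lo0, hi0 = sorted(toy_plus.introns()[0])
        novel = JunctionRecord(toy_plus.chrom, lo0, hi0 - 7, "+", 10)  # shares donor with intron 1
        (c,) = call_abnormal_junctions(_ann_junctions(toy_plus, 40) + [novel], toy_plus)
        assert c.canonical_partner is not None
        assert (c.canonical_partner.intron_start, c.canonical_partner.intron_end) == (lo0, hi0)

    def test_orphan_junction_flagged(self, toy_plus):
        elo, ehi = sorted(toy_plus.exons[1])
        inside = JunctionRecord(toy_plus.chrom, elo + 5, elo + 20, "+", 6)
        calls = call_abnormal_junctions([inside], toy_plus)
        (c,) = calls
        assert c.orphan and c.relative_support == 1.0 and c.passes

    def test_annotated_junctions_never_called(self, toy_plus):
        assert call_abnormal_junctions(_ann_junctions(toy_plus), toy_plus) == []

    @settings(max_examples=50, deadline=None)
    @given(reads=st.integers(0, 50), more=st.integers(0, 50))
    def test_monotone_in_novel_reads(self, toy_plus, reads, more):
        """Raising a novel junction's count never flips passes true -> false."""
        ann = _ann_junctions(toy_plus, 40)
        low = call_abnormal_junctions(ann + [self._novel(toy_plus, 11, reads)], toy_plus)[0]
        high = call_abnormal_junctions(ann + [self._novel(toy_plus, 11, reads + more)], toy_plus)[0]
        assert high.passes or not low.passes


class TestPsi:
    def test_exon_skipping_arithmetic(self):
        psi = compute_psi([20, 20], [80])
        assert psi.psi == pytest.approx(0.20)

    @pytest.mark.parametrize(
        "inc, exc, expected",
        [([5], [5], 0.5), ([7], [0], 1.0), ([0], [7], 0.0)],
    )
    def test_boundaries(self, inc, exc, expected):
        assert compute_psi(inc, exc).psi == pytest.approx(expected)

    def test_all_zero_flagged_undefined(self):
        psi = compute_psi([0, 0], [0])
        assert not psi.defined and psi.psi is None

    @settings(max_examples=100, deadline=None)
    @given(
        inc=st.lists(st.integers(0, 500), min_size=1, max_size=4),
        exc=st.lists(st.integers(0, 500), min_size=1, max_size=4),
    )
    def test_complement_identity(self, inc, exc):
        """PSI(inc, exc) + PSI(exc, inc) = 1 whenever defined."""
        a, b = compute_psi(inc, exc), compute_psi(exc, inc)
        if a.defined:
            assert a.psi + b.psi == pytest.approx(1.0)
            assert 0.0 <= a.psi <= 1.0
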