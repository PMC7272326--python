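"""Coordinate arithmetic, HGVS parsing, splice-region windows and PWMs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicedx.synthetic_data import make_transcript
from splicedx.transcript_model import (
    CoordinateError,
    CPosition,
    CVariant,
    HgvsParseError,
    UnsupportedHgvsError,
    build_pwm,
    c_to_genomic,
    genomic_to_c,
    label_genomic_position,
    parse_hgvs_c,
    splice_region_label,
)


class TestHgvsParsing:
    @pytest.mark.parametrize(
        "text, base, offset, ref, alt",
        [
            ("c.915+10G>A", 915, 10, "G", "A"),
            ("c.1224-80G>A", 1224, -80, "G", "A"),
            ("c.417C>T", 417, 0, "C", "T"),
            ("c.414+1G>A", 414, 1, "G", "A"),
            ("c.5153-26A>G", 5153, -26, "A", "G"),
            ("c.4868C>G", 4868, 0, "C", "G"),
        ],
    )
    def test_substitutions(self, text, base, offset, ref, alt):
        v = parse_hgvs_c(text)
        assert v.position == CPosition(base, offset)
        assert (v.ref_allele, v.alt_allele, v.span) == (ref, alt, 1)

    @pytest.mark.parametrize(
        "text, base, span, alt",
        [
            ("c.100_105del", 100, 6, ""),
            ("c.100del", 100, 1, ""),
            ("c.100_102delinsAT", 100, 3, "AT"),
            ("c.100_102delTAG", 100, 3, ""),
        ],
    )
    def test_deletion_forms(self, text, base, span, alt):
        v = parse_hgvs_c(text)
        assert v.position.exonic_base == base
        assert v.span == span
        assert v.alt_allele == alt

    @pytest.mark.parametrize("bad", ["c.100G>G", "c.abcG>A", "g.100G>A", "c.100_99delX"])
    def test_malformed_raises_parse_error(self, bad):
        with pytest.raises((HgvsParseError, ValueError)):
            parse_hgvs_c(bad)

    @pytest.mark.parametrize("bad", ["c.100dupG", "c.100_105inv", "c.100G>A;c.101C>T"])
    def test_unsupported_forms_are_explicit(self, bad):
        with pytest.raises((UnsupportedHgvsError, HgvsParseError)):
            parse_hgvs_c(bad)

    def test_del_length_mismatch_rejected(self):
        with pytest.raises(HgvsParseError):
            parse_hgvs_c("c.100_102delTAGG")


class TestCoordinateMapping:
    def test_first_coding_base_plus_strand(self, toy_plus):
        assert c_to_genomic(CPosition(1), toy_plus) == toy_plus.exons[0][0]

    def test_first_coding_base_minus_strand(self, toy_minus):
        assert c_to_genomic(CPosition(1), toy_minus) == toy_minus.exons[0][1]

    def test_intron_offset_steps_in_transcript_orientation(self, toy_both):
        # D+1 is the base immediately after the first exon's last base
        last_exon1 = 100
        g_exonic = c_to_genomic(CPosition(last_exon1), toy_both)
        g_plus1 = c_to_genomic(CPosition(last_exon1, 1), toy_both)
        step = 1 if toy_both.strand == "+" else -1
        assert g_plus1 == g_exonic + step

    def test_exhaustive_round_trip(self, toy_both):
        """c -> genomic -> c is the identity over every position of the toy."""
        tm = toy_both
        for base in range(1, tm.length + 1):
            pos = CPosition(base)
            assert genomic_to_c(c_to_genomic(pos, tm), tm) == pos
        # every intronic base round-trips through the genomic map too
        for ilo, ihi in tm.introns():
            for g in range(min(ilo, ihi), max(ilo, ihi) + 1):
                assert c_to_genomic(genomic_to_c(g, tm), tm) == g

    def test_out_of_range_rejected(self, toy_plus):
        with pytest.raises(CoordinateError):
            c_to_genomic(CPosition(10_000), toy_plus)
        with pytest.raises(CoordinateError):
            # +offset anchored away from an exon boundary
            c_to_genomic(CPosition(5, 3), toy_plus)
        with pytest.raises(CoordinateError):
            # offset beyond the intron
            c_to_genomic(CPosition(100, 51), toy_plus)

    @settings(max_examples=40, deadline=None)
    @given(
        strand=st.sampled_from("+-"),
        exon_lens=st.lists(st.integers(10, 60), min_size=2, max_size=6),
        seed=st.integers(0, 10_000),
    )
    def test_round_trip_random_transcripts(self, strand, exon_lens, seed):
        rng = np.random.default_rng(seed)
        intron_lens = [int(rng.integers(20, 100)) for _ in range(len(exon_lens) - 1)]
        tm = make_transcript("R", "chrR", strand, exon_lens, intron_lens)
        for base in rng.integers(1, tm.length + 1, size=25):
            pos = CPosition(int(base))
            assert genomic_to_c(c_to_genomic(pos, tm), tm) == pos


def _oracle_label(g, tm):
    """Independent interval-arithmetic oracle for the splice-region windows.

    Enumerates the donor/acceptor windows as explicit genomic position
    sets straight from the exon intervals, with no shared code with
    label_genomic_position.
    """
    step = 1 if tm.strand == "+" else -1
    donor, acceptor = {}, {}
    for i, (lo, hi) in enumerate(tm.exons):
        end3 = hi if tm.strand == "+" else lo   # 3' (donor-side) exon edge
        start5 = lo if tm.strand == "+" else hi
        if i < len(tm.exons) - 1:
            for k in range(1, 4):
                donor.setdefault(end3 - step * (k - 1), -k)
            for k in range(1, 9):
                donor.setdefault(end3 + step * k, k)
        if i > 0:
            for k in range(1, 4):
                acceptor.setdefault(start5 + step * (k - 1), k)
            for k in range(1, 9):
                acceptor.setdefault(start5 - step * k, -k)
    exonic = {p for lo, hi in tm.exons for p in range(lo, hi + 1)}
    if g in donor and g in acceptor:
        # overlapping windows in short exons/introns: nearer junction wins,
        # ties toward the donor
        dd = abs(donor[g]) if donor[g] > 0 else abs(donor[g])
        da = abs(acceptor[g])
        return ("donor", donor[g]) if dd <= da else ("acceptor", acceptor[g])
    if g in donor:
        return ("donor", donor[g])
    if g in acceptor:
        return ("acceptor", acceptor[g])
    return ("deep_exonic", None) if g in exonic else ("deep_intronic", None)


class TestSpliceRegionLabel:
    def test_partition_matches_interval_oracle(self, toy_both):
        """Every footprint base gets exactly one label, equal to the oracle's."""
        tm = toy_both
        lo, hi = tm.span
        for g in range(lo, hi + 1):
            lab = label_genomic_position(g, tm)
            region, offset = _oracle_label(g, tm)
            assert (lab.region, lab.offset) == (region, offset), f"position {g}"

    @pytest.mark.parametrize(
        "case_name, expected_code",
        [
            ("DCTN1_constitutive_skipping", "D+1"),
            ("DKC1_novel_intronic_donor", "deep_intronic"),
            ("BRCA1_downstream_exon_skipping", "deep_intronic"),
        ],
    )
    def test_worked_examples(self, worked_cases, case_name, expected_code):
        fx = worked_cases[case_name]
        lab = splice_region_label(fx.variant, fx.transcript)
        assert lab.code == expected_code

    def test_canonical_positions(self, toy_plus):
        v = parse_hgvs_c("c.100+1A>G")
        assert splice_region_label(v, toy_plus).canonical
        v = parse_hgvs_c("c.101-2A>G")
        lab = splice_region_label(v, toy_plus)
        assert lab.canonical and lab.code == "A-2"

    def test_third_last_exon_base_is_donor_minus_3(self, toy_both):
        v = parse_hgvs_c("c.98A>G")  # exon 1 spans c.1-100
        assert splice_region_label(v, toy_both).code == "D-3"

    def test_multinucleotide_takes_proximal_base(self, toy_plus):
        # c.96_99del spans D-5..D-2: most proximal base is D-2
        v = parse_hgvs_c("c.96_99del")
        lab = splice_region_label(v, toy_plus)
        assert (lab.region, lab.offset, lab.from_span) == ("donor", -2, True)

    def test_terminal_exons_use_single_junction(self, toy_plus):
        # last base of the transcript: no donor side, not near an acceptor
        v = CVariant(CPosition(toy_plus.length), "A", "G")
        assert splice_region_label(v, toy_plus).region == "deep_exonic"


class TestPwm:
    def test_identical_sequences_one_hot(self):
        m = build_pwm(["GTAAGT"] * 10)
        assert np.allclose(m.to_numpy().sum(axis=0), 1.0)
        assert m.loc["G", 1] == 1.0 and m.loc["T", 2] == 1.0

    def test_hand_count_gt_gc(self):
        m = build_pwm(["GT", "GC"])
        assert m.loc["G", 1] == 1.0
        assert m.loc["T", 2] == 0.5 and m.loc["C", 2] == 0.5

    def test_columns_normalized_random_input(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 22)) for _ in range(50)]
        m = build_pwm(seqs, side="donor")
        assert np.allclose(m.to_numpy().sum(axis=0), 1.0, atol=1e-12)

    def test_pseudocount_zero_one_hot_idempotent(self):
        m1 = build_pwm(["ACGT"] * 5, pseudocount=0)
        m2 = build_pwm(["ACGT"] * 5, pseudocount=0)
        assert np.array_equal(m1.to_numpy(), m2.to_numpy())
        assert set(np.unique(m1.to_numpy())) == {0.0, 1.0}

    @pytest.mark.parametrize("bad", [[], ["ACGT", "ACG"], ["ACGN"]])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            build_pwm(bad)
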