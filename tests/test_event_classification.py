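"""Event taxonomy, transcript-level consequences, IR and the constitutive filter."""

import numpy as np
import pytest

from splicedx.event_classification import (
    call_intron_retention,
    classify_event,
    cohort_summary,
    constitutive_exon_filter,
    ir_event,
    suppress_constitutive,
    SpliceEvent,
    VariantSplicingResult,
)
from splicedx.junction_analysis import (
    AbnormalJunctionCall,
    JunctionRecord,
    call_abnormal_junctions,
)
from splicedx.pipeline import analyze_variant
from splicedx.synthetic_data import make_transcript
from splicedx.transcript_model import SpliceRegionLabel, parse_hgvs_c


def _call(tm, lo, hi, reads=10, partner=None):
    return AbnormalJunctionCall(
        junction=JunctionRecord(tm.chrom, lo, hi, tm.strand, reads),
        canonical_partner=partner,
        relative_support=1.0 if partner is None else reads / (reads + partner.unique_reads),
        passes=True,
        orphan=partner is None,
    )


def _delta_oracle(tm, lo, hi):
    """Independent set-arithmetic oracle for delta_nt.

    Builds the mature transcript as explicit genomic position sets: the
    aberrant isoform removes the novel span plus every annotated intron
    not touching it; delta is the length difference vs the annotated
    isoform.
    """
    span_lo, span_hi = tm.span
    footprint = set(range(span_lo, span_hi + 1))
    introns = [set(range(min(a, b), max(a, b) + 1)) for a, b in tm.introns()]
    novel = set(range(lo, hi + 1))
    annotated_mature = footprint - set().union(*introns)
    removed = novel | set().union(*(i for i in introns if not (i & novel)))
    aberrant_mature = footprint - removed
    return len(aberrant_mature) - len(annotated_mature)


class TestWorkedExamples:
    """The six published illustrative cases, run through the full pipeline."""

    @pytest.mark.parametrize(
        "name",
        [
            "DKC1_novel_intronic_donor",
            "P3H1_multiple_abnormalities",
            "DCTN1_constitutive_skipping",
            "BRCA1_exonic_cryptic_donor",
            "BRCA1_downstream_exon_skipping",
            "SF3B4_exitron",
        ],
    )
    def test_fixture_classifies_as_published(self, worked_cases, name):
        fx = worked_cases[name]
        res = analyze_variant(
            fx.name, fx.transcript, fx.variant, fx.patient_junctions,
            coverage=fx.coverage, control_junctions=fx.control_junctions,
        )
        got = sorted(
            (e.event_type, e.delta_nt, e.frame_effect) for e in res.events
        )
        want = sorted(
            (e["event_type"], e["delta_nt"], e["frame_effect"])
            for e in fx.expected["events"]
        )
        assert got == want

    def test_dkc1_psi_is_20_percent(self, worked_cases):
        fx = worked_cases["DKC1_novel_intronic_donor"]
        res = analyze_variant(fx.name, fx.transcript, fx.variant, fx.patient_junctions)
        (event,) = res.events
        assert event.psi.psi == pytest.approx(0.20)

    def test_p3h1_has_multiple_abnormalities(self, worked_cases):
        fx = worked_cases["P3H1_multiple_abnormalities"]
        res = analyze_variant(
            fx.name, fx.transcript, fx.variant, fx.patient_junctions, coverage=fx.coverage
        )
        assert res.multiple_abnormalities and len(res.events) >= 3


class TestClassifyEvent:
    def test_se_upstream_by_definition(self, toy_plus):
        """Junction from exon 1 donor to exon 3 acceptor with the variant at
        exon 2's D+5 skips exon 2 as an upstream event."""
        lo = sorted(toy_plus.introns()[0])[0]
        hi = sorted(toy_plus.introns()[1])[1]
        v = parse_hgvs_c("c.160+5G>A")  # exon 2 is c.101-160
        e = classify_event(_call(toy_plus, lo, hi), toy_plus, v)
        assert e.event_type == "SE_upstream"
        assert e.skipped_exons == (2,)
        assert e.delta_nt == -60 and e.frame_effect == "in_frame"

    def test_se_downstream_when_variant_acceptor_proximal(self, toy_plus):
        lo = sorted(toy_plus.introns()[0])[0]
        hi = sorted(toy_plus.introns()[1])[1]
        v = parse_hgvs_c("c.101-5G>A")
        e = classify_event(_call(toy_plus, lo, hi), toy_plus, v)
        assert e.event_type == "SE_downstream"

    def test_delta_matches_set_arithmetic_oracle(self, toy_both):
        """delta_nt equals the transcript-reconstruction oracle on random junctions."""
        tm = toy_both
        rng = np.random.default_rng(5)
        span_lo, span_hi = tm.span
        v = parse_hgvs_c("c.100+5G>A")
        checked = 0
        while checked < 60:
            lo = int(rng.integers(span_lo, span_hi - 10))
            hi = int(rng.integers(lo + 5, span_hi))
            try:
                e = classify_event(_call(tm, lo, hi), tm, v)
            except Exception:
                continue
            assert e.delta_nt == _delta_oracle(tm, lo, hi)
            checked += 1

    @pytest.mark.parametrize("delta", range(-200, 201))
    def test_frame_effect_is_mod3(self, delta):
        e = SpliceEvent(
            event_type="A5SS",
            delta_nt=delta,
            frame_effect="frameshift" if delta % 3 else "in_frame",
        )
        assert (e.frame_effect == "in_frame") == (delta % 3 == 0)

    def test_inconsistent_frame_rejected(self):
        with pytest.raises(ValueError):
            SpliceEvent(event_type="A5SS", delta_nt=10, frame_effect="in_frame")

    def test_annotated_intron_not_classifiable(self, toy_plus):
        lo, hi = sorted(toy_plus.introns()[0])
        v = parse_hgvs_c("c.100+5G>A")
        with pytest.raises(Exception):
            classify_event(_call(toy_plus, lo, hi), toy_plus, v)


class TestIntronRetention:
    @pytest.mark.parametrize(
        "intron_median, exon_median, expect",
        [(0, 100, "none"), (6, 100, "retained"), (4, 100, "none"), (5, 100, "retained")],
    )
    def test_thresholds(self, intron_median, exon_median, expect):
        r = call_intron_retention([intron_median] * 11, [exon_median] * 11)
        assert r.status == expect

    def test_absolute_read_floor(self):
        # 2 reads is 20% of a depth-10 exon but below the 3-read floor
        assert call_intron_retention([2] * 11, [10] * 11).status == "none"

    def test_missing_coverage_not_assessable(self):
        assert call_intron_retention(None, [100]).status == "not_assessable"
        assert call_intron_retention([], [100]).status == "not_assessable"

    def test_ir_event_delta_is_intron_length(self, toy_plus):
        e = ir_event(1, toy_plus)
        assert e.event_type == "IR" and e.delta_nt == 50
        assert e.frame_effect == "frameshift"


class TestConstitutiveFilter:
    def _skip_table(self, tm, skip_reads, inclusion_reads):
        lo = sorted(tm.introns()[0])[0]
        hi = sorted(tm.introns()[1])[1]
        table = []
        if inclusion_reads:
            table += [
                JunctionRecord(tm.chrom, a, b, tm.strand, inclusion_reads, annotated=True)
                for a, b in (sorted(iv) for iv in tm.introns())
            ]
        if skip_reads:
            table.append(JunctionRecord(tm.chrom, lo, hi, tm.strand, skip_reads))
        return table

    def test_fully_skipped_in_all_controls_masks(self, toy_plus):
        controls = [self._skip_table(toy_plus, 100, 0), self._skip_table(toy_plus, 90, 0)]
        assert constitutive_exon_filter(toy_plus, controls) == {2}

    def test_no_skip_reads_no_mask(self, toy_plus):
        controls = [self._skip_table(toy_plus, 0, 100)]
        assert constitutive_exon_filter(toy_plus, controls) == set()

    def test_requires_all_controls(self, toy_plus):
        controls = [self._skip_table(toy_plus, 100, 0), self._skip_table(toy_plus, 0, 100)]
        assert constitutive_exon_filter(toy_plus, controls) == set()

    def test_no_controls_disables_filter(self, toy_plus):
        assert constitutive_exon_filter(toy_plus, []) == set()

    def test_suppression_drops_masked_se_only(self):
        se = SpliceEvent("SE_upstream", skipped_exons=(2,), delta_nt=-60, frame_effect="in_frame")
        a5 = SpliceEvent("A5SS", delta_nt=11, frame_effect="frameshift")
        assert suppress_constitutive([se, a5], {2}) == [a5]
        assert suppress_constitutive([se, a5], set()) == [se, a5]


class TestCohortSummary:
    def test_empty_cohort_all_zero(self):
        s = cohort_summary([], [])
        assert s["event_types"]["count"].sum() == 0
        assert s["positions"]["n_variants"].sum() == 0

    def test_single_event_distribution(self):
        res = [VariantSplicingResult("v1", [SpliceEvent("SE_upstream", skipped_exons=(2,), delta_nt=-60, frame_effect="in_frame")])]
        labs = [SpliceRegionLabel("donor", 5, canonical=False)]
        s = cohort_summary(res, labs)
        et = s["event_types"].set_index("event_type")
        assert et.loc["SE_upstream", "proportion"] == 1.0
        assert s["regions"].set_index("group").loc["all", "proportion_affecting"] == 1.0

    def test_position_tally_counts_affecting(self):
        res = [
            VariantSplicingResult("v1", [SpliceEvent("A5SS", delta_nt=4, frame_effect="frameshift")]),
            VariantSplicingResult("v2", []),
        ]
        labs = [SpliceRegionLabel("donor", 5), SpliceRegionLabel("donor", 5)]
        s = cohort_summary(res, labs)
        row = s["positions"].set_index("position").loc["D+5"]
        assert (row["n_variants"], row["n_affecting"]) == (2, 1)
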