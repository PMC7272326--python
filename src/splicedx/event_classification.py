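"""Classify passing abnormal junctions into splice events with consequences.

Event taxonomy: skipped exon (SE, split into upstream/downstream by the
variant's position relative to the skipped exon's donor vs acceptor
site), alternative 5'/3' splice site (A5SS/A3SS), intron retention (IR)
and exitron (a novel intron entirely inside one annotated exon).

The transcript-level consequence ``delta_nt`` is the net number of
nucleotides inserted into (+) or deleted from (-) the mature transcript,
computed with a single rule valid for every class:

    delta_nt = (total length of annotated introns overlapping the novel
                junction span) - (novel junction span length)

and +intron length for IR.  A frameshift is exactly delta_nt mod 3 != 0.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import pandas as pd

from .junction_analysis import AbnormalJunctionCall, JunctionRecord, PsiValue, compute_psi
from .transcript_model import (
    CVariant,
    SpliceRegionLabel,
    TranscriptModel,
    c_to_genomic,
)

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE_upstream", "SE_downstream", "A5SS", "A3SS", "IR", "exitron")

IR_MIN_FRACTION_DEFAULT = 0.05
IR_MIN_READS_DEFAULT = 3
CONSTITUTIVE_SKIP_FRACTION_DEFAULT = 0.95


class ClassificationError(ValueError):
    """Junction inconsistent with the transcript model."""


@dataclass(frozen=True)
class SpliceEvent:
    event_type: str
    junctions: tuple[AbnormalJunctionCall, ...] = ()
    skipped_exons: tuple[int, ...] = ()  # 1-based exon indices, transcript order
    delta_nt: int = 0
    frame_effect: str = "in_frame"
    psi: PsiValue | None = None
    tie_break: bool = False       # variant equidistant from donor and acceptor
    complex_ends: bool = False    # both junction ends novel, not an exitron

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        expected = "frameshift" if self.delta_nt % 3 != 0 else "in_frame"
        if self.frame_effect != expected:
            raise ValueError(
                f"frame_effect {self.frame_effect!r} inconsistent with delta_nt {self.delta_nt}"
            )
        if self.event_type.startswith("SE") and not self.skipped_exons:
            raise ValueError("SE events must carry at least one skipped exon")


@dataclass(frozen=True)
class IRResult:
    """Coverage-based intron-retention assessment for one intron."""

    status: str  # 'retained' | 'none' | 'not_assessable'
    intron_index: int | None = None
    intron_median: float | None = None
    exon_median: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("retained", "none", "not_assessable"):
            raise ValueError(f"unknown IR status {self.status!r}")


@dataclass
class VariantSplicingResult:
    variant_id: str
    events: list[SpliceEvent] = field(default_factory=list)
    ir_not_assessable: bool = False

    @property
    def splice_affecting(self) -> bool:
        return len(self.events) > 0

    @property
    def multiple_abnormalities(self) -> bool:
        return len(self.events) > 1


def _frame(delta_nt: int) -> str:
    return "frameshift" if delta_nt % 3 != 0 else "in_frame"


def _delta_nt(junction: JunctionRecord, tm: TranscriptModel) -> int:
    novel_len = junction.length
    ann = sum(
        hi - lo + 1
        for lo, hi in (tuple(sorted(iv)) for iv in tm.introns())
        if not (hi < junction.intron_start or lo > junction.intron_end)
    )
    return ann - novel_len


def classify_event(
    call: AbnormalJunctionCall,
    tm: TranscriptModel,
    v: CVariant,
) -> SpliceEvent:
    """Classify one passing abnormal junction.

    Donor/acceptor ends are checked against the transcript's annotated
    intron boundaries (strand-aware).  Both-ends-annotated junctions
    spanning one or more exons are exon skipping; one novel end is an
    alternative donor (A5SS) or acceptor (A3SS); both ends novel inside
    one exon is an exitron.  A both-ends-novel junction that is not an
    exitron is assigned to A5SS or A3SS by its larger end shift and
    flagged ``complex_ends``.
    """
    j = call.junction
    if j.chrom != tm.chrom:
        raise ClassificationError(f"junction chrom {j.chrom} != transcript chrom {tm.chrom}")
    donor_sites = tm.donor_sites()
    acceptor_sites = tm.acceptor_sites()
    j_donor = j.intron_start if tm.strand == "+" else j.intron_end
    j_acceptor = j.intron_end if tm.strand == "+" else j.intron_start
    donor_annot = j_donor in donor_sites
    acceptor_annot = j_acceptor in acceptor_sites

    delta = _delta_nt(j, tm)
    psi = None
    if call.canonical_partner is not None:
        psi = compute_psi([j.unique_reads], [call.canonical_partner.unique_reads])

    if donor_annot and acceptor_annot:
        di = donor_sites.index(j_donor)
        ai = acceptor_sites.index(j_acceptor)
        if ai == di:
            raise ClassificationError("junction matches an annotated intron; not abnormal")
        if ai < di:
            raise ClassificationError("junction donor lies downstream of its acceptor")
        skipped = tuple(range(di + 2, ai + 2))  # exons between intron di and intron ai (1-based)
        gv = c_to_genomic(v.position, tm)
        # nearest skipped exon decides the upstream/downstream assignment
        def _edges(exon_1based: int) -> tuple[int, int]:
            lo, hi = tm.exons[exon_1based - 1]
            donor_edge = hi if tm.strand == "+" else lo
            acceptor_edge = lo if tm.strand == "+" else hi
            return donor_edge, acceptor_edge

        best = min(
            skipped,
            key=lambda e: min(abs(gv - _edges(e)[0]), abs(gv - _edges(e)[1])),
        )
        donor_edge, acceptor_edge = _edges(best)
        d_don, d_acc = abs(gv - donor_edge), abs(gv - acceptor_edge)
        tie = d_don == d_acc
        if tie:
            logger.warning(
                "variant equidistant from donor and acceptor of skipped exon %d; "
                "classifying as upstream skipping", best,
            )
        etype = "SE_upstream" if d_don <= d_acc else "SE_downstream"
        return SpliceEvent(
            event_type=etype,
            junctions=(call,),
            skipped_exons=skipped,
            delta_nt=delta,
            frame_effect=_frame(delta),
            psi=psi,
            tie_break=tie,
        )

    if not donor_annot and not acceptor_annot:
        inside_one_exon = any(
            min(lo, hi) < j.intron_start and j.intron_end < max(lo, hi)
            for lo, hi in tm.exons
        )
        if inside_one_exon:
            return SpliceEvent(
                event_type="exitron",
                junctions=(call,),
                delta_nt=delta,
                frame_effect=_frame(delta),
                psi=psi,
            )
        # both ends novel across annotated structure: pick the dominant shift
        donor_shift = min(abs(j_donor - d) for d in donor_sites) if donor_sites else 0
        acceptor_shift = min(abs(j_acceptor - a) for a in acceptor_sites) if acceptor_sites else 0
        etype = "A5SS" if donor_shift >= acceptor_shift else "A3SS"
        return SpliceEvent(
            event_type=etype,
            junctions=(call,),
            delta_nt=delta,
            frame_effect=_frame(delta),
            psi=psi,
            complex_ends=True,
        )

    etype = "A5SS" if not donor_annot else "A3SS"
    return SpliceEvent(
        event_type=etype,
        junctions=(call,),
        delta_nt=delta,
        frame_effect=_frame(delta),
        psi=psi,
    )


def ir_event(intron_index_1based: int, tm: TranscriptModel, psi: PsiValue | None = None) -> SpliceEvent:
    """Intron-retention event for the given intron (1-based transcript order)."""
    lengths = tm.intron_lengths()
    if not (1 <= intron_index_1based <= len(lengths)):
        raise ClassificationError(f"transcript has no intron {intron_index_1based}")
    delta = lengths[intron_index_1based - 1]
    return SpliceEvent(
        event_type="IR",
        delta_nt=delta,
        frame_effect=_frame(delta),
        psi=psi,
    )


# ---------------------------------------------------------------------------
# intron retention from per-base coverage
# ---------------------------------------------------------------------------


def call_intron_retention(
    intron_coverage: list[float] | None,
    flanking_exon_coverage: list[float] | None,
    canonical_junction_reads: int | None = None,
    min_fraction: float = IR_MIN_FRACTION_DEFAULT,
    min_reads: int = IR_MIN_READS_DEFAULT,
    intron_index: int | None = None,
) -> IRResult:
    """Coverage-based intron-retention call.

    Retention is called iff the median intron depth reaches both
    ``min_fraction`` of the median flanking-exon depth and ``min_reads``
    absolute depth (the junction-calling thresholds reused as coverage
    thresholds).  Missing coverage yields 'not_assessable', never a
    negative call.
    """
    if not intron_coverage or not flanking_exon_coverage:
        return IRResult(status="not_assessable", intron_index=intron_index)
    med_i = statistics.median(intron_coverage)
    med_e = statistics.median(flanking_exon_coverage)
    retained = med_e > 0 and med_i >= min_fraction * med_e and med_i >= min_reads
    return IRResult(
        status="retained" if retained else "none",
        intron_index=intron_index,
        intron_median=med_i,
        exon_median=med_e,
    )


def ir_from_coverage_table(
    coverage: pd.DataFrame,
    tm: TranscriptModel,
    min_fraction: float = IR_MIN_FRACTION_DEFAULT,
    min_reads: int = IR_MIN_READS_DEFAULT,
) -> list[IRResult]:
    """Assess every fully covered intron from a (chrom, pos, depth) table."""
    results: list[IRResult] = []
    cov = coverage[coverage["chrom"] == tm.chrom]
    depth_at = dict(zip(cov["pos"].astype(int), cov["depth"].astype(float)))
    exon_positions = {
        p for lo, hi in tm.exons for p in range(min(lo, hi), max(lo, hi) + 1)
    }
    exon_depths = [depth_at[p] for p in exon_positions if p in depth_at]
    for i, iv in enumerate(tm.introns(), start=1):
        lo, hi = sorted(iv)
        positions = range(lo, hi + 1)
        if not all(p in depth_at for p in positions):
            continue  # intron not assayed in this table
        intron_depths = [depth_at[p] for p in positions]
        results.append(
            call_intron_retention(
                intron_depths,
                exon_depths,
                min_fraction=min_fraction,
                min_reads=min_reads,
                intron_index=i,
            )
        )
    return results


# ---------------------------------------------------------------------------
# constitutive-exon filter
# ---------------------------------------------------------------------------


def constitutive_exon_filter(
    tm: TranscriptModel,
    control_junction_tables: list[list[JunctionRecord]],
    skip_fraction: float = CONSTITUTIVE_SKIP_FRACTION_DEFAULT,
) -> set[int]:
    """Exons (1-based indices) that are constitutively spliced out in ALL controls.

    An exon is masked when, in every control, its skipping junctions
    dominate: skip / (skip + inclusion) >= ``skip_fraction``, where the
    inclusion evidence is the mean read count of the exon's two flanking
    annotated junctions.  With no control data the filter is disabled.
    """
    if not control_junction_tables:
        logger.warning("constitutive-exon filter disabled: no control junction tables")
        return set()
    n_exons = len(tm.exons)
    donor_sites = tm.donor_sites()
    acceptor_sites = tm.acceptor_sites()
    intron_set = {tuple(sorted(iv)) for iv in tm.introns()}
    masked: set[int] | None = None
    for table in control_junction_tables:
        table = [j for j in table if j.chrom == tm.chrom]
        this_control: set[int] = set()
        ann = {(j.intron_start, j.intron_end): j.unique_reads for j in table
               if (j.intron_start, j.intron_end) in intron_set}
        for j in table:
            if (j.intron_start, j.intron_end) in intron_set:
                continue
            j_donor = j.intron_start if tm.strand == "+" else j.intron_end
            j_acceptor = j.intron_end if tm.strand == "+" else j.intron_start
            if j_donor not in donor_sites or j_acceptor not in acceptor_sites:
                continue
            di, ai = donor_sites.index(j_donor), acceptor_sites.index(j_acceptor)
            if ai <= di:
                continue
            skipped = range(di + 2, ai + 2)
            for e in skipped:
                flank = [
                    ann.get(tuple(sorted(tm.introns()[k])), 0)
                    for k in (e - 2, e - 1)
                    if 0 <= k < n_exons - 1
                ]
                inclusion = sum(flank) / len(flank) if flank else 0.0
                denom = j.unique_reads + inclusion
                if denom > 0 and j.unique_reads / denom >= skip_fraction:
                    this_control.add(e)
        masked = this_control if masked is None else (masked & this_control)
    return masked or set()


def suppress_constitutive(
    events: list[SpliceEvent], masked_exons: set[int]
) -> list[SpliceEvent]:
    """Drop SE events whose skipped exons are all constitutively absent."""
    if not masked_exons:
        return list(events)
    kept = []
    for e in events:
        if e.event_type.startswith("SE") and set(e.skipped_exons) <= masked_exons:
            logger.info("suppressing SE event over constitutively skipped exons %s", e.skipped_exons)
            continue
        kept.append(e)
    return kept


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------


def cohort_summary(
    results: list[VariantSplicingResult],
    labels: list[SpliceRegionLabel],
    variants: list[CVariant] | None = None,
    transcripts: list[TranscriptModel] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort-level tallies: event types, splice-region positions, proportions.

    Per-position tallies count SNVs only (multinucleotide variants carry a
    span-derived label and are excluded from the position plot).  When the
    variants and their transcripts are supplied, upstream vs downstream
    intron lengths around intronic variants are reported descriptively.
    """
    if len(results) != len(labels):
        raise ValueError("results and labels must be index-aligned")

    type_counts = {t: 0 for t in EVENT_TYPES}
    n_affecting = 0
    n_multi = 0
    for r in results:
        if r.splice_affecting:
            n_affecting += 1
        if r.multiple_abnormalities:
            n_multi += 1
        for e in r.events:
            type_counts[e.event_type] += 1
    total_events = sum(type_counts.values())
    events_df = pd.DataFrame(
        {
            "event_type": list(type_counts),
            "count": list(type_counts.values()),
            "proportion": [
                c / total_events if total_events else 0.0 for c in type_counts.values()
            ],
        }
    )

    position_rows = []
    codes = [f"D{o:+d}" for o in list(range(-3, 0)) + list(range(1, 9))] + [
        f"A{o:+d}" for o in list(range(-8, 0)) + list(range(1, 4))
    ]
    counts = {c: [0, 0] for c in codes}
    for i, (r, lab) in enumerate(zip(results, labels)):
        is_snv = variants[i].is_snv if variants is not None else True
        if lab.from_span or not is_snv:
            continue
        if lab.region in ("donor", "acceptor"):
            code = lab.code
            counts[code][0] += 1
            if r.splice_affecting:
                counts[code][1] += 1
    for c in codes:
        position_rows.append({"position": c, "n_variants": counts[c][0], "n_affecting": counts[c][1]})
    positions_df = pd.DataFrame(position_rows)

    region_totals: dict[str, list[int]] = {}
    for r, lab in zip(results, labels):
        reg = lab.region
        region_totals.setdefault(reg, [0, 0])
        region_totals[reg][0] += 1
        if r.splice_affecting:
            region_totals[reg][1] += 1
    overall_rows = [
        {
            "group": reg,
            "n_variants": n,
            "n_affecting": k,
            "proportion_affecting": k / n if n else 0.0,
        }
        for reg, (n, k) in sorted(region_totals.items())
    ]
    overall_rows.append(
        {
            "group": "all",
            "n_variants": len(results),
            "n_affecting": n_affecting,
            "proportion_affecting": n_affecting / len(results) if results else 0.0,
        }
    )
    overall_df = pd.DataFrame(overall_rows)

    intron_rows = []
    if variants is not None and transcripts is not None:
        for v, tm, r in zip(variants, transcripts, results):
            if v.position.intron_offset == 0:
                continue
            gv = c_to_genomic(v.position, tm)
            for i, iv in enumerate(tm.introns()):
                lo, hi = sorted(iv)
                if lo <= gv <= hi:
                    lens = tm.intron_lengths()
                    intron_rows.append(
                        {
                            "affecting": r.splice_affecting,
                            "intron_length": lens[i],
                            "upstream_intron_length": lens[i - 1] if i > 0 else None,
                            "downstream_intron_length": lens[i + 1] if i + 1 < len(lens) else None,
                        }
                    )
                    break
    intron_df = pd.DataFrame(intron_rows)

    meta = pd.DataFrame(
        [
            {"key": "n_variants", "value": len(results)},
            {"key": "n_affecting", "value": n_affecting},
            {"key": "n_multiple_abnormalities", "value": n_multi},
        ]
    )
    return {
        "event_types": events_df,
        "positions": positions_df,
        "regions": overall_df,
        "intron_lengths": intron_df,
        "meta": meta,
    }
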