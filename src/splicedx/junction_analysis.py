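"""Splice-junction table I/O, abnormal-junction calling, and PSI.

Junction evidence comes in as either the STAR ``SJ.out.tab`` dialect
(9 tab-separated columns, intron coordinates 1-based inclusive, column 7
the uniquely-mapped read count) or a 12-column junction BED (0-based
half-open blocks; each junction is the gap between consecutive blocks).
Both are normalized to one internal convention: ``intron_start`` /
``intron_end`` are the first and last intronic bases, 1-based inclusive.

An abnormal (novel) junction is reportable when it carries at least
``min_reads`` uniquely-mapped reads (default 3) and its read support
relative to the alternative canonical junction reaches at least
``min_rel_support`` (default 5%), computed as
novel / (novel + canonical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .transcript_model import TranscriptModel

logger = logging.getLogger(__name__)

MIN_READS_DEFAULT = 3
MIN_REL_SUPPORT_DEFAULT = 0.05

_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


class JunctionParseError(ValueError):
    """Malformed junction file; message carries the 1-based line number."""


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction: first/last intronic base, 1-based inclusive."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "."
    unique_reads: int = 0
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.intron_end < self.intron_start:
            raise ValueError(f"intron_end {self.intron_end} < intron_start {self.intron_start}")
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be >= 0")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start + 1

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class AbnormalJunctionCall:
    """A novel junction scored against its canonical partner."""

    junction: JunctionRecord
    canonical_partner: JunctionRecord | None
    relative_support: float
    passes: bool
    orphan: bool = False  # no annotated partner found; support computed vs 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_support <= 1.0):
            raise ValueError("relative_support must lie in [0, 1]")


@dataclass(frozen=True)
class PsiValue:
    """Percent spliced in: inclusion / (inclusion + exclusion), length-normalized."""

    inclusion_reads_normalized: float
    exclusion_reads_normalized: float
    psi: float | None
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and self.psi is not None and not (0.0 <= self.psi <= 1.0):
            raise ValueError("psi must lie in [0, 1]")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_star_sj(path) -> list[JunctionRecord]:
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) != 9:
                raise JunctionParseError(f"{path}:{i}: expected 9 columns, found {len(cols)}")
            chrom, start, end, strand_c, _motif, annotated_c, uniq, _multi, _overhang = cols
            try:
                start_i, end_i, uniq_i = int(start), int(end), int(uniq)
            except ValueError as exc:
                raise JunctionParseError(f"{path}:{i}: non-integer coordinate or count: {exc}")
            if strand_c not in _STAR_STRAND:
                raise JunctionParseError(f"{path}:{i}: bad strand code {strand_c!r}")
            if end_i < start_i or start_i < 1:
                raise JunctionParseError(f"{path}:{i}: bad intron interval {start_i}-{end_i}")
            records.append(
                JunctionRecord(
                    chrom=chrom,
                    intron_start=start_i,
                    intron_end=end_i,
                    strand=_STAR_STRAND[strand_c],
                    unique_reads=uniq_i,
                    annotated=annotated_c == "1",
                )
            )
    return records


def _read_junction_bed(path) -> list[JunctionRecord]:
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise JunctionParseError(f"{path}:{i}: expected 12 BED columns, found {len(cols)}")
            chrom = cols[0]
            try:
                chrom_start = int(cols[1])
                score = int(float(cols[4]))
                n_blocks = int(cols[9])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise JunctionParseError(f"{path}:{i}: malformed BED12 fields: {exc}")
            strand = cols[5] if cols[5] in ("+", "-") else "."
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise JunctionParseError(
                    f"{path}:{i}: blockCount {n_blocks} disagrees with sizes/starts"
                )
            if n_blocks < 2:
                raise JunctionParseError(f"{path}:{i}: junction BED line needs >= 2 blocks")
            for b in range(n_blocks - 1):
                gap_start0 = chrom_start + starts[b] + sizes[b]   # 0-based first intronic base
                gap_end0 = chrom_start + starts[b + 1]            # 0-based exclusive
                if gap_end0 <= gap_start0:
                    raise JunctionParseError(f"{path}:{i}: blocks {b},{b+1} leave no gap")
                records.append(
                    JunctionRecord(
                        chrom=chrom,
                        intron_start=gap_start0 + 1,  # to 1-based inclusive
                        intron_end=gap_end0,
                        strand=strand,
                        unique_reads=score,
                        annotated=False,
                    )
                )
    return records


def read_junctions(path, dialect: str = "star_sj") -> list[JunctionRecord]:
    """Read a junction table, normalizing coordinates across dialects.

    The same physical junction encoded in either dialect yields an
    identical :class:`JunctionRecord` (1-based inclusive intron).
    """
    if dialect == "star_sj":
        records = _read_star_sj(path)
    elif dialect == "junction_bed":
        records = _read_junction_bed(path)
    else:
        raise ValueError(f"unknown junction dialect {dialect!r}")
    if not records:
        logger.warning("junction table %s is empty", path)
    return records


def write_calls_tsv(calls: list[AbnormalJunctionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tintron_start\tintron_end\tstrand\tunique_reads\t"
            "partner_start\tpartner_end\tpartner_reads\trelative_support\tpasses\torphan\n"
        )
        for c in calls:
            j, p = c.junction, c.canonical_partner
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t{j.strand}\t{j.unique_reads}\t"
                f"{p.intron_start if p else ''}\t{p.intron_end if p else ''}\t"
                f"{p.unique_reads if p else 0}\t{c.relative_support:.6g}\t"
                f"{c.passes}\t{c.orphan}\n"
            )


# ---------------------------------------------------------------------------
# abnormal-junction calling
# ---------------------------------------------------------------------------


def _overlap(a: JunctionRecord, lo: int, hi: int) -> int:
    return max(0, min(a.intron_end, hi) - max(a.intron_start, lo) + 1)


def call_abnormal_junctions(
    junctions: list[JunctionRecord],
    tm: TranscriptModel,
    min_reads: int = MIN_READS_DEFAULT,
    min_rel_support: float = MIN_REL_SUPPORT_DEFAULT,
) -> list[AbnormalJunctionCall]:
    """Call abnormal (non-annotated) junctions against the transcript model.

    A junction is annotated iff it matches one of the transcript's introns
    exactly.  Each novel junction is paired with the annotated junction
    sharing its donor end (else its acceptor end, else the annotated
    intron it overlaps most); junctions with no annotated partner are
    flagged orphan and their relative support is computed against zero
    canonical reads (i.e. 1.0).
    """
    intron_set = {tuple(sorted(iv)) for iv in tm.introns()}
    lo_g, hi_g = tm.span
    ann = [j for j in junctions if j.chrom == tm.chrom and (j.intron_start, j.intron_end) in intron_set]

    donor_of = (lambda j: j.intron_start) if tm.strand == "+" else (lambda j: j.intron_end)
    acceptor_of = (lambda j: j.intron_end) if tm.strand == "+" else (lambda j: j.intron_start)

    calls: list[AbnormalJunctionCall] = []
    for j in junctions:
        if j.chrom != tm.chrom:
            continue
        if j.intron_end < lo_g or j.intron_start > hi_g:
            continue
        if (j.intron_start, j.intron_end) in intron_set:
            continue  # annotated junction, not abnormal
        partner = None
        for a in ann:
            if donor_of(a) == donor_of(j):
                partner = a
                break
        if partner is None:
            for a in ann:
                if acceptor_of(a) == acceptor_of(j):
                    partner = a
                    break
        if partner is None and ann:
            best = max(ann, key=lambda a: _overlap(a, j.intron_start, j.intron_end))
            if _overlap(best, j.intron_start, j.intron_end) > 0:
                partner = best
        orphan = partner is None
        denom = j.unique_reads + (partner.unique_reads if partner else 0)
        rel = (j.unique_reads / denom) if denom > 0 else 0.0
        if orphan:
            logger.warning(
                "orphan junction %s:%d-%d has no annotated partner; "
                "relative support computed against 0 canonical reads",
                j.chrom, j.intron_start, j.intron_end,
            )
        passes = j.unique_reads >= min_reads and rel >= min_rel_support
        calls.append(
            AbnormalJunctionCall(
                junction=j,
                canonical_partner=partner,
                relative_support=rel,
                passes=passes,
                orphan=orphan,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def compute_psi(
    inclusion_junction_reads: list[int | float],
    exclusion_junction_reads: list[int | float],
) -> PsiValue:
    """Percent spliced in from supporting junction counts.

    Each side is length-normalized as the mean read count over its
    supporting junctions (an exon-skipping event has two inclusion
    junctions and one exclusion junction); with uniform read length the
    per-junction mean is the length-normalized quantity.  When both
    sides have zero evidence the PSI is undefined and flagged, never 0.
    """
    if not inclusion_junction_reads and not exclusion_junction_reads:
        raise ValueError("at least one junction count is required")
    if any(c < 0 for c in list(inclusion_junction_reads) + list(exclusion_junction_reads)):
        raise ValueError("junction read counts must be non-negative")
    inc = (
        sum(inclusion_junction_reads) / len(inclusion_junction_reads)
        if inclusion_junction_reads
        else 0.0
    )
    exc = (
        sum(exclusion_junction_reads) / len(exclusion_junction_reads)
        if exclusion_junction_reads
        else 0.0
    )
    if inc + exc == 0:
        return PsiValue(0.0, 0.0, psi=None, defined=False)
    return PsiValue(inc, exc, psi=inc / (inc + exc), defined=True)
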