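"""Transcript coordinate arithmetic, HGVS c. parsing and splice-region annotation.

The coordinate conventions used throughout the package:

* genomic coordinates are 1-based inclusive (GTF/HGVS style);
* a transcript position ``t`` is the 1-based offset into the spliced
  transcript (concatenated exons, 5'->3' in transcript orientation);
* a coding (c.) position is anchored at the first coding base
  (``c.1`` sits at transcript position ``cds_start_c``), with intronic
  positions written as ``exonic_base +/- offset`` in the HGVS manner.

Splice-region windows follow the sequence-ontology definition: the donor
region runs from the third-last exonic base (D-3) to the eighth intronic
base (D+8); the acceptor region from the eighth-last intronic base (A-8)
to the third exonic base (A+3).  D+1/D+2 and A-1/A-2 are the canonical
GT/AG dinucleotide positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DONOR_INTRON_MAX = 8   # D+1 .. D+8
DONOR_EXON_MAX = 3     # D-3 .. D-1
ACCEPTOR_INTRON_MAX = 8  # A-8 .. A-1
ACCEPTOR_EXON_MAX = 3    # A+1 .. A+3

NUCLEOTIDES = ("A", "C", "G", "T")


class HgvsParseError(ValueError):
    """Malformed HGVS c. description."""


class UnsupportedHgvsError(ValueError):
    """Well-formed HGVS that this package deliberately does not handle."""


class CoordinateError(ValueError):
    """Position outside the transcript or inconsistent with its structure."""


@dataclass(frozen=True)
class CPosition:
    """A position in HGVS c. space: coding base plus signed intron offset.

    ``intron_offset`` 0 means exonic; +k is k bases into the intron
    downstream of ``exonic_base`` (which must then be an exon's last
    base); -k is k bases into the intron upstream (first exon base).
    """

    exonic_base: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.exonic_base < 1:
            raise CoordinateError(
                f"coding base must be >= 1 (positions upstream of c.1 are "
                f"not supported); got {self.exonic_base}"
            )

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return f"c.{self.exonic_base}"
        return f"c.{self.exonic_base}{self.intron_offset:+d}"


@dataclass(frozen=True)
class CVariant:
    """A variant anchored in c. space.

    ``span`` is the number of reference nucleotides replaced (1 for a
    SNV); ``ref_allele`` may be None for deletions written without the
    deleted sequence.
    """

    position: CPosition
    ref_allele: str | None
    alt_allele: str
    span: int = 1

    def __post_init__(self) -> None:
        if self.span < 1:
            raise ValueError(f"span must be >= 1, got {self.span}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if allele:
                bad = set(allele) - set(NUCLEOTIDES)
                if bad:
                    raise ValueError(f"{name} allele contains non-ACGT characters: {sorted(bad)}")
        if self.span == 1 and self.ref_allele and self.alt_allele and self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical ({self.ref_allele})")

    @property
    def is_snv(self) -> bool:
        return self.span == 1 and len(self.alt_allele or "") == 1 and bool(self.ref_allele)


@dataclass(frozen=True)
class SpliceRegionLabel:
    """Sequence-ontology splice-region assignment of one variant.

    ``region`` is one of donor / acceptor / deep_exonic / deep_intronic.
    ``offset`` uses the D/A position code: donor D-3..D-1 are offsets
    -3..-1 (exonic) and D+1..D+8 offsets +1..+8 (intronic); acceptor
    A-8..A-1 are offsets -8..-1 (intronic) and A+1..A+3 +1..+3 (exonic).
    ``canonical`` marks D+1/D+2/A-1/A-2.  ``from_span`` flags labels
    assigned to a multinucleotide variant via its most splice-proximal
    base.
    """

    region: str
    offset: int | None = None
    canonical: bool = False
    from_span: bool = False

    def __post_init__(self) -> None:
        if self.region not in ("donor", "acceptor", "deep_exonic", "deep_intronic"):
            raise ValueError(f"unknown region {self.region!r}")
        if (self.offset is None) != (self.region in ("deep_exonic", "deep_intronic")):
            raise ValueError("offset must be present iff region is donor/acceptor")

    @property
    def code(self) -> str:
        """Position code such as 'D+5', 'A-2', or the deep region name."""
        if self.offset is None:
            return self.region
        side = "D" if self.region == "donor" else "A"
        return f"{side}{self.offset:+d}"


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon structure of one transcript.

    ``exons`` are (low, high) genomic 1-based inclusive intervals listed
    5'->3' in transcript orientation (descending genomic coordinates on
    the minus strand).  ``cds_start_c`` is the transcript position of the
    first coding base, so transcript position of c.n is
    ``cds_start_c + n - 1``.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_c: int = 1
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        for lo, hi in self.exons:
            if hi < lo:
                raise ValueError(f"exon ({lo}, {hi}) has negative length")
        lows = [e[0] for e in self.exons]
        ordered = lows == sorted(lows) if self.strand == "+" else lows == sorted(lows, reverse=True)
        if not ordered:
            raise ValueError("exons must be ordered 5'->3' in transcript orientation")
        for (l1, h1), (l2, h2) in zip(self.exons, self.exons[1:]):
            gap = (l2 - h1) if self.strand == "+" else (l1 - h2)
            if gap < 2:
                raise ValueError("exons overlap or abut (zero-length intron)")
        if self.cds_start_c < 1 or self.cds_start_c > self.length:
            raise ValueError(f"cds_start_c {self.cds_start_c} outside transcript (length {self.length})")

    # -- structure ---------------------------------------------------------

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(hi - lo + 1 for lo, hi in self.exons)

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (low, high) footprint of the transcript."""
        lows = [e[0] for e in self.exons]
        highs = [e[1] for e in self.exons]
        return min(lows), max(highs)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic (low, high) of each intron, in transcript order."""
        out = []
        for (l1, h1), (l2, h2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((h1 + 1, l2 - 1))
            else:
                out.append((h2 + 1, l1 - 1))
        return tuple(out)

    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(hi - lo + 1 for lo, hi in self.introns())

    def donor_sites(self) -> tuple[int, ...]:
        """Genomic coordinate of each intron's first (5') base, transcript order."""
        return tuple((lo if self.strand == "+" else hi) for lo, hi in self.introns())

    def acceptor_sites(self) -> tuple[int, ...]:
        """Genomic coordinate of each intron's last (3') base, transcript order."""
        return tuple((hi if self.strand == "+" else lo) for lo, hi in self.introns())

    # -- coordinate maps ---------------------------------------------------

    def tx_to_genomic(self, t: int) -> int:
        if t < 1 or t > self.length:
            raise CoordinateError(
                f"transcript position {t} outside {self.transcript_id} (length {self.length})"
            )
        for (lo, hi), ln in zip(self.exons, self.exon_lengths):
            if t <= ln:
                return lo + t - 1 if self.strand == "+" else hi - (t - 1)
            t -= ln
        raise AssertionError("unreachable")

    def genomic_to_tx(self, g: int) -> int | None:
        """Transcript position of genomic base ``g``, or None if intronic/outside."""
        offset = 0
        for lo, hi in self.exons:
            if lo <= g <= hi:
                within = (g - lo) if self.strand == "+" else (hi - g)
                return offset + within + 1
            offset += hi - lo + 1
        return None

    def exon_index_of_tx(self, t: int) -> tuple[int, int]:
        """(exon index 0-based in transcript order, 0-based offset within exon)."""
        if t < 1 or t > self.length:
            raise CoordinateError(f"transcript position {t} outside transcript")
        for i, ln in enumerate(self.exon_lengths):
            if t <= ln:
                return i, t - 1
            t -= ln
        raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# HGVS c. parsing
# ---------------------------------------------------------------------------

_SNV_RE = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_DEL_RE = re.compile(
    r"^c\.(\d+)([+-]\d+)?(?:_(\d+)([+-]\d+)?)?del([ACGT]+)?(?:ins([ACGT]+))?$"
)
_INS_RE = re.compile(r"^c\.(\d+)([+-]\d+)?_(\d+)([+-]\d+)?ins([ACGT]+)$")
_UNSUPPORTED_RE = re.compile(r"dup|inv|con|\[|\(|=|\?")


def parse_hgvs_c(text: str) -> CVariant:
    """Parse the HGVS c. subset used by the pipeline into a :class:`CVariant`.

    Supported forms: substitutions ``c.N[+/-k]R>A``, deletions
    ``c.N[_M]del[SEQ]`` and deletion-insertions ``c.N_Mdel[SEQ]insSEQ``,
    and insertions ``c.N_N+1insSEQ``.  Anything else (duplications,
    inversions, alleles, uncertain positions) raises
    :class:`UnsupportedHgvsError`; malformed text raises
    :class:`HgvsParseError` naming the offending token.
    """
    text = text.strip()
    if not text.startswith("c."):
        raise HgvsParseError(f"expected a 'c.' description, got {text!r}")
    if _UNSUPPORTED_RE.search(text):
        token = _UNSUPPORTED_RE.search(text).group(0)
        raise UnsupportedHgvsError(f"unsupported HGVS form (token {token!r}) in {text!r}")

    m = _SNV_RE.match(text)
    if m:
        base, off, ref, alt = m.groups()
        if ref == alt:
            raise HgvsParseError(f"reference and alternate allele identical in {text!r}")
        return CVariant(
            position=CPosition(int(base), int(off) if off else 0),
            ref_allele=ref,
            alt_allele=alt,
            span=1,
        )

    m = _INS_RE.match(text)
    if m:
        b1, o1, b2, o2, seq = m.groups()
        p1 = CPosition(int(b1), int(o1) if o1 else 0)
        return CVariant(position=p1, ref_allele=None, alt_allele=seq, span=1)

    m = _DEL_RE.match(text)
    if m:
        b1, o1, b2, o2, delseq, insseq = m.groups()
        p1 = CPosition(int(b1), int(o1) if o1 else 0)
        o1i = int(o1) if o1 else 0
        if b2 is None:
            span = 1
        else:
            o2i = int(o2) if o2 else 0
            b2i = int(b2)
            if o1i == 0 and o2i == 0:
                span = b2i - int(b1) + 1
            elif b2i == int(b1):
                span = o2i - o1i + 1
            elif o1i != 0 and o2i != 0 and b2i == int(b1):
                span = o2i - o1i + 1
            else:
                # endpoints anchored on different exon boundaries; exact span
                # needs the transcript model, take the exonic extent as floor
                span = max(1, b2i - int(b1) + 1)
        if delseq is not None and b2 is not None and o1i == 0 and (o2 is None or int(o2) == 0):
            if len(delseq) != span:
                raise HgvsParseError(
                    f"deleted sequence length {len(delseq)} does not match coordinate span {span} in {text!r}"
                )
        return CVariant(position=p1, ref_allele=delseq, alt_allele=insseq or "", span=span)

    # point at the first token that breaks the grammar
    bad = re.search(r"[^c.\d+_>ACGTdelins-]", text)
    token = bad.group(0) if bad else text
    raise HgvsParseError(f"cannot parse HGVS c. description {text!r} (offending token {token!r})")


# ---------------------------------------------------------------------------
# c. <-> genomic mapping
# ---------------------------------------------------------------------------


def _c_to_tx(pos: CPosition, tm: TranscriptModel) -> int:
    t = tm.cds_start_c + pos.exonic_base - 1
    if t < 1 or t > tm.length:
        raise CoordinateError(
            f"c.{pos.exonic_base} maps to transcript position {t}, outside "
            f"{tm.transcript_id} (length {tm.length})"
        )
    return t


def c_to_genomic(pos: CPosition, tm: TranscriptModel) -> int:
    """Genomic 1-based coordinate of an HGVS c. position on ``tm``.

    Intronic offsets require the anchoring exonic base to sit at the
    corresponding exon boundary (the HGVS convention) and must stay
    strictly inside the adjacent intron.
    """
    t = _c_to_tx(pos, tm)
    g = tm.tx_to_genomic(t)
    off = pos.intron_offset
    if off == 0:
        return g
    idx, within = tm.exon_index_of_tx(t)
    n_ex = len(tm.exons)
    if off > 0:
        if within != tm.exon_lengths[idx] - 1:
            raise CoordinateError(
                f"{pos}: +offset anchor c.{pos.exonic_base} is not the last base of an exon"
            )
        if idx == n_ex - 1:
            raise CoordinateError(f"{pos}: no intron downstream of the last exon")
        if off > tm.intron_lengths()[idx]:
            raise CoordinateError(f"{pos}: offset exceeds intron length {tm.intron_lengths()[idx]}")
    else:
        if within != 0:
            raise CoordinateError(
                f"{pos}: -offset anchor c.{pos.exonic_base} is not the first base of an exon"
            )
        if idx == 0:
            raise CoordinateError(f"{pos}: no intron upstream of the first exon")
        if -off > tm.intron_lengths()[idx - 1]:
            raise CoordinateError(
                f"{pos}: offset exceeds intron length {tm.intron_lengths()[idx - 1]}"
            )
    return g + off if tm.strand == "+" else g - off


def genomic_to_c(g: int, tm: TranscriptModel) -> CPosition:
    """Inverse of :func:`c_to_genomic` (nearest-boundary anchor for introns)."""
    t = tm.genomic_to_tx(g)
    if t is not None:
        base = t - tm.cds_start_c + 1
        if base < 1:
            raise CoordinateError("positions upstream of c.1 are not supported")
        return CPosition(base, 0)
    lo_g, hi_g = tm.span
    if not (lo_g <= g <= hi_g):
        raise CoordinateError(f"genomic position {g} outside transcript footprint")
    for i, (ilo, ihi) in enumerate(tm.introns()):
        if ilo <= g <= ihi:
            donor_g = ilo if tm.strand == "+" else ihi
            acceptor_g = ihi if tm.strand == "+" else ilo
            d_donor = abs(g - donor_g) + 1   # D+1 at the intron's first base
            d_acc = abs(g - acceptor_g) + 1  # A-1 at the intron's last base
            # exon index i is upstream of intron i
            up_last_t = sum(tm.exon_lengths[: i + 1])
            down_first_t = up_last_t + 1
            if d_donor <= d_acc:
                return CPosition(up_last_t - tm.cds_start_c + 1, d_donor)
            return CPosition(down_first_t - tm.cds_start_c + 1, -d_acc)
    raise CoordinateError(f"genomic position {g} not locatable in {tm.transcript_id}")


# ---------------------------------------------------------------------------
# splice-region labelling
# ---------------------------------------------------------------------------


def _junction_distance(g: int, tm: TranscriptModel) -> int:
    """Distance in nt from genomic base g to the nearest exon/intron junction."""
    best = None
    for i, (lo, hi) in enumerate(tm.exons):
        e_lo, e_hi = (lo, hi) if tm.strand == "+" else (hi, lo)
        # donor side = 3' exon edge (skip for the last exon), acceptor = 5' edge
        if i < len(tm.exons) - 1:
            d = abs(g - e_hi)
            best = d if best is None else min(best, d)
        if i > 0:
            d = abs(g - e_lo)
            best = d if best is None else min(best, d)
    return best if best is not None else 10**9


def label_genomic_position(g: int, tm: TranscriptModel) -> SpliceRegionLabel:
    """Splice-region label of a single genomic base with respect to ``tm``."""
    t = tm.genomic_to_tx(g)
    n_ex = len(tm.exons)
    if t is not None:
        idx, within = tm.exon_index_of_tx(t)
        ln = tm.exon_lengths[idx]
        d_donor = ln - within          # 1 for the exon's last base
        d_acc = within + 1             # 1 for the exon's first base
        donor_ok = idx < n_ex - 1 and d_donor <= DONOR_EXON_MAX
        acc_ok = idx > 0 and d_acc <= ACCEPTOR_EXON_MAX
        if donor_ok and (not acc_ok or d_donor <= d_acc):
            return SpliceRegionLabel("donor", -d_donor, canonical=False)
        if acc_ok:
            return SpliceRegionLabel("acceptor", +d_acc, canonical=False)
        return SpliceRegionLabel("deep_exonic")
    for ilo, ihi in tm.introns():
        if ilo <= g <= ihi:
            donor_g = ilo if tm.strand == "+" else ihi
            acceptor_g = ihi if tm.strand == "+" else ilo
            d_donor = abs(g - donor_g) + 1
            d_acc = abs(g - acceptor_g) + 1
            if d_donor <= DONOR_INTRON_MAX and d_donor <= d_acc:
                return SpliceRegionLabel("donor", +d_donor, canonical=d_donor <= 2)
            if d_acc <= ACCEPTOR_INTRON_MAX:
                return SpliceRegionLabel("acceptor", -d_acc, canonical=d_acc <= 2)
            return SpliceRegionLabel("deep_intronic")
    raise CoordinateError(f"genomic position {g} outside transcript {tm.transcript_id}")


def splice_region_label(v: CVariant, tm: TranscriptModel) -> SpliceRegionLabel:
    """Sequence-ontology splice-region label of a variant.

    SNVs are labelled at their single base.  Multinucleotide variants
    take the label of the most splice-proximal base they span (ties
    broken toward the donor side) and carry ``from_span=True``.
    """
    g0 = c_to_genomic(v.position, tm)
    if v.span == 1:
        return label_genomic_position(g0, tm)
    step = 1 if tm.strand == "+" else -1
    lo_g, hi_g = tm.span
    best: tuple[int, int, SpliceRegionLabel] | None = None
    for k in range(v.span):
        g = g0 + step * k
        if not (lo_g <= g <= hi_g):
            break
        lab = label_genomic_position(g, tm)
        dist = _junction_distance(g, tm)
        donor_rank = 0 if lab.region == "donor" else 1
        key = (dist, donor_rank)
        if best is None or key < (best[0], best[1]):
            best = (dist, donor_rank, lab)
    assert best is not None
    lab = best[2]
    return SpliceRegionLabel(lab.region, lab.offset, lab.canonical, from_span=True)


# ---------------------------------------------------------------------------
# position-probability matrix
# ---------------------------------------------------------------------------


def build_pwm(
    sequences: Sequence[str],
    side: str | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Position-probability matrix from aligned nucleotide windows.

    Rows are A/C/G/T, columns 1..L; every column sums to 1.  ``side``
    is carried as metadata only: donor windows are aligned with the +1
    intronic base at column 12, acceptor windows with the -1 intronic
    base at column 25 (22- and 28-column defaults respectively).
    """
    if side is not None and side not in ("donor", "acceptor"):
        raise ValueError(f"side must be 'donor' or 'acceptor', got {side!r}")
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("cannot build a PWM from zero sequences")
    length = len(seqs[0])
    if length == 0:
        raise ValueError("sequences must be non-empty")
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged input: all sequences must have equal length")
    for s in seqs:
        bad = set(s) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"non-ACGT characters in input: {sorted(bad)}")
    counts = np.full((4, length), float(pseudocount))
    index = {b: i for i, b in enumerate(NUCLEOTIDES)}
    for s in seqs:
        for j, b in enumerate(s):
            counts[index[b], j] += 1.0
    probs = counts / counts.sum(axis=0, keepdims=True)
    df = pd.DataFrame(probs, index=list(NUCLEOTIDES), columns=range(1, length + 1))
    df.attrs["side"] = side
    df.attrs["n_sequences"] = len(seqs)
    df.attrs["pseudocount"] = pseudocount
    return df


def splice_site_windows(
    tm: TranscriptModel,
    genome: dict[str, str] | None = None,
    donor_width: tuple[int, int] = (11, 11),
    acceptor_width: tuple[int, int] = (25, 3),
) -> dict[str, list[str]]:
    """Extract donor/acceptor windows around every junction of ``tm``.

    ``genome`` maps chrom -> sequence (1-based semantics: character i-1 is
    base i).  Donor windows cover D-``donor_width[0]`` .. D+``donor_width[1]``
    so the +1 base sits at column ``donor_width[0] + 1`` (12 with defaults);
    acceptor windows cover A-``acceptor_width[0]`` .. A+``acceptor_width[1]``
    with the -1 base at column 25 with defaults.
    """
    if genome is None:
        raise ValueError("a genome sequence dict is required to extract windows")
    seq = genome[tm.chrom]
    comp = str.maketrans("ACGT", "TGCA")

    def fetch(g_from: int, g_to: int) -> str:
        s = seq[g_from - 1 : g_to]
        return s if tm.strand == "+" else s.translate(comp)[::-1]

    donors, acceptors = [], []
    for d in tm.donor_sites():
        # transcript-orientation window: exonic part then intronic part
        up, down = donor_width
        if tm.strand == "+":
            w = seq[d - 1 - up : d - 1 + down]
        else:
            w = fetch(d - down + 1, d + up)
        donors.append(w.upper())
    for a in tm.acceptor_sites():
        up, down = acceptor_width
        if tm.strand == "+":
            w = seq[a - up : a + down]
        else:
            w = fetch(a - down, a + up - 1)
        acceptors.append(w.upper())
    return {"donor": donors, "acceptor": acceptors}
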