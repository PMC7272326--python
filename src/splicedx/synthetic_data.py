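"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the structure of the clinical cohort the analysis
models: ~257 variants spread over donor/acceptor splice regions and deep
exonic/intronic positions, about a third splice-affecting, with an
event-type mix dominated by upstream exon skipping; per-sample junction
tables carrying injected aberrant junctions at controlled read depth and
PSI (always above the 3-read / 5% calling thresholds, so every injected
event is detectable by construction); per-base intron coverage for
intron-retention variants; and per-tool prediction scores drawn from
two beta distributions whose shapes are solved in closed form so the
thresholded expected sensitivity/specificity equal the requested
operating characteristics.  A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .junction_analysis import JunctionRecord
from .transcript_model import (
    CPosition,
    CVariant,
    NUCLEOTIDES,
    TranscriptModel,
    c_to_genomic,
    genomic_to_c,
    label_genomic_position,
    parse_hgvs_c,
)

# operating characteristics of the five tools on the published cohort
# (sensitivity, specificity, missing rate out of 257)
@dataclass(frozen=True)
class ToolProfile:
    sensitivity: float
    specificity: float
    missing_rate: float


DEFAULT_TOOL_PROFILES: dict[str, ToolProfile] = {
    "MES": ToolProfile(0.7381, 0.9070, 1 / 257),
    "NNSplice": ToolProfile(0.6923, 0.8631, 11 / 257),
    "SSF": ToolProfile(0.7317, 0.9294, 5 / 257),
    "HSF": ToolProfile(0.8941, 0.3958, 28 / 257),
    "SpliceAI": ToolProfile(0.8987, 0.9162, 11 / 257),
}

# cohort region mix: donor 57/257 and acceptor 19/257 match the published
# splice-region SNV counts; the deep exonic/intronic split is our choice.
DEFAULT_REGION_MIX: dict[str, float] = {
    "donor": 57 / 257,
    "acceptor": 19 / 257,
    "deep_exonic": 0.45,
    "deep_intronic": 1.0 - 57 / 257 - 19 / 257 - 0.45,
}

# event-type mix proportional to the published event counts
DEFAULT_EVENT_MIX: dict[str, float] = {
    "SE_upstream": 39 / 96,
    "SE_downstream": 15 / 96,
    "A5SS": 23 / 96,
    "A3SS": 16 / 96,
    "IR": 3 / 96,
}

DEFAULT_THRESHOLDS = {"MES": 0.10, "NNSplice": 0.05, "SSF": 0.05, "HSF": 0.2, "SpliceAI": 0.2}


class ConfigError(ValueError):
    """Infeasible or inconsistent cohort configuration."""


@dataclass
class CohortConfig:
    seed: int = 0
    n_variants: int = 257
    frac_affecting: float = 0.33
    region_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    event_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    multiple_event_rate: float = 4 / 85
    frac_multinucleotide: float = 14 / 257
    depth: float = 100.0
    psi_range: tuple[float, float] = (0.10, 0.80)
    tool_profiles: dict[str, ToolProfile] = field(
        default_factory=lambda: dict(DEFAULT_TOOL_PROFILES)
    )
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    n_transcripts: int = 8
    n_controls: int = 3

    def validate(self) -> None:
        if not (0.0 <= self.frac_affecting <= 1.0):
            raise ConfigError("frac_affecting must lie in [0, 1]")
        for name, mix in (("region_mix", self.region_mix), ("event_mix", self.event_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ConfigError(f"{name} must be a probability distribution")
        if not (self.psi_range[0] > 0 and self.psi_range[1] <= 1 and self.psi_range[0] <= self.psi_range[1]):
            raise ConfigError("psi_range must satisfy 0 < lo <= hi <= 1")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        for tool, p in self.tool_profiles.items():
            thr = self.thresholds.get(tool)
            if thr is None:
                raise ConfigError(f"no threshold for tool {tool}")
            if not (0.0 < p.sensitivity < 1.0 and 0.0 < p.specificity < 1.0):
                raise ConfigError(
                    f"{tool}: target sensitivity/specificity must lie strictly in (0, 1)"
                )
            if not (0.0 <= p.missing_rate < 1.0):
                raise ConfigError(f"{tool}: missing_rate must lie in [0, 1)")
            if not (0.0 < thr < 1.0):
                raise ConfigError(f"{tool}: threshold must lie in (0, 1)")


@dataclass
class CohortBundle:
    config: CohortConfig
    transcripts: dict[str, TranscriptModel]
    genome: dict[str, str]
    variants: pd.DataFrame          # variant_id, transcript_id, hgvs_c, region_truth
    truth: pd.DataFrame             # variant_id, splice_affecting
    tool_scores: pd.DataFrame       # variant_id, tool, delta, missing
    patient_junctions: dict[str, list[JunctionRecord]]
    control_junctions: dict[str, list[list[JunctionRecord]]]
    coverage: dict[str, pd.DataFrame]
    events_truth: pd.DataFrame      # variant_id, intended_type, psi, delta info


# ---------------------------------------------------------------------------
# transcript panel and genome
# ---------------------------------------------------------------------------


def make_transcript(
    transcript_id: str,
    chrom: str,
    strand: str,
    exon_lengths: list[int],
    intron_lengths: list[int],
    tx_start: int = 1001,
    gene_id: str | None = None,
) -> TranscriptModel:
    """Assemble a transcript from exon/intron lengths, strand-aware.

    ``tx_start`` is the genomic coordinate of the transcript's lowest
    base; exon order in the output follows transcript orientation.
    """
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError("need exactly one intron length between consecutive exons")
    e_lens = list(exon_lengths) if strand == "+" else list(exon_lengths)[::-1]
    i_lens = list(intron_lengths) if strand == "+" else list(intron_lengths)[::-1]
    blocks: list[tuple[int, int]] = []
    g = tx_start
    for i, ln in enumerate(e_lens):
        blocks.append((g, g + ln - 1))
        g += ln
        if i < len(i_lens):
            g += i_lens[i]
    if strand == "-":
        blocks = blocks[::-1]
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id or transcript_id,
        strand=strand,
        exons=tuple(blocks),
        cds_start_c=1,
        chrom=chrom,
    )


def _random_transcript(rng: np.random.Generator, idx: int) -> TranscriptModel:
    n_exons = int(rng.integers(5, 9))
    exon_lens = [int(rng.integers(80, 251)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(400, 2001)) for _ in range(n_exons - 1)]
    strand = "+" if rng.random() < 0.5 else "-"
    return make_transcript(
        transcript_id=f"TX{idx:02d}",
        chrom=f"chr{idx}",
        strand=strand,
        exon_lengths=exon_lens,
        intron_lengths=intron_lens,
    )


def _random_genome_for(tm: TranscriptModel, rng: np.random.Generator) -> str:
    """Random chromosome with canonical GT/AG (and consensus-ish flanks) at junctions."""
    lo, hi = tm.span
    length = hi + 100
    seq = rng.choice(list(NUCLEOTIDES), size=length)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def put(g: int, base: str) -> None:
        seq[g - 1] = base if tm.strand == "+" else comp[base]

    step = 1 if tm.strand == "+" else -1
    for d in tm.donor_sites():
        put(d, "G")
        put(d + step, "T")
        # degenerate consensus beyond the GT
        for k, bases in enumerate(("AG", "AG", "GA", "TG")):
            if rng.random() < 0.7:
                put(d + step * (2 + k), bases[0])
    for a in tm.acceptor_sites():
        put(a, "G")
        put(a - step, "A")
        # polypyrimidine-ish tract upstream of the AG
        for k in range(2, 15):
            if rng.random() < 0.75:
                put(a - step * k, "C" if rng.random() < 0.5 else "T")
    return "".join(seq)


# ---------------------------------------------------------------------------
# variant placement
# ---------------------------------------------------------------------------


def _mid_range(n: int) -> tuple[int, int]:
    """Index range preferring internal structure elements (0-based lo, hi incl.)."""
    if n >= 3:
        return 1, n - 2
    return 0, n - 1


def _place_variant(rng: np.random.Generator, tm: TranscriptModel, region: str) -> int:
    """Genomic position of a variant in the requested splice-region class."""
    step = 1 if tm.strand == "+" else -1
    introns = tm.introns()
    n_int = len(introns)
    if region == "donor":
        lo, hi = _mid_range(n_int)
        i = int(rng.integers(lo, hi + 1))
        d = tm.donor_sites()[i]
        off = int(rng.choice(list(range(-3, 0)) + list(range(1, 9))))
        return d - step * (-off) if off < 0 else d + step * (off - 1)
    if region == "acceptor":
        lo, hi = _mid_range(n_int)
        i = int(rng.integers(lo, hi + 1))
        a = tm.acceptor_sites()[i]
        off = int(rng.choice(list(range(-8, 0)) + list(range(1, 4))))
        return a - step * (-off - 1) if off < 0 else a + step * off
    if region == "deep_exonic":
        lo, hi = _mid_range(len(tm.exons))
        e = int(rng.integers(lo, hi + 1))
        elo, ehi = sorted(tm.exons[e])
        ln = ehi - elo + 1
        within = int(rng.integers(4, ln - 3))  # >3 nt from both edges (0-based offset)
        first = elo if tm.strand == "+" else ehi
        return first + step * within
    if region == "deep_intronic":
        lo, hi = _mid_range(n_int)
        i = int(rng.integers(lo, hi + 1))
        ilo, ihi = sorted(introns[i])
        ln = ihi - ilo + 1
        k = int(rng.integers(9, max(10, ln - 8)))  # D+9 .. A-9
        d = tm.donor_sites()[i]
        return d + step * (k - 1)
    raise ConfigError(f"unknown region class {region!r}")


def _hgvs_for(g: int, tm: TranscriptModel, rng: np.random.Generator, span: int = 1) -> str:
    cpos = genomic_to_c(g, tm)
    if span > 1:
        end = CPosition(cpos.exonic_base + span - 1, 0)
        return f"c.{cpos.exonic_base}_{end.exonic_base}del"
    ref, alt = rng.choice(list(NUCLEOTIDES), size=2, replace=False)
    return f"{cpos}{ref}>{alt}"


# ---------------------------------------------------------------------------
# event injection
# ---------------------------------------------------------------------------


def _nearest_intron(gv: int, tm: TranscriptModel) -> int:
    """0-based index of the intron nearest the variant position."""
    best, best_d = 0, None
    for i, iv in enumerate(tm.introns()):
        lo, hi = sorted(iv)
        d = 0 if lo <= gv <= hi else min(abs(gv - lo), abs(gv - hi))
        if best_d is None or d < best_d:
            best, best_d = i, d
    return best


def _se_junction(tm: TranscriptModel, exon_1based: int) -> tuple[int, int]:
    introns = tm.introns()
    a = sorted(introns[exon_1based - 2])
    b = sorted(introns[exon_1based - 1])
    return min(a[0], b[0]), max(a[1], b[1])


def _inject_event(
    rng: np.random.Generator,
    tm: TranscriptModel,
    gv: int,
    etype: str,
) -> tuple[str, tuple[int, int] | None, int | None, int | None]:
    """Plan one aberrant event near the variant.

    Returns (realized_intent, junction genomic (lo, hi) or None for IR,
    retained intron 0-based index or None, canonical partner intron
    0-based index or None).  The partner index names the annotated
    junction the caller will score the novel junction against, so read
    counts can be injected at a controlled PSI.  The realized intent may
    fall back to the opposite skipping direction at transcript ends.
    """
    introns = tm.introns()
    n_exons = len(tm.exons)
    i0 = _nearest_intron(gv, tm)
    step = 1 if tm.strand == "+" else -1

    if etype in ("SE_upstream", "SE_downstream"):
        # exon adjacent to the variant's intron on the requested side,
        # 1-based; internal exons only (2 .. n_exons-1)
        up_candidate = i0 + 1
        down_candidate = i0 + 2
        def internal(e: int) -> bool:
            return 2 <= e <= n_exons - 1
        if etype == "SE_upstream":
            exon = up_candidate if internal(up_candidate) else down_candidate
            realized = "SE_upstream" if internal(up_candidate) else "SE_downstream"
        else:
            exon = down_candidate if internal(down_candidate) else up_candidate
            realized = "SE_downstream" if internal(down_candidate) else "SE_upstream"
        if not internal(exon):
            raise ConfigError("transcript too short to place a skipped-exon event")
        return realized, _se_junction(tm, exon), None, exon - 2

    if etype in ("A5SS", "A3SS"):
        ilo, ihi = sorted(introns[i0])
        intron_len = ihi - ilo + 1
        donor_g = tm.donor_sites()[i0]
        acceptor_g = tm.acceptor_sites()[i0]
        into_intron = bool(rng.random() < 0.5)
        if etype == "A5SS":
            exon_idx = i0  # upstream exon, 0-based == intron index
            exon_len = tm.exon_lengths[exon_idx]
            max_shift = (intron_len - 12) if into_intron else (exon_len - 6)
            shift = int(rng.integers(4, max(5, min(61, max_shift))))
            new_donor = donor_g + step * shift if into_intron else donor_g - step * shift
            lo, hi = sorted((new_donor, acceptor_g))
        else:
            exon_idx = i0 + 1  # downstream exon
            exon_len = tm.exon_lengths[exon_idx]
            max_shift = (intron_len - 12) if into_intron else (exon_len - 6)
            shift = int(rng.integers(4, max(5, min(61, max_shift))))
            new_acceptor = acceptor_g - step * shift if into_intron else acceptor_g + step * shift
            lo, hi = sorted((donor_g, new_acceptor))
        return etype, (lo, hi), None, i0

    if etype == "IR":
        return "IR", None, i0, None

    if etype == "exitron":
        lo_e, hi_e = _mid_range(n_exons)
        candidates = [e for e in range(lo_e, hi_e + 1) if tm.exon_lengths[e] >= 60]
        if not candidates:
            raise ConfigError("no exon long enough for an exitron")
        e = int(rng.choice(candidates))
        elo, ehi = sorted(tm.exons[e])
        ln = ehi - elo + 1
        ex_len = int(rng.integers(30, min(120, ln - 20)))
        start = int(rng.integers(elo + 5, ehi - ex_len - 4))
        return "exitron", (start, start + ex_len - 1), None, None

    raise ConfigError(f"unknown event type {etype!r}")


# ---------------------------------------------------------------------------
# junction tables, coverage, scores
# ---------------------------------------------------------------------------


def _nb_reads(rng: np.random.Generator, mean: float, size: float = 10.0, floor: int = 20) -> int:
    p = size / (size + mean)
    return max(floor, int(rng.negative_binomial(size, p)))


def _annotated_table(tm: TranscriptModel, rng: np.random.Generator, depth: float) -> list[JunctionRecord]:
    recs = []
    for iv in tm.introns():
        lo, hi = sorted(iv)
        recs.append(
            JunctionRecord(
                chrom=tm.chrom, intron_start=lo, intron_end=hi, strand=tm.strand,
                unique_reads=_nb_reads(rng, depth), annotated=True,
            )
        )
    return recs


def _noise_junctions(tm: TranscriptModel, rng: np.random.Generator, n: int = 2) -> list[JunctionRecord]:
    """Sub-threshold novel junctions (1-2 reads, never reportable)."""
    out = []
    introns = tm.introns()
    for _ in range(n):
        i = int(rng.integers(0, len(introns)))
        lo, hi = sorted(introns[i])
        shift = int(rng.integers(3, 30))
        if hi - lo + 1 <= shift + 10:
            continue
        out.append(
            JunctionRecord(
                chrom=tm.chrom, intron_start=lo + shift, intron_end=hi, strand=tm.strand,
                unique_reads=int(rng.integers(1, 3)), annotated=False,
            )
        )
    return out


def beta_shapes_for_profile(
    profile: ToolProfile, threshold: float
) -> tuple[float, float]:
    """Closed-form Beta shapes for the two score distributions.

    Positives are Beta(a, 1) (CDF x^a) with a chosen so
    P(score >= threshold) = sensitivity; negatives are Beta(1, b)
    (survival (1-x)^b) with P(score >= threshold) = 1 - specificity.
    """
    a = math.log(1.0 - profile.sensitivity) / math.log(threshold)
    b = math.log(1.0 - profile.specificity) / math.log(1.0 - threshold)
    return a, b


def _draw_score(
    rng: np.random.Generator, affecting: bool, a: float, b: float
) -> float:
    u = rng.random()
    return u ** (1.0 / a) if affecting else 1.0 - (1.0 - u) ** (1.0 / b)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate a fully ground-truthed synthetic cohort bundle."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    transcripts = {
        tm.transcript_id: tm
        for tm in (_random_transcript(rng, i + 1) for i in range(config.n_transcripts))
    }
    genome = {tm.chrom: _random_genome_for(tm, rng) for tm in transcripts.values()}
    tids = list(transcripts)

    region_names = list(config.region_mix)
    region_p = np.array([config.region_mix[r] for r in region_names])
    event_names = list(config.event_mix)
    event_p = np.array([config.event_mix[e] for e in event_names])
    shapes = {
        tool: beta_shapes_for_profile(p, config.thresholds[tool])
        for tool, p in config.tool_profiles.items()
    }

    control_junctions = {
        tid: [
            _annotated_table(transcripts[tid], rng, config.depth)
            + _noise_junctions(transcripts[tid], rng)
            for _ in range(config.n_controls)
        ]
        for tid in tids
    }

    variant_rows, truth_rows, score_rows, event_rows = [], [], [], []
    patient_junctions: dict[str, list[JunctionRecord]] = {}
    coverage: dict[str, pd.DataFrame] = {}

    for i in range(config.n_variants):
        vid = f"VAR{i + 1:04d}"
        tid = tids[int(rng.integers(0, len(tids)))]
        tm = transcripts[tid]
        region = region_names[int(rng.choice(len(region_names), p=region_p))]
        gv = _place_variant(rng, tm, region)
        span = 1
        if region == "deep_exonic" and rng.random() < config.frac_multinucleotide:
            span = int(rng.integers(2, 7))
        hgvs = _hgvs_for(gv, tm, rng, span=span)
        region_truth = label_genomic_position(gv, tm).region
        affecting = bool(rng.random() < config.frac_affecting)

        table = _annotated_table(tm, rng, config.depth) + _noise_junctions(tm, rng)
        ann_reads = {
            tuple(sorted(iv)): r.unique_reads
            for iv, r in zip(tm.introns(), table)
        }
        if affecting:
            n_events = 2 if rng.random() < config.multiple_event_rate else 1
            placed: set[tuple] = set()
            for _ in range(n_events):
                etype = event_names[int(rng.choice(len(event_names), p=event_p))]
                realized, junction, ir_intron, partner = _inject_event(rng, tm, gv, etype)
                key = (realized, junction, ir_intron)
                if key in placed:
                    continue
                placed.add(key)
                psi = float(rng.uniform(*config.psi_range))
                if junction is not None:
                    if partner is not None:
                        canonical = ann_reads[tuple(sorted(tm.introns()[partner]))]
                    else:
                        canonical = _nb_reads(rng, config.depth)
                    novel = max(3, round(canonical * psi / (1.0 - psi)))
                    table.append(
                        JunctionRecord(
                            chrom=tm.chrom, intron_start=junction[0], intron_end=junction[1],
                            strand=tm.strand, unique_reads=novel, annotated=False,
                        )
                    )
                else:
                    ilo, ihi = sorted(tm.introns()[ir_intron])
                    exon_depth = config.depth
                    frac = float(rng.uniform(0.06, 0.30))
                    rows = [
                        {"chrom": tm.chrom, "pos": p, "depth": max(3.0, round(frac * exon_depth))}
                        for p in range(ilo, ihi + 1)
                    ]
                    for elo, ehi in (sorted(e) for e in tm.exons):
                        rows.extend(
                            {"chrom": tm.chrom, "pos": p, "depth": exon_depth}
                            for p in range(elo, ehi + 1)
                        )
                    coverage[vid] = pd.DataFrame(rows)
                event_rows.append(
                    {
                        "variant_id": vid,
                        "intended_type": realized,
                        "junction_start": junction[0] if junction else None,
                        "junction_end": junction[1] if junction else None,
                        "retained_intron": ir_intron,
                        "psi": psi,
                    }
                )
        patient_junctions[vid] = table

        for tool, profile in config.tool_profiles.items():
            missing = bool(rng.random() < profile.missing_rate)
            delta = None if missing else _draw_score(rng, affecting, *shapes[tool])
            score_rows.append(
                {"variant_id": vid, "tool": tool, "delta": delta, "missing": missing}
            )

        variant_rows.append(
            {
                "variant_id": vid,
                "transcript_id": tid,
                "hgvs_c": hgvs,
                "region_truth": region_truth,
                "span": span,
            }
        )
        truth_rows.append({"variant_id": vid, "splice_affecting": affecting})

    return CohortBundle(
        config=config,
        transcripts=transcripts,
        genome=genome,
        variants=pd.DataFrame(variant_rows),
        truth=pd.DataFrame(truth_rows),
        tool_scores=pd.DataFrame(score_rows),
        patient_junctions=patient_junctions,
        control_junctions=control_junctions,
        coverage=coverage,
        events_truth=pd.DataFrame(event_rows),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _write_star_sj(records: list[JunctionRecord], path: Path) -> None:
    strand_code = {"+": "1", "-": "2", ".": "0"}
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.intron_start}\t{r.intron_end}\t{strand_code[r.strand]}\t"
                f"1\t{1 if r.annotated else 0}\t{r.unique_reads}\t0\t30\n"
            )


def write_bundle(bundle: CohortBundle, outdir) -> dict:
    """Write the bundle in the exact formats the pipeline consumes.

    Emits an exon-table TSV, variant/truth/score TSVs, one STAR
    ``SJ.out.tab`` per patient sample and per control, per-base coverage
    TSVs, and a manifest JSON listing every file with its SHA-256.
    """
    from .io import write_transcripts_tsv

    outdir = Path(outdir)
    (outdir / "junctions").mkdir(parents=True, exist_ok=True)
    (outdir / "controls").mkdir(exist_ok=True)
    (outdir / "coverage").mkdir(exist_ok=True)

    write_transcripts_tsv(bundle.transcripts, outdir / "transcripts.tsv")
    bundle.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    scores = bundle.tool_scores.copy()
    scores.insert(2, "ref_score", np.nan)
    scores.insert(3, "alt_score", np.nan)
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    bundle.events_truth.to_csv(outdir / "events_truth.tsv", sep="\t", index=False)

    for vid, table in bundle.patient_junctions.items():
        _write_star_sj(table, outdir / "junctions" / f"{vid}.SJ.out.tab")
    for tid, tables in bundle.control_junctions.items():
        for k, table in enumerate(tables, start=1):
            _write_star_sj(table, outdir / "controls" / f"{tid}_ctrl{k}.SJ.out.tab")
    for vid, cov in bundle.coverage.items():
        cov.to_csv(outdir / "coverage" / f"{vid}.tsv", sep="\t", index=False)

    manifest: dict = {"seed": bundle.config.seed, "n_variants": bundle.config.n_variants, "files": {}}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["files"][str(path.relative_to(outdir))] = digest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# hand-built worked-example fixtures
# ---------------------------------------------------------------------------


@dataclass
class FixtureCase:
    name: str
    transcript: TranscriptModel
    hgvs_c: str
    variant: CVariant
    patient_junctions: list[JunctionRecord]
    control_junctions: list[list[JunctionRecord]]
    coverage: pd.DataFrame | None
    expected: dict


def _ann(tm: TranscriptModel, reads: dict[int, int] | int = 80) -> list[JunctionRecord]:
    out = []
    for i, iv in enumerate(tm.introns()):
        lo, hi = sorted(iv)
        r = reads if isinstance(reads, int) else reads.get(i, 80)
        if r <= 0:
            continue
        out.append(JunctionRecord(tm.chrom, lo, hi, tm.strand, r, annotated=True))
    return out


def fixture_worked_examples() -> list[FixtureCase]:
    """Six hand-built cases mirroring the published illustrative examples.

    Each toy transcript reproduces the relevant exon arithmetic of the
    corresponding gene (the c. anchors and event sizes), not its real
    genomic sequence: a novel intronic donor adding 11 nt (DKC1-like), a
    deep intronic variant with multiple abnormalities including intron
    retention (P3H1-like), a canonical donor variant over constitutively
    skipped exons (DCTN1-like), an exonic cryptic donor deleting 119 nt
    (BRCA1 exon-15-like), downstream exon skipping from an intronic
    variant (BRCA1 exon-18-like), and a 125-nt exitron (SF3B4-like).
    """
    cases: list[FixtureCase] = []

    # --- DKC1-like: novel intronic donor, +11 nt, PSI 20% --------------------
    tm = make_transcript("DKC1like", "chrD", "+", [400, 515, 300], [500, 500])
    i2lo, i2hi = sorted(tm.introns()[1])
    patient = _ann(tm, 80) + [
        JunctionRecord("chrD", i2lo + 11, i2hi, "+", 20, annotated=False)
    ]
    cases.append(
        FixtureCase(
            name="DKC1_novel_intronic_donor",
            transcript=tm,
            hgvs_c="c.915+10G>A",
            variant=parse_hgvs_c("c.915+10G>A"),
            patient_junctions=patient,
            control_junctions=[_ann(tm, 80), _ann(tm, 90)],
            coverage=None,
            expected={
                "region": "deep_intronic",
                "events": [{"event_type": "A5SS", "delta_nt": 11, "frame_effect": "frameshift"}],
                "psi": 0.20,
            },
        )
    )

    # --- P3H1-like: deep intronic, multiple events incl. IR ------------------
    tm = make_transcript(
        "P3H1like", "chrP", "+",
        [200, 150, 175, 150, 200, 150, 198, 120, 200],
        [400] * 8,
    )
    i7lo, i7hi = sorted(tm.introns()[6])  # intron 7 (0-based 6), length 400
    patient = _ann(tm, {6: 60}) + [
        JunctionRecord("chrP", i7lo, i7hi - 68, "+", 15, annotated=False),       # A3SS +68
        JunctionRecord("chrP", i7lo + 92, i7hi + 17, "+", 12, annotated=False),  # +92/-17 = +75
    ]
    # make every non-target intron deep by default reads
    cov_rows = [{"chrom": "chrP", "pos": p, "depth": 10.0} for p in range(i7lo, i7hi + 1)]
    for elo, ehi in (sorted(e) for e in tm.exons):
        cov_rows.extend({"chrom": "chrP", "pos": p, "depth": 100.0} for p in range(elo, ehi + 1))
    cases.append(
        FixtureCase(
            name="P3H1_multiple_abnormalities",
            transcript=tm,
            hgvs_c="c.1224-80G>A",
            variant=parse_hgvs_c("c.1224-80G>A"),
            patient_junctions=patient,
            control_junctions=[_ann(tm, 80), _ann(tm, 90)],
            coverage=pd.DataFrame(cov_rows),
            expected={
                "region": "deep_intronic",
                "events": [
                    {"event_type": "A3SS", "delta_nt": 68, "frame_effect": "frameshift"},
                    {"event_type": "A5SS", "delta_nt": 75, "frame_effect": "in_frame",
                     "complex_ends": True},
                    {"event_type": "IR", "delta_nt": 400, "frame_effect": "frameshift"},
                ],
            },
        )
    )

    # --- DCTN1-like: canonical donor variant, constitutive skipping ----------
    tm = make_transcript(
        "DCTN1like", "chrC", "+",
        [100, 120, 94, 100, 90, 80, 110, 200, 150],
        [300] * 8,
    )
    skip_lo, skip_hi = _se_junction(tm, 5)[0], _se_junction(tm, 7)[1]
    skip_j = JunctionRecord("chrC", skip_lo, skip_hi, "+", 100, annotated=False)
    # introns 4-6 (0-based 3..5) flank/join the never-expressed exons 5-7
    expressed = {i: 80 for i in range(8) if i not in (3, 4, 5, 6)}
    patient = _ann(tm, {**{i: 0 for i in range(8)}, **expressed}) + [skip_j]
    controls = [
        _ann(tm, {**{i: 0 for i in range(8)}, **expressed}) + [skip_j],
        _ann(tm, {**{i: 0 for i in range(8)}, **expressed})
        + [JunctionRecord("chrC", skip_lo, skip_hi, "+", 90, annotated=False)],
    ]
    cases.append(
        FixtureCase(
            name="DCTN1_constitutive_skipping",
            transcript=tm,
            hgvs_c="c.414+1G>A",
            variant=parse_hgvs_c("c.414+1G>A"),
            patient_junctions=patient,
            control_junctions=controls,
            coverage=None,
            expected={"region": "donor", "canonical": True, "events": []},
        )
    )

    # --- BRCA1 exon-15-like: exonic cryptic donor, -119 nt -------------------
    tm = make_transcript("BRCA1ex15like", "chrB1", "-", [4000, 987, 300], [600, 600])
    g4868 = c_to_genomic(CPosition(4868), tm)
    i2 = sorted(tm.introns()[1])
    novel = (i2[0], g4868 - 1)  # minus strand: novel donor just past c.4868
    patient = _ann(tm, 70) + [
        JunctionRecord("chrB1", novel[0], novel[1], "-", 25, annotated=False)
    ]
    cases.append(
        FixtureCase(
            name="BRCA1_exonic_cryptic_donor",
            transcript=tm,
            hgvs_c="c.4868C>G",
            variant=parse_hgvs_c("c.4868C>G"),
            patient_junctions=patient,
            control_junctions=[_ann(tm, 70), _ann(tm, 75)],
            coverage=None,
            expected={
                "region": "deep_exonic",
                "events": [{"event_type": "A5SS", "delta_nt": -119, "frame_effect": "frameshift"}],
            },
        )
    )

    # --- BRCA1 exon-18-like: intronic variant, downstream exon skipping ------
    tm = make_transcript("BRCA1ex18like", "chrB2", "-", [2000, 3152, 41, 300], [500, 500, 500])
    lo, hi = _se_junction(tm, 3)
    patient = _ann(tm, 60) + [JunctionRecord("chrB2", lo, hi, "-", 18, annotated=False)]
    cases.append(
        FixtureCase(
            name="BRCA1_downstream_exon_skipping",
            transcript=tm,
            hgvs_c="c.5153-26A>G",
            variant=parse_hgvs_c("c.5153-26A>G"),
            patient_junctions=patient,
            control_junctions=[_ann(tm, 60), _ann(tm, 65)],
            coverage=None,
            expected={
                "region": "deep_intronic",
                "events": [
                    {"event_type": "SE_downstream", "delta_nt": -41,
                     "frame_effect": "frameshift", "skipped_exons": (3,)}
                ],
            },
        )
    )

    # --- SF3B4-like: synonymous deep exonic variant, 125-nt exitron ----------
    tm = make_transcript("SF3B4like", "chrS", "+", [100, 63, 600, 200], [400] * 3)
    g417 = c_to_genomic(CPosition(417), tm)
    patient = _ann(tm, 80) + [
        JunctionRecord("chrS", g417 + 1, g417 + 125, "+", 14, annotated=False)
    ]
    cases.append(
        FixtureCase(
            name="SF3B4_exitron",
            transcript=tm,
            hgvs_c="c.417C>T",
            variant=parse_hgvs_c("c.417C>T"),
            patient_junctions=patient,
            control_junctions=[_ann(tm, 80), _ann(tm, 85)],
            coverage=None,
            expected={
                "region": "deep_exonic",
                "events": [{"event_type": "exitron", "delta_nt": -125, "frame_effect": "frameshift"}],
            },
        )
    )

    return cases
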