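"""End-to-end orchestration: junctions -> events -> benchmark tables.

Thin composition of the stage modules so scripts, tests and the CLI all
run the identical analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import evaluation
from .event_classification import (
    SpliceEvent,
    VariantSplicingResult,
    classify_event,
    cohort_summary,
    constitutive_exon_filter,
    ir_event,
    ir_from_coverage_table,
    suppress_constitutive,
)
from .junction_analysis import (
    MIN_READS_DEFAULT,
    MIN_REL_SUPPORT_DEFAULT,
    JunctionRecord,
    call_abnormal_junctions,
    compute_psi,
)
from .prediction_scoring import (
    ALAMUT_TOOLS,
    CONSENSUS_NAME,
    TOOLS,
    ToolScore,
    call_all,
)
from .transcript_model import CVariant, SpliceRegionLabel, TranscriptModel, splice_region_label

logger = logging.getLogger(__name__)


def analyze_variant(
    variant_id: str,
    tm: TranscriptModel,
    variant: CVariant,
    junctions: list[JunctionRecord],
    coverage: pd.DataFrame | None = None,
    control_junctions: list[list[JunctionRecord]] | None = None,
    min_reads: int = MIN_READS_DEFAULT,
    min_rel_support: float = MIN_REL_SUPPORT_DEFAULT,
    use_constitutive_filter: bool = True,
) -> VariantSplicingResult:
    """Call, classify and filter the splice events of one patient sample."""
    calls = call_abnormal_junctions(junctions, tm, min_reads=min_reads, min_rel_support=min_rel_support)
    events: list[SpliceEvent] = [
        classify_event(c, tm, variant) for c in calls if c.passes
    ]
    ir_not_assessable = False
    if coverage is not None:
        for ir in ir_from_coverage_table(coverage, tm, min_fraction=min_rel_support, min_reads=min_reads):
            if ir.status == "retained":
                canonical = next(
                    (
                        j.unique_reads
                        for j in junctions
                        if (j.intron_start, j.intron_end)
                        == tuple(sorted(tm.introns()[ir.intron_index - 1]))
                    ),
                    0,
                )
                psi = compute_psi([ir.intron_median], [canonical]) if canonical else None
                events.append(ir_event(ir.intron_index, tm, psi=psi))
            elif ir.status == "not_assessable":
                ir_not_assessable = True
    if use_constitutive_filter and control_junctions:
        mask = constitutive_exon_filter(tm, control_junctions)
        events = suppress_constitutive(events, mask)
    return VariantSplicingResult(
        variant_id=variant_id, events=events, ir_not_assessable=ir_not_assessable
    )


@dataclass
class CohortAnalysis:
    results: list[VariantSplicingResult]
    labels: list[SpliceRegionLabel]
    variants: list[CVariant]
    summary: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def called_affecting(self) -> dict[str, bool]:
        return {r.variant_id: r.splice_affecting for r in self.results}


def analyze_cohort(
    bundle,
    min_reads: int = MIN_READS_DEFAULT,
    min_rel_support: float = MIN_REL_SUPPORT_DEFAULT,
    use_constitutive_filter: bool = True,
) -> CohortAnalysis:
    """Run the junction/event pipeline over a synthetic (or loaded) bundle."""
    from .transcript_model import parse_hgvs_c

    results, labels, variants, tms = [], [], [], []
    for _, row in bundle.variants.iterrows():
        vid = row["variant_id"]
        tm = bundle.transcripts[row["transcript_id"]]
        v = parse_hgvs_c(row["hgvs_c"])
        res = analyze_variant(
            vid,
            tm,
            v,
            bundle.patient_junctions[vid],
            coverage=bundle.coverage.get(vid),
            control_junctions=bundle.control_junctions.get(row["transcript_id"]),
            min_reads=min_reads,
            min_rel_support=min_rel_support,
            use_constitutive_filter=use_constitutive_filter,
        )
        results.append(res)
        labels.append(splice_region_label(v, tm))
        variants.append(v)
        tms.append(tm)
    summary = cohort_summary(results, labels, variants=variants, transcripts=tms)
    return CohortAnalysis(results=results, labels=labels, variants=variants, summary=summary)


# ---------------------------------------------------------------------------
# predictor benchmark
# ---------------------------------------------------------------------------


def scores_from_frame(df: pd.DataFrame) -> list[ToolScore]:
    """ToolScore records from a tidy (variant_id, tool, delta, missing) frame."""
    out = []
    for _, row in df.iterrows():
        missing = bool(row.get("missing", False)) or pd.isna(row.get("delta"))
        out.append(
            ToolScore(
                variant_id=str(row["variant_id"]),
                tool=str(row["tool"]),
                delta=None if missing else float(row["delta"]),
                missing=missing,
            )
        )
    return out


@dataclass
class BenchmarkResult:
    calls: pd.DataFrame
    confusions: dict[str, evaluation.ConfusionMatrix]
    metrics_table: pd.DataFrame
    roc: dict[str, evaluation.RocResult]
    overlap_n: int


def benchmark_predictors(
    scores_df: pd.DataFrame,
    truth_df: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    overlap_only_roc: bool = True,
) -> BenchmarkResult:
    """Thresholded calls, confusion matrices, metric rows and ROC/AUC.

    Metrics per tool use all variants that tool scored (missing excluded
    from the 2x2 but counted); ROC curves are computed on the overlap
    set scored by every tool, with the Alamut consensus entered as the
    ordinal 0-3 count of component tools above threshold.
    """
    truth = dict(zip(truth_df["variant_id"], truth_df["splice_affecting"].astype(bool)))
    scores = scores_from_frame(scores_df)
    calls = call_all(scores, thresholds)

    confusions: dict[str, evaluation.ConfusionMatrix] = {}
    for tool in list(TOOLS) + [CONSENSUS_NAME]:
        sub = calls[calls["tool"] == tool]
        confusions[tool] = evaluation.confusion(
            dict(zip(sub["variant_id"], sub["call"])), truth
        )
    table = evaluation.metrics_table(confusions)

    # per-variant continuous score for ROC: the thresholded quantity itself;
    # consensus enters as the number of Alamut tools above threshold (0-3)
    score_of: dict[str, dict[str, float | None]] = {t: {} for t in TOOLS}
    for _, row in calls.iterrows():
        if row["tool"] in TOOLS:
            score_of[row["tool"]][row["variant_id"]] = (
                None if row["call"] == "missing" else row["score_used"]
            )
    overlap = evaluation.overlap_variants(score_of) if overlap_only_roc else set(truth)
    roc: dict[str, evaluation.RocResult] = {}
    for tool in TOOLS:
        sc = {v: s for v, s in score_of[tool].items() if v in overlap and s is not None}
        roc[tool] = evaluation.roc_auc(sc, {v: truth[v] for v in sc})
    ala_counts: dict[str, float] = {}
    pos_count = calls[(calls["tool"].isin(ALAMUT_TOOLS)) & (calls["call"] == "positive")]
    counted = pos_count.groupby("variant_id").size()
    for v in overlap:
        ala_counts[v] = float(counted.get(v, 0))
    roc[CONSENSUS_NAME] = evaluation.roc_auc(ala_counts, {v: truth[v] for v in ala_counts})

    return BenchmarkResult(
        calls=calls,
        confusions=confusions,
        metrics_table=table,
        roc=roc,
        overlap_n=len(overlap),
    )


def events_table(analysis: CohortAnalysis) -> pd.DataFrame:
    """Tidy per-event output (variant_id, type, skipped exons, delta, frame, psi)."""
    rows = []
    for r in analysis.results:
        for e in r.events:
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "event_type": e.event_type,
                    "skipped_exons": ",".join(map(str, e.skipped_exons)),
                    "delta_nt": e.delta_nt,
                    "frame_effect": e.frame_effect,
                    "psi": None if e.psi is None or not e.psi.defined else e.psi.psi,
                }
            )
        if not r.events:
            rows.append(
                {
                    "variant_id": r.variant_id,
                    "event_type": "none",
                    "skipped_exons": "",
                    "delta_nt": 0,
                    "frame_effect": "in_frame",
                    "psi": None,
                }
            )
    return pd.DataFrame(rows)
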