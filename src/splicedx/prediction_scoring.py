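"""Threshold per-tool splice-prediction scores into binary calls.

Five tools are supported.  MaxEntScan (MES), NNSplice and SpliceSiteFinder
(SSF) are splice-site-strength tools thresholded on the relative change
|alt - ref| / |ref| of the site score (MES >= 10%, NNSplice/SSF >= 5%);
Human Splicing Finder (HSF) and SpliceAI are thresholded directly on
their variation / maximum-delta score (both >= 0.2).  All thresholds
are inclusive.  The consensus of the three Alamut-bundled tools calls a
variant splice-altering when at least two of the three agree, and is
missing whenever any component score is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

SITE_STRENGTH_TOOLS = ("MES", "NNSplice", "SSF")
DELTA_TOOLS = ("HSF", "SpliceAI")
TOOLS = SITE_STRENGTH_TOOLS + DELTA_TOOLS
ALAMUT_TOOLS = SITE_STRENGTH_TOOLS
CONSENSUS_NAME = "Alamut23"

DEFAULT_THRESHOLDS: dict[str, float] = {
    "MES": 0.10,
    "NNSplice": 0.05,
    "SSF": 0.05,
    "HSF": 0.2,
    "SpliceAI": 0.2,
}

DE_NOVO_SENTINEL = math.inf


class ToolConfigurationError(ValueError):
    """Unknown tool or malformed score record."""


@dataclass(frozen=True)
class ToolScore:
    variant_id: str
    tool: str
    ref_score: float | None = None
    alt_score: float | None = None
    delta: float | None = None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ToolConfigurationError(f"unknown tool {self.tool!r}")
        if not self.missing:
            has_pair = self.ref_score is not None and self.alt_score is not None
            has_delta = self.delta is not None
            if has_pair and has_delta:
                raise ToolConfigurationError(
                    f"{self.variant_id}/{self.tool}: carry (ref, alt) or a precomputed "
                    "change, never both"
                )
            if not has_pair and not has_delta:
                raise ToolConfigurationError(
                    f"{self.variant_id}/{self.tool}: non-missing score needs (ref, alt) or delta"
                )


@dataclass(frozen=True)
class ToolCall:
    variant_id: str
    tool: str
    call: str  # 'positive' | 'negative' | 'missing'
    threshold_used: float | None = None
    score_used: float | None = None

    def __post_init__(self) -> None:
        if self.call not in ("positive", "negative", "missing"):
            raise ValueError(f"bad call {self.call!r}")
        if self.call != "missing" and self.threshold_used is None:
            raise ValueError("non-missing calls must record the threshold used")


def relative_change(ref_score: float, alt_score: float, de_novo_min: float = 0.0) -> float:
    """Unsigned relative change |alt - ref| / |ref| of a site-strength score.

    A reference score of zero with a called alternate site (alt above
    ``de_novo_min``) is a de-novo site: the change is returned as +inf,
    exceeding any threshold.  Both scores zero gives 0.
    """
    if not (math.isfinite(ref_score) and math.isfinite(alt_score)):
        raise ValueError("scores must be finite")
    if ref_score == 0:
        return DE_NOVO_SENTINEL if alt_score > de_novo_min else 0.0
    return abs(alt_score - ref_score) / abs(ref_score)


def threshold_call(
    score: ToolScore, thresholds: dict[str, float] | None = None
) -> ToolCall:
    """Binary call for one tool score; thresholds are inclusive (>=)."""
    thr_map = DEFAULT_THRESHOLDS if thresholds is None else {**DEFAULT_THRESHOLDS, **thresholds}
    if score.tool not in thr_map:
        raise ToolConfigurationError(f"no threshold configured for {score.tool!r}")
    thr = thr_map[score.tool]
    if score.missing:
        return ToolCall(score.variant_id, score.tool, "missing")
    if score.delta is not None:
        value = score.delta if score.tool in DELTA_TOOLS else abs(score.delta)
    else:
        value = relative_change(score.ref_score, score.alt_score)
    call = "positive" if value >= thr else "negative"
    return ToolCall(score.variant_id, score.tool, call, threshold_used=thr, score_used=value)


def alamut_consensus(mes: ToolCall, nn: ToolCall, ssf: ToolCall) -> ToolCall:
    """2-of-3 consensus of the Alamut-bundled tools.

    Missing whenever any component is missing; otherwise positive iff at
    least two components are positive.
    """
    parts = {c.tool: c for c in (mes, nn, ssf)}
    if set(parts) != set(ALAMUT_TOOLS):
        raise ToolConfigurationError(
            f"consensus needs one call each from {ALAMUT_TOOLS}, got {sorted(parts)}"
        )
    vids = {c.variant_id for c in (mes, nn, ssf)}
    if len(vids) != 1:
        raise ToolConfigurationError(f"consensus calls span multiple variants: {sorted(vids)}")
    vid = vids.pop()
    if any(c.call == "missing" for c in (mes, nn, ssf)):
        return ToolCall(vid, CONSENSUS_NAME, "missing")
    n_pos = sum(c.call == "positive" for c in (mes, nn, ssf))
    return ToolCall(
        vid,
        CONSENSUS_NAME,
        "positive" if n_pos >= 2 else "negative",
        threshold_used=2.0,
        score_used=float(n_pos),
    )


# ---------------------------------------------------------------------------
# table-level helpers
# ---------------------------------------------------------------------------


def read_tool_scores_tsv(path) -> list[ToolScore]:
    """Read a score table: variant_id, tool, ref_score, alt_score, delta, missing.

    Empty numeric cells mean 'not scored'; a row is missing when its
    ``missing`` column is truthy or it carries no numeric score at all.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    scores = []
    for _, row in df.iterrows():
        ref = row.get("ref_score")
        alt = row.get("alt_score")
        delta = row.get("delta")
        ref = None if pd.isna(ref) else float(ref)
        alt = None if pd.isna(alt) else float(alt)
        delta = None if pd.isna(delta) else float(delta)
        missing_col = row.get("missing", False)
        missing = (not pd.isna(missing_col) and bool(missing_col)) or (
            ref is None and alt is None and delta is None
        )
        scores.append(
            ToolScore(
                variant_id=str(row["variant_id"]),
                tool=str(row["tool"]),
                ref_score=None if missing else ref,
                alt_score=None if missing else alt,
                delta=None if missing else delta,
                missing=missing,
            )
        )
    return scores


def call_all(
    scores: list[ToolScore], thresholds: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-variant calls for every tool plus the Alamut 2/3 consensus.

    Returns a tidy frame (variant_id, tool, call, score_used); variants
    with no record at all for a tool are treated as missing for it.
    """
    by_variant: dict[str, dict[str, ToolScore]] = {}
    for s in scores:
        by_variant.setdefault(s.variant_id, {})[s.tool] = s
    rows = []
    for vid, tool_scores in by_variant.items():
        calls: dict[str, ToolCall] = {}
        for tool in TOOLS:
            s = tool_scores.get(tool, ToolScore(vid, tool, missing=True))
            calls[tool] = threshold_call(s, thresholds)
        consensus = alamut_consensus(calls["MES"], calls["NNSplice"], calls["SSF"])
        for c in list(calls.values()) + [consensus]:
            rows.append(
                {
                    "variant_id": c.variant_id,
                    "tool": c.tool,
                    "call": c.call,
                    "score_used": c.score_used,
                    "threshold_used": c.threshold_used,
                }
            )
    return pd.DataFrame(rows)
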