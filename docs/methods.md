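# Methods

This note records the models, conventions and numerical choices behind
`splicedx`, and what its synthetic-data tests do and do not establish.

## Coordinates and HGVS subset

All external coordinates are 1-based inclusive (the HGVS/GTF
convention); half-open arithmetic exists only inside interval helpers.
A transcript is an ordered exon list in transcript orientation with a
single CDS anchor `cds_start_c` (the transcript position of c.1), so
coding coordinates upstream of c.1 (5′UTR forms like `c.-12`) are
rejected rather than guessed. The HGVS parser covers the subset the
pipeline consumes — substitutions with optional intronic offsets,
deletions, deletion-insertions and insertions — and refuses everything
else (duplications, inversions, alleles, uncertain positions) with an
explicit "unsupported" error; silent misparses are treated as bugs.
Intronic offsets must anchor on the adjacent exon boundary and stay
strictly inside the intron, which makes the c.↔genomic map a bijection
(property-tested on random transcripts, both strands).

## Splice-region annotation

The donor window is D−3…D+8 and the acceptor window A−8…A+3; deep exonic
means more than 3 nt from both flanking junctions, deep intronic more
than 8 nt from both intron ends. In exons or introns short enough for
windows to overlap, the nearer junction wins and exact ties go to the
donor side. Terminal exons have only one junction, so only that side is
considered. Multinucleotide variants take the label of the most
splice-proximal base they span (ties toward the donor), flagged
`from_span`; cohort per-position tallies count SNVs only, since a
span-derived position code is not comparable to a single-base one.

## Junction calling and PSI

A junction is *annotated* iff it matches a transcript intron exactly.
A novel junction is reportable at ≥ 3 unique reads and ≥ 5 % relative
support, both inclusive. The 5 % rule is implemented with the bounded
denominator, r = novel/(novel + canonical), because the alternative
reading (novel/canonical) is unbounded and coincides with the bounded
form to first order at small r; the knob is exposed
(`min_rel_support`). The canonical partner is the annotated junction
sharing the novel junction's donor, else its acceptor, else the
annotated intron with the largest overlap; a novel junction with no
annotated partner is still scored (against 0 canonical reads, support
1.0) but flagged *orphan*. The 3-read threshold applies per junction,
not per event. PSI length-normalizes each side as the mean read count
over its supporting junctions (two inclusion junctions vs one exclusion
junction for exon skipping); read-length normalization cancels because
all reads in one table share a length. PSI is undefined — flagged, never
reported as 0 — when both sides have zero evidence.

## Event classification

End status against annotated boundaries (strand-aware) determines the
class: both ends annotated but not an annotated intron ⇒ skipped
exon(s); novel donor ⇒ A5SS; novel acceptor ⇒ A3SS; both ends novel
inside one exon ⇒ exitron. A both-ends-novel junction that crosses
annotated structure (e.g. a novel intronic donor paired with a novel
exonic acceptor) has no member of its own in the taxonomy; it is
assigned A5SS or A3SS by the larger end shift and flagged
`complex_ends`. A junction skipping several exons is one event listing
all of them, matching per-variant counting. Upstream vs downstream
skipping follows the variant's distance to the skipped exon's donor vs
acceptor site; exact ties classify upstream (the donor-proximal class
dominates real cohorts) with a `tie_break` flag and a logged warning.

The mature-transcript length change uses one rule for every class:

    delta_nt = sum(len(annotated introns overlapping the novel span))
               - len(novel span),

positive = net insertion. This reproduces +11 (intronic donor shift),
−119 (exonic cryptic donor), −125 (exitron), +92−17 = +75 (complex) and
−(exon length) for skipping, and is checked against an independent
set-arithmetic transcript-reconstruction oracle. Frameshift is exactly
`delta_nt % 3 != 0`; intron retention inserts the full intron length.

Coverage-based IR reuses the junction thresholds (median intron depth
≥ 5 % of median flanking-exon depth and ≥ 3 reads) because no separate
coverage thresholds are stated anywhere; missing coverage yields
"not assessable", never a negative call. The constitutive-exon filter
masks exons whose skip ratio is ≥ 0.95 in *every* control (an invented,
exposed default); with no controls it is disabled with a warning.

## Predictor thresholding and evaluation

Site-strength tools (MES, NNSplice, SSF) threshold the unsigned
relative change |alt − ref|/|ref| at 10 %/5 %/5 %; a site gained from a
zero reference is a de-novo site and exceeds any threshold (+∞
sentinel). HSF and SpliceAI threshold their variation / max-delta score
at 0.2; for SpliceAI "score" means the maximum of the four delta
scores, the standard usage. The HSF threshold is genuinely ambiguous in
the source material (0.2 vs "2 %"); 0.2 is the default and the knob is
exposed. All thresholds are inclusive and regression-pinned. The Alamut
2-of-3 consensus is missing whenever any component is missing — the only
rule consistent with the published missing-count arithmetic (11 variants
missing one score + 3 missing two = 14 missing consensus calls).

Confusion matrices exclude missing calls from the 2×2 but count them,
so tp+fp+tn+fn+missing = total always. Metrics with zero denominators
are undefined (None), never 0 or NaN. Comparisons against printed
values use half-up rounding at 4 decimals, the printed precision. ROC
is an explicit threshold sweep with ties grouped and trapezoidal AUC;
tests verify equality with the Mann–Whitney pair-count statistic and
with scikit-learn on 1000 random toy sets. Binary-only consensus enters
ROC as the ordinal count (0–3) of agreeing component tools. No
multiple-testing correction is applied — none is part of the modelled
analysis.

**Published-row reconstruction.** The published benchmark reports only
rounded metrics; the underlying 2×2 tables are recovered by exhaustive
search over (positives among missing, tp, tn) consistent with n = 257,
85 experimental positives, the row's missing count and four of the five
metrics at printed precision. Each of the six rows admits exactly one
solution, and the held-out fifth metric (accuracy) recomputed from it
matches the printed value — an internal-consistency check, at about a
millisecond per row.

## Synthetic cohort generator

The generator emulates the structure of the modelled clinical cohort:
257 variants over a panel of 8 random transcripts (5–8 exons of
80–250 nt, introns 400–2000 nt, both strands), with region mix donor
57/257 and acceptor 19/257 (the published splice-region SNV counts) and
the remainder split deep exonic 0.45 / deep intronic ≈ 0.25 (our choice;
the published split of non-splice-region variants is not broken down).
A variant is splice-affecting with probability 0.33 independent of
region — the published overall rate; region-conditional rates would be
more realistic but are not what the recovery checks target. Affecting
variants get events drawn from the published mix (SE upstream 39 :
SE downstream 15 : A5SS 23 : A3SS 16 : IR 3), a second event with
probability 4/85, and about 14/257 of deep-exonic variants are
multinucleotide deletions. Injected junctions are placed at the
variant's nearest intron with end shifts of 4–60 nt; their read counts
are derived from the *actual* canonical partner's count at a PSI drawn
uniformly from [0.10, 0.80], so every injected event passes the 3-read /
5 % thresholds by construction and the junction caller's detection rate
on them is exactly 100 % (a calibration property, not an empirical
claim). Non-affecting variants carry only annotated junctions plus 1–2
read noise junctions, which can never pass. Annotated junction depths
are negative-binomial (mean 100, size 10, floored at 20 reads).

Tool scores are Beta-distributed: positives Beta(a, 1), negatives
Beta(1, b), with a = ln(1−sens)/ln(thr) and b = ln(1−spec)/ln(1−thr) so
the thresholded expected sensitivity and specificity exactly equal the
published per-tool operating characteristics; missingness is Bernoulli
per tool (published missing rates), independent of the label.
Everything streams from a single `numpy` Generator seeded by the config,
and a fixed seed reproduces every output file byte-for-byte (SHA-256
manifest).

What the synthetic tests therefore show: the pipeline's arithmetic,
thresholds, bookkeeping and metric computations are correct and
internally consistent at study scale. What they do not show: performance
on real junction tables, where read depth varies along genes,
annotation is imperfect, PSI of causal events can fall below detection,
and tool scores correlate with variant position — none of which the
generator models.

## Problem sizes and defaults

Default analyses run one 257-variant cohort (seed 1 in the drivers);
calibration checks average 20 seeds, the scale at which per-tool
sensitivity estimates have standard errors ≈ 0.01. Junction tables per
sample hold ~10 records; intron-retention coverage tables hold one
fully covered intron plus exons (≲ 3000 rows). The whole test suite and
the acceptance script each run in seconds on one CPU.

## Known limitations

* HGVS coverage is the diagnostic subset, not the full grammar; no
  protein-level consequence or NMD-efficiency modelling.
* The exitron class requires both novel ends strictly inside one exon;
  recursive splicing is not modelled.
* ROC for site-strength tools uses the same quantity the thresholds
  use (relative change); if a published comparison used raw scores
  instead, AUC values are not directly comparable (AUC is invariant
  only under monotone transforms of a single tool's score).
* The published cohort-level biological counts (85/257 affecting, 39
  upstream-SE, …) depend on unpublished experimental labels; they enter
  only as generator defaults and are not treated as reproducible
  quantities. The published benchmark table is reproduced through its
  internal consistency (unique confusion-matrix reconstruction), which
  is the strongest check its printed precision supports.
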