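# splicedx

Blood-RNA splicing analysis for variant interpretation: annotate variants
by splice-region position, call and classify aberrant splicing events
from splice-junction read tables, and benchmark in-silico splice
predictors against experimental splicing outcomes.

## The problem

A large share of variants of uncertain significance (VUS) found in
diagnostic sequencing may act by disrupting RNA splicing rather than by
changing protein sequence. Blood RNA-seq makes the splicing outcome
directly observable: a variant that creates or destroys a splice site
leaves a footprint in the splice-junction read table — a novel junction,
a skipped exon, a retained intron. This package implements that analysis
as a reusable pipeline for anyone who has (i) transcript models, (ii)
variants as HGVS c. descriptions, (iii) junction read counts (STAR
`SJ.out.tab` or junction BED12), and optionally (iv) per-variant scores
from splice-prediction tools together with experimental outcome labels.

## The model

**Splice regions.** Sequence ontology defines the donor region as
D−3…D+8 (third-last exonic base to eighth intronic base) and the
acceptor region as A−8…A+3; D+1/D+2 and A−1/A−2 are the canonical GT/AG
positions. Everything else is deep exonic or deep intronic.

**Abnormal junction calling.** A junction absent from the transcript
model is reportable when it has ≥ 3 uniquely-mapped reads *and* its read
support relative to the alternative canonical junction is
r = n/(n + c) ≥ 5 %, with n the novel and c the canonical junction's
reads (both thresholds inclusive). Intron retention is called from
per-base coverage when the median intron depth reaches 5 % of the median
flanking-exon depth and 3 reads absolute.

**Percent spliced in.**
PSI = inc / (inc + exc), where inc and exc are the length-normalized
(mean per-junction) inclusion and exclusion read counts.

**Event taxonomy and consequence.** Passing junctions classify as
skipped exon (SE, upstream vs downstream by whether the variant lies
closer to the skipped exon's donor or acceptor site), alternative 5′/3′
splice site (A5SS/A3SS), intron retention (IR) or exitron (a novel
intron wholly inside one exon). The transcript-level consequence is

Δnt = Σ |annotated introns overlapping the novel junction| − |novel junction|,

one rule valid for every class; frameshift ⇔ Δnt mod 3 ≠ 0. Exons that
are constitutively spliced out in *all* control samples
(skip/(skip+inclusion) ≥ 0.95) are masked so annotation errors do not
masquerade as variant effects.

**Predictor benchmark.** Tool calls are thresholded (MES relative change
≥ 10 %, NNSplice/SSF ≥ 5 %, HSF ≥ 0.2, SpliceAI max delta ≥ 0.2, all
inclusive; a site gained from a zero reference score counts as positive
at any threshold). The Alamut 2-of-3 consensus is positive when ≥ 2 of
MES/NNSplice/SSF are positive, and missing when *any* component is
missing. Per tool: sensitivity tp/(tp+fn), specificity tn/(tn+fp),
accuracy (tp+tn)/(tp+tn+fp+fn), PPV tp/(tp+fp), NPV tn/(tn+fn), computed
over scored variants, with the missing count reported alongside; ROC and
trapezoidal AUC are computed on the overlap set scored by every tool,
with the consensus entered as the ordinal 0–3 count of agreeing tools.

## Worked example

Junction evidence for a hemizygous *DKC1*-like variant, c.915+10G>A: the
patient junction table carries the annotated intron at 80 reads plus a
novel junction whose donor sits 11 nt into the intron, at 20 reads.

```python
from splicedx import parse_hgvs_c
from splicedx.pipeline import analyze_variant
from splicedx.synthetic_data import fixture_worked_examples

fx = {f.name: f for f in fixture_worked_examples()}["DKC1_novel_intronic_donor"]
res = analyze_variant(fx.name, fx.transcript, fx.variant, fx.patient_junctions)
e = res.events[0]
print(e.event_type, e.delta_nt, e.frame_effect, e.psi.psi)
```

prints

```
A5SS 11 frameshift 0.2
```

— an alternative 5′ splice site inserting 11 nt (frameshift), used by
20 % of transcripts (PSI = 20/(20+80)): the kind of small-scale change
RNA-seq detects where Sanger sequencing of RT-PCR products fails.
`analysis/03_call_and_classify_events.py` replays all six illustrative
cases (novel intronic donor, multi-event deep intronic variant,
constitutively skipped exons, exonic cryptic donor, downstream exon
skipping, exitron) and prints each call.

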