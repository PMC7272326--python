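#!/usr/bin/env python
"""Annotate the cohort by splice-region position and build splice-site PWMs.

Labels every variant with its sequence-ontology position code (donor
D-3..D+8, acceptor A-8..A+3, else deep exonic/intronic) and builds
donor/acceptor position-probability matrices from the synthetic genome's
junction windows (donor +1 base at column 12 of a 22-column window;
acceptor -1 base at column 25 of a 28-column window).  Outputs land in
results/annotation/.
"""

from pathlib import Path

import pandas as pd

from splicedx.synthetic_data import CohortConfig, generate_cohort
from splicedx.transcript_model import build_pwm, parse_hgvs_c, splice_region_label, splice_site_windows

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "annotation"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = generate_cohort(CohortConfig(seed=SEED))

    rows = []
    for _, r in bundle.variants.iterrows():
        tm = bundle.transcripts[r.transcript_id]
        lab = splice_region_label(parse_hgvs_c(r.hgvs_c), tm)
        rows.append({"variant_id": r.variant_id, "hgvs_c": r.hgvs_c,
                     "region": lab.region, "position_code": lab.code,
                     "canonical": lab.canonical})
    labels = pd.DataFrame(rows)
    labels.to_csv(OUT / "splice_region_labels.tsv", sep="\t", index=False)
    print("variants per region:")
    print(labels.region.value_counts().to_string())

    donors, acceptors = [], []
    for tm in bundle.transcripts.values():
        w = splice_site_windows(tm, genome=bundle.genome)
        donors += w["donor"]
        acceptors += w["acceptor"]
    pwm_d = build_pwm(donors, side="donor")
    pwm_a = build_pwm(acceptors, side="acceptor")
    pwm_d.to_csv(OUT / "pwm_donor.tsv", sep="\t")
    pwm_a.to_csv(OUT / "pwm_acceptor.tsv", sep="\t")
    print(f"\ndonor PWM from {len(donors)} windows; "
          f"column 12 (intron +1) G fraction = {pwm_d.loc['G', 12]:.2f}")
    print(f"acceptor PWM from {len(acceptors)} windows; "
          f"column 25 (intron -1) G fraction = {pwm_a.loc['G', 25]:.2f}")


if __name__ == "__main__":
    main()
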