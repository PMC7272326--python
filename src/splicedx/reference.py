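"""Published benchmark reference data.

The packaged table holds the published performance of five in-silico
splice predictors (plus the Alamut 2-of-3 consensus) on a 257-variant
blood-RNA cohort with 85 experimentally splice-affecting variants:
per-tool missing-score counts and the five metrics at 4-decimal
precision.  The underlying 2x2 confusion matrices were not published;
:func:`splicedx.evaluation.reconstruct_confusion` recovers them uniquely
from these rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

COHORT_N_TOTAL = 257
COHORT_N_POSITIVE = 85
# overlap set scored by every tool, used for the published ROC comparison
OVERLAP_N_NEGATIVE = 136
OVERLAP_N_POSITIVE = 70

TOOL_MISSING_COUNTS = {"HSF": 28, "SpliceAI": 11, "SSF": 5, "MES": 1, "NNSplice": 11}


def load_published_benchmark() -> pd.DataFrame:
    """Published per-tool benchmark rows (tool, n_missing, five metrics)."""
    with resources.files("splicedx.data").joinpath("published_benchmark.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
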