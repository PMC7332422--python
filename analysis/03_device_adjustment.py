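"""Emulate portable-device analytical-range truncation, fit conversion
regressions on laboratory studies, and adjust device-measured strata.

Writes strata.csv (with provenance column) and conversion_models.json.
"""

import pandas as pd

from common import OUT, run_config
from lipidtrends.pipeline import run_pipeline

run_pipeline(run_config(("simulate", "clean", "adjust")))
strata = pd.read_csv(f"{OUT}/strata.csv")
adj = strata[strata["provenance"] == "device-adjusted"]
print(f"{len(strata)} stratum summaries; {len(adj)} device-adjusted")
if len(adj):
    print("adjusted strata by metric:")
    print(adj["metric"].value_counts().to_string())
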