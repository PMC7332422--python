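"""Apply participant-level plausibility filters and collapse the cleaned
records into survey-weighted sex x age-band stratum summaries.

Writes exclusion_log.csv; the summaries feed the adjustment stage.
"""

import pandas as pd

from common import OUT, run_config
from lipidtrends.pipeline import run_pipeline

run_pipeline(run_config(("simulate", "clean")))
log = pd.read_csv(f"{OUT}/exclusion_log.csv")
removed = log.drop(columns=["study_id", "retained", "n_input", "config_hash"]).sum()
print("records removed per rule:")
print(removed.to_string())
print(f"retained: {log['retained'].sum():,} of {log['n_input'].sum():,}")
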