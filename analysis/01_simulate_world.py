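"""Generate the synthetic survey world: hierarchy, true cholesterol
surfaces, study portfolio and individual records.

Writes records.csv, studies.csv and truth.csv under results/analysis_run.
"""

import pandas as pd

from common import OUT, run_config
from lipidtrends.pipeline import run_pipeline

manifest = run_pipeline(run_config(("simulate",)))
studies = pd.read_csv(f"{OUT}/studies.csv")
records = pd.read_csv(f"{OUT}/records.csv")
print(f"simulated {len(records):,} records from {len(studies)} studies")
print(studies["coverage"].value_counts(normalize=True).round(3).to_string())
print(f"portable-device studies: {(studies['device_id'] != 'laboratory').mean():.1%}")
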