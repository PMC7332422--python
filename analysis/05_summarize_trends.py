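"""Age-standardized estimates, regional/global aggregates, change per
decade and posterior trend probabilities. Writes estimates.csv and
trends.csv.
"""

import pandas as pd

from common import OUT, run_config
from lipidtrends.pipeline import run_pipeline

run_pipeline(run_config(("simulate", "clean", "adjust", "fit", "summarize")))
trends = pd.read_csv(f"{OUT}/trends.csv")
world = trends[trends["entity_type"] == "world"]
cols = ["metric", "sex", "change_per_decade", "lo", "hi", "pp_decline", "pp_increase"]
print("world age-standardized change per decade (mmol/l):")
print(world[cols].round(3).to_string(index=False))
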