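"""External predictive validity: hold out 10% of countries (test 1) or
10% of sources (test 2), refit, and score the held-out stratum means.

Writes validation_countries.csv / validation_sources.csv and text
summaries.
"""

from common import OUT, run_config
from lipidtrends.pipeline import run_pipeline

run_pipeline(run_config(("simulate", "clean", "adjust", "validate")))
for kind in ("countries", "sources"):
    print(open(f"{OUT}/validation_{kind}.txt").read())
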