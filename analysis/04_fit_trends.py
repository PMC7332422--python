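"""Fit the hierarchical trend models: total cholesterol first, then the
non-HDL and HDL models with the age-standardized total-cholesterol
covariate. Writes MCMC diagnostics.
"""

import json

from common import OUT, run_config
from lipidtrends.pipeline import run_pipeline

run_pipeline(run_config(("simulate", "clean", "adjust", "fit")))
diag = json.load(open(f"{OUT}/mcmc_diagnostics.json"))
for key, d in diag.items():
    print(f"{key}: max split R-hat {d['max_rhat']:.3f} flagged={d['flagged']}")
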