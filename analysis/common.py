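"""Shared study configuration for the numbered analysis drivers.

One compact synthetic world (12 countries, 3 regions, 2000-2014) keeps
every driver runnable on a laptop in minutes; all computation lives in
the ``lipidtrends`` package.
"""

from lipidtrends.pipeline import RunConfig
from lipidtrends.synthetic_world import StudyConfig, WorldConfig

SEED = 1
OUT = "results/analysis_run"


def run_config(stages) -> RunConfig:
    return RunConfig(
        out_dir=OUT,
        seed=SEED,
        stages=stages,
        world=WorldConfig(
            n_countries=12,
            n_regions=3,
            n_super_regions=1,
            year_start=2000,
            year_end=2014,
            studies=StudyConfig(mean_studies_per_country=4.0),
        ),
        metrics=("total", "non_hdl", "hdl"),
        sexes=("female", "male"),
        n_burn=300,
        n_draws=500,
        validation_kinds=("countries", "sources"),
        validation_reps=5,
    )
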