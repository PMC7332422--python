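import numpy as np
import pytest

from lipidtrends import ingest_clean
from lipidtrends.synthetic_world import (
    StudyConfig,
    WorldConfig,
    generate_records,
    generate_studies,
    generate_world,
    studies_to_frame,
)


@pytest.fixture(scope="session")
def small_world():
    """A compact laboratory-only world shared by the model-facing tests:
    10 countries in 2 regions / 1 super-region over 2000-2009."""
    cfg = WorldConfig(
        n_countries=10,
        n_regions=2,
        n_super_regions=1,
        year_start=2000,
        year_end=2009,
        studies=StudyConfig(mean_studies_per_country=4.0, device_prob=0.0),
    )
    hierarchy, surfaces = generate_world(cfg, seed=7)
    studies = generate_studies(hierarchy, cfg.studies, seed=7)
    records = generate_records(hierarchy, surfaces, studies, cfg.records, seed=7)
    retained, log = ingest_clean.filter_participants(records)
    strata = ingest_clean.summarize_strata(
        retained, studies_meta=studies_to_frame(studies)
    )
    return {
        "config": cfg,
        "hierarchy": hierarchy,
        "surfaces": surfaces,
        "studies": studies,
        "studies_meta": studies_to_frame(studies),
        "records": records,
        "retained": retained,
        "exclusion_log": log,
        "strata": strata,
    }


@pytest.fixture(scope="session")
def small_fit(small_world):
    """One short total-cholesterol fit on the small world (female)."""
    from lipidtrends import trend_model

    return trend_model.fit_metric(
        small_world["strata"],
        small_world["hierarchy"],
        "total",
        "female",
        seed=11,
        n_burn=300,
        n_draws=300,
    )


def weighted_mean_se_oracle(values, weights):
    """Brute-force weighted mean / SE oracle used by the stratum tests."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    m = np.sum(weights * values) / np.sum(weights)
    n = len(values)
    n_eff = np.sum(weights) ** 2 / np.sum(weights**2)
    s2 = np.sum(weights * (values - m) ** 2) / np.sum(weights) * n / (n - 1)
    return m, np.sqrt(s2 / n_eff)
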