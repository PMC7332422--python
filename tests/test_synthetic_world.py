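"""Ground-truth generator: determinism, degenerate cases, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidtrends.bands import AGE_BAND_LABELS, SEXES
from lipidtrends.synthetic_world import (
    RecordConfig,
    StudyConfig,
    StudySource,
    SurfaceParams,
    WorldConfig,
    generate_records,
    generate_studies,
    generate_world,
    studies_to_frame,
)


def _tiny_cfg(**kwargs):
    base = dict(
        n_countries=6, n_regions=2, n_super_regions=1, year_start=2000, year_end=2009
    )
    base.update(kwargs)
    return WorldConfig(**base)


def _flat_params(metric_params: SurfaceParams, rw2_zero=True) -> SurfaceParams:
    return dataclasses.replace(
        metric_params,
        sd_intercept=(0.0, 0.0, 0.0),
        sd_slope_per_decade=(0.0, 0.0, 0.0),
        rw2_innovation_sd=(0.0, 0.0, 0.0, 0.0) if rw2_zero else metric_params.rw2_innovation_sd,
        sd_age_perturb=0.0,
        urban_effect=0.0,
    )


class TestGenerateWorld:
    def test_deterministic_under_seed(self):
        cfg = _tiny_cfg()
        h1, s1 = generate_world(cfg, seed=7)
        h2, s2 = generate_world(cfg, seed=7)
        assert np.array_equal(h1.population, h2.population)
        assert np.array_equal(h1.urbanization, h2.urbanization)
        for m in s1:
            assert np.array_equal(s1[m].values, s2[m].values)

    def test_zero_variance_collapses_to_global_curve(self):
        cfg = _tiny_cfg()
        cfg.total = _flat_params(cfg.total)
        cfg.hdl = _flat_params(cfg.hdl)
        _, surfaces = generate_world(cfg, seed=3)
        v = surfaces["total"].values
        # every country identical to the first
        assert np.allclose(v, v[0][None], atol=1e-12)

    def test_zero_rw2_gives_exactly_linear_trends(self):
        cfg = _tiny_cfg()
        cfg.total = dataclasses.replace(
            cfg.total, rw2_innovation_sd=(0.0, 0.0, 0.0, 0.0), urban_effect=0.0
        )
        _, surfaces = generate_world(cfg, seed=3)
        v = surfaces["total"].values  # (c, t, sex, band)
        second_diff = np.diff(v, n=2, axis=1)
        assert np.max(np.abs(second_diff)) < 1e-10

    def test_non_hdl_is_total_minus_hdl(self):
        _, surfaces = generate_world(_tiny_cfg(), seed=9)
        gap = surfaces["non_hdl"].values - (
            surfaces["total"].values - surfaces["hdl"].values
        )
        assert np.max(np.abs(gap)) < 1e-12

    def test_rejects_config_with_implausible_variances(self):
        cfg = _tiny_cfg()
        cfg.total = dataclasses.replace(cfg.total, sd_intercept=(5.0, 5.0, 5.0))
        with pytest.raises(ValueError, match="plausibility"):
            generate_world(cfg, seed=1)

    def test_hierarchy_and_bounds_invariants(self):
        h, surfaces = generate_world(_tiny_cfg(), seed=5)
        h.validate()
        assert np.all(surfaces["total"].values >= 1.75)
        assert np.all(surfaces["total"].values <= 20)
        assert np.all(surfaces["hdl"].values >= 0.4)
        assert np.all(surfaces["hdl"].values <= 5)


class TestGenerateStudies:
    def test_zero_community_fraction(self):
        h, _ = generate_world(_tiny_cfg(), seed=7)
        sc = StudyConfig(coverage_probs=(0.6, 0.4, 0.0))
        studies = generate_studies(h, sc, seed=7)
        assert all(s.coverage != "community" for s in studies)

    def test_national_fraction_within_binomial_bounds(self):
        # 1,000 studies at the default mixture: the national count must sit
        # inside the central 99% binomial band around p = 0.363
        h, _ = generate_world(_tiny_cfg(n_countries=10), seed=7)
        sc = StudyConfig(studies_per_country={c: 100 for c in h.country_ids})
        studies = generate_studies(h, sc, seed=7)
        assert len(studies) == 1000
        n_nat = sum(s.coverage == "national" for s in studies)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.363)
        assert lo <= n_nat <= hi

    def test_zero_offset_variance_gives_configured_means(self):
        h, _ = generate_world(_tiny_cfg(), seed=7)
        sc = StudyConfig(
            offset_sd={"national": 0.0, "subnational": 0.0, "community": 0.0}
        )
        for s in generate_studies(h, sc, seed=7):
            assert s.offsets["total"] == pytest.approx(sc.offset_mean[s.coverage])

    def test_device_share_and_determinism(self):
        h, _ = generate_world(_tiny_cfg(n_countries=10), seed=7)
        sc = StudyConfig(studies_per_country={c: 100 for c in h.country_ids})
        s1 = generate_studies(h, sc, seed=4)
        s2 = generate_studies(h, sc, seed=4)
        assert studies_to_frame(s1).equals(studies_to_frame(s2))
        n_dev = sum(s.device_id is not None for s in s1)
        lo, hi = stats.binom.ppf([0.005, 0.995], len(s1), 0.10)
        assert lo <= n_dev <= hi


def _one_stratum_study(country, year, n, offset=0.0, coverage="national"):
    stratum_n = {(sex, b): 0 for sex in SEXES for b in AGE_BAND_LABELS}
    stratum_n[("female", "40-49")] = n
    return StudySource(
        study_id="S-test",
        country=country,
        year=year,
        coverage=coverage,
        urbanicity="mixed",
        frame="probabilistic",
        device_id=None,
        stratum_n=stratum_n,
        offsets={"total": offset, "hdl": offset * 0.3},
        extra_sd=0.0,
    )


class TestGenerateRecords:
    def test_sample_mean_near_truth_at_large_n(self):
        h, surf = generate_world(_tiny_cfg(), seed=7)
        study = _one_stratum_study("C000", 2005, 100_000)
        rc = RecordConfig(injection_rate=0.0, under18_rate=0.0, pregnancy_rate=0.0)
        rec = generate_records(h, surf, [study], rc, seed=7)
        truth = rec["_true_mean_total"].iloc[0]
        se = rc.within_sd["total"] / np.sqrt(len(rec))
        assert abs(rec["total"].mean() - truth) < 3 * se

    @pytest.mark.parametrize("n", [100, 10_000])
    def test_empirical_recovery_rate(self, n):
        h, surf = generate_world(_tiny_cfg(), seed=7)
        study = _one_stratum_study("C001", 2004, n, offset=0.25, coverage="subnational")
        study.extra_sd = 0.0
        rc = RecordConfig(injection_rate=0.0, under18_rate=0.0, pregnancy_rate=0.0)
        rec = generate_records(h, surf, [study], rc, seed=11)
        truth = surf["total"].at(h, "C001", 2004, "female", "40-49") + 0.25
        assert abs(rec["total"].mean() - truth) < 5 * rc.within_sd["total"] / np.sqrt(n)

    def test_injection_count_within_binomial_bounds(self):
        h, surf = generate_world(_tiny_cfg(), seed=7)
        study = _one_stratum_study("C000", 2005, 10_000)
        rc = RecordConfig(injection_rate=0.01, under18_rate=0.0, pregnancy_rate=0.0)
        rec = generate_records(h, surf, [study], rc, seed=13)
        count = int(rec["_injected_total"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.01)
        assert lo <= count <= hi
        # injected values are guaranteed implausible
        inj = rec.loc[rec["_injected_total"], "total"]
        assert ((inj < 1.75) | (inj > 20)).all()

    def test_no_pregnant_or_minor_when_rates_zero(self):
        h, surf = generate_world(_tiny_cfg(), seed=7)
        study = _one_stratum_study("C000", 2005, 500)
        rc = RecordConfig(pregnancy_rate=0.0, under18_rate=0.0, injection_rate=0.0)
        rec = generate_records(h, surf, [study], rc, seed=5)
        assert not rec["pregnant"].any()
        assert (rec["age"] >= 18).all()

    def test_records_deterministic(self):
        h, surf = generate_world(_tiny_cfg(), seed=7)
        studies = generate_studies(h, StudyConfig(mean_studies_per_country=2), seed=7)
        r1 = generate_records(h, surf, studies, RecordConfig(), seed=21)
        r2 = generate_records(h, surf, studies, RecordConfig(), seed=21)
        pd.testing.assert_frame_equal(r1, r2)
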