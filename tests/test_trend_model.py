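"""Hierarchical model: design assembly, sampler correctness, shrinkage."""

import numpy as np
import pandas as pd
import pytest

from lipidtrends import trend_model
from lipidtrends.bands import AGE_BAND_LABELS
from lipidtrends.synthetic_world import GeoHierarchy
from lipidtrends.trend_model import (
    ModelSpec,
    _constraint_basis,
    _surface_from_beta,
    build_design,
    fit_mcmc,
    fit_metric,
    predict_surface,
)


def _toy_hierarchy(n_c=2, n_t=10, urban=0.6):
    years = np.arange(2000, 2000 + n_t)
    countries = [f"C{i:03d}" for i in range(n_c)]
    return GeoHierarchy(
        country_ids=countries,
        region_of={c: "R00" for c in countries},
        super_region_of_region={"R00": "SR0"},
        years=years,
        population=np.ones((n_c, n_t, 2, 8)),
        urbanization=np.full((n_c, n_t), urban),
    )


def _stratum(country="C000", year=2004, coverage="national", urbanicity="mixed",
             mean=5.0, se=0.1, study_id="S1", band="40-49", sex="female"):
    return {
        "study_id": study_id, "country": country, "year": year, "sex": sex,
        "age_band": band, "metric": "total", "mean": mean, "se": se,
        "coverage": coverage, "urbanicity": urbanicity,
    }


class TestBuildDesign:
    def test_national_mixed_study_has_no_study_type_terms(self):
        h = _toy_hierarchy()
        am = build_design(pd.DataFrame([_stratum()]), h, ModelSpec(), "total", "female")
        fx = am.blocks["fixed"][0]
        row = am.X.toarray()[0]
        # fe_sub, fe_com, fe_rural, fe_urban are the last four fixed slots
        assert np.allclose(row[fx + 3 : fx + 7], 0.0)
        assert am.blocks["re_study"][0] == am.blocks["re_study"][1]

    def test_rural_and_urban_weights_follow_urban_share(self):
        # country 60% urban: rural-only effect enters with weight 0.6,
        # urban-only with 0.4 (hand evaluation of the weighting rule)
        h = _toy_hierarchy(urban=0.6)
        strata = pd.DataFrame(
            [
                _stratum(coverage="subnational", urbanicity="rural", study_id="S1"),
                _stratum(coverage="subnational", urbanicity="urban", study_id="S2"),
            ]
        )
        am = build_design(strata, h, ModelSpec(), "total", "female")
        fx = am.blocks["fixed"][0]
        X = am.X.toarray()
        i_rural, i_urban = fx + 5, fx + 6
        assert X[0, i_rural] == pytest.approx(0.6)
        assert X[0, i_urban] == 0.0
        assert X[1, i_urban] == pytest.approx(0.4)
        assert X[1, i_rural] == 0.0

    def test_same_study_shares_one_random_effect(self):
        h = _toy_hierarchy()
        strata = pd.DataFrame(
            [
                _stratum(coverage="subnational", study_id="S9", band="30-39"),
                _stratum(coverage="subnational", study_id="S9", band="50-59"),
            ]
        )
        am = build_design(strata, h, ModelSpec(), "total", "female")
        start, stop = am.blocks["re_study"]
        assert stop - start == 1
        X = am.X.toarray()
        assert X[0, start] == 1.0 and X[1, start] == 1.0

    def test_unknown_country_and_year_are_hard_errors(self):
        h = _toy_hierarchy()
        with pytest.raises(ValueError, match="not in hierarchy"):
            build_design(
                pd.DataFrame([_stratum(country="XX")]), h, ModelSpec(), "total", "female"
            )
        with pytest.raises(ValueError, match="outside model range"):
            build_design(
                pd.DataFrame([_stratum(year=1990)]), h, ModelSpec(), "total", "female"
            )

    def test_constraint_basis_orthogonal_to_constant_and_trend(self):
        Z = _constraint_basis(12)
        t = np.arange(12, dtype=float)
        assert np.allclose(Z.T @ np.ones(12), 0, atol=1e-10)
        assert np.allclose(Z.T @ (t - t.mean()), 0, atol=1e-10)
        assert np.allclose(Z.T @ Z, np.eye(10), atol=1e-10)


class TestSampler:
    def _flat_strata(self, level=4.6, se=0.01, n_per_year=3):
        rows = []
        for year in range(2000, 2010):
            for k in range(n_per_year):
                rows.append(
                    _stratum(year=year, mean=level, se=se, study_id=f"S{year}-{k}")
                )
        return pd.DataFrame(rows)

    def test_posterior_matches_conjugate_oracle_on_flat_data(self):
        # one country, flat truth, 30 national strata with tiny SEs: the
        # posterior surface must match the normal-normal closed form, which
        # collapses to the data mean at these SEs
        h = _toy_hierarchy(n_c=1)
        strata = self._flat_strata()
        fit = fit_metric(strata, h, "total", "female", seed=5, n_burn=300, n_draws=300)
        prior_prec = 1 / ModelSpec().priors.fixed_sd**2
        data_prec = (1 / strata["se"] ** 2).sum()
        oracle = (strata["mean"] / strata["se"] ** 2).sum() / (data_prec + prior_prec)
        pm = fit.surface[:, 0, :, AGE_BAND_LABELS.index("40-49")].mean()
        assert abs(pm - oracle) < 0.05

    def test_seed_reproducibility(self):
        h = _toy_hierarchy(n_c=1)
        strata = self._flat_strata(se=0.1)
        f1 = fit_metric(strata, h, "total", "female", seed=9, n_burn=50, n_draws=50)
        f2 = fit_metric(strata, h, "total", "female", seed=9, n_burn=50, n_draws=50)
        assert np.array_equal(f1.surface, f2.surface)

    def test_draw_count_contract(self):
        h = _toy_hierarchy(n_c=1)
        strata = self._flat_strata(se=0.1)
        fit = fit_metric(strata, h, "total", "female", seed=2, n_burn=30, n_draws=77)
        assert fit.n_draws == 77
        assert np.all(np.isfinite(fit.surface))

    def test_default_draw_count_is_5000(self):
        assert ModelSpec().mcmc.n_draws == 5000

    def test_rw2_constraints_hold_in_every_draw(self, small_fit):
        am = small_fit.model
        Z = am.Z
        t = np.arange(len(am.years), dtype=float)
        for name in ("rw2_world", "rw2_c"):
            start, stop = am.blocks[name]
            k_rw = Z.shape[1]
            W = small_fit.beta[:, start:stop].astype(float).reshape(
                small_fit.n_draws, -1, k_rw
            )
            U = W @ Z.T  # deviations on the year grid
            assert np.max(np.abs(U.sum(axis=-1))) < 1e-4  # float32 storage
            detrend = U @ (t - t.mean())
            assert np.max(np.abs(detrend)) < 1e-3

    def test_surface_recovers_truth_on_small_world(self, small_world, small_fit):
        truth = small_world["surfaces"]["total"].values[:, :, 0, :]
        pm = small_fit.surface.astype(float).mean(axis=0)
        assert np.abs(pm - truth).mean() < 0.15

    def test_predict_surface_identity_for_intercept_only(self):
        h = _toy_hierarchy(n_c=2)
        am = build_design(
            pd.DataFrame([_stratum()]), h, ModelSpec(), "total", "female"
        )
        beta = np.zeros(am.n_params)
        beta[am.blocks["fixed"][0]] = 4.6
        surf = _surface_from_beta(am, beta)
        assert np.allclose(surf, 4.6)

    def test_predict_surface_index_errors(self, small_fit):
        with pytest.raises(IndexError):
            predict_surface(small_fit, small_fit.countries[0], 1900, "40-49")

    def test_no_data_country_tracks_region(self):
        # a country with no sources must follow the common signal of its
        # region rather than drift to the prior mean
        h = _toy_hierarchy(n_c=4)
        rows = []
        for ci in range(1, 4):  # C000 has no data
            for year in range(2000, 2010):
                rows.append(
                    _stratum(
                        country=f"C{ci:03d}", year=year, mean=5.5, se=0.05,
                        study_id=f"S{ci}-{year}",
                    )
                )
        fit = fit_metric(
            pd.DataFrame(rows), h, "total", "female", seed=3, n_burn=300, n_draws=300
        )
        ai = AGE_BAND_LABELS.index("40-49")
        nodata = fit.surface[:, 0, :, ai].astype(float)
        others = fit.surface[:, 1:, :, ai].astype(float).mean(axis=1)
        dev = np.abs(nodata.mean(axis=0) - others.mean(axis=0))
        assert dev.max() < 3 * max(others.std(axis=0).max(), 0.05)

    def test_shrinkage_between_community_study_and_region(self):
        h = _toy_hierarchy(n_c=4)
        rows = []
        for ci in range(1, 4):
            for year in range(2000, 2010):
                rows.append(
                    _stratum(
                        country=f"C{ci:03d}", year=year, mean=5.0, se=0.05,
                        study_id=f"S{ci}-{year}",
                    )
                )
        # target country: one small community study displaced upward
        rows.append(
            _stratum(
                country="C000", year=2005, mean=5.8, se=0.15,
                coverage="community", urbanicity="mixed", study_id="S-comm",
            )
        )
        fit = fit_metric(
            pd.DataFrame(rows), h, "total", "female", seed=13, n_burn=400, n_draws=400
        )
        ai = AGE_BAND_LABELS.index("40-49")
        target = fit.surface[:, 0, 5, ai].astype(float).mean()
        region = 5.0
        assert region - 0.02 < target < 5.8 + 0.02
        # pulled toward its own study, though the random-effect discount on
        # a single community source keeps the pull deliberately small
        assert target > region + 0.001


class TestSequence:
    def test_fraction_model_accepts_tc_covariate(self, small_world):
        h = small_world["hierarchy"]
        strata = small_world["strata"]
        tc_cov = small_world["surfaces"]["total"].values[:, :, 0, :].mean(axis=-1)
        fit = fit_metric(
            strata, h, "hdl", "female", seed=4, tc_covariate=tc_cov,
            n_burn=80, n_draws=80,
        )
        assert fit.model.has_tc_cov
        assert np.all(np.isfinite(fit.surface))

    def test_bad_covariate_shape_rejected(self, small_world):
        with pytest.raises(ValueError, match="tc_covariate"):
            build_design(
                small_world["strata"], small_world["hierarchy"], ModelSpec(),
                "hdl", "female", tc_covariate=np.ones((2, 2)),
            )
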