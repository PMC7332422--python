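"""Analytical-range truncation and conversion regressions."""

import numpy as np
import pandas as pd
import pytest

from lipidtrends.device_adjust import (
    ConversionModel,
    DeviceSpec,
    apply_conversion,
    fit_conversion,
    make_training_pairs,
    truncate_to_device,
)

SPEC = DeviceSpec("dev", "total", 2.5, 6.5)


class TestTruncate:
    def test_quoted_example(self):
        out = truncate_to_device([2.0, 3.0, 7.0], SPEC)
        assert out.tolist() == [3.0]

    def test_at_bound_values_dropped(self):
        out = truncate_to_device([2.5, 6.5, 5.0], SPEC)
        assert out.tolist() == [5.0]

    def test_wide_range_is_identity(self):
        vals = [3.0, 4.0, 5.0]
        wide = DeviceSpec("dev", "total", 1.8, 19.0)
        assert truncate_to_device(vals, wide).tolist() == vals

    def test_upper_bound_strictly_decreases_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, 500).clip(2.2, 9.0)
        spec = DeviceSpec("dev", "total", 1.8, float(vals.max()) - 0.1)
        assert truncate_to_device(vals, spec).mean() < vals.mean()

    def test_lower_bound_strictly_increases_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, 500).clip(2.2, 9.0)
        spec = DeviceSpec("dev", "total", float(vals.min()) + 0.1, 19.9)
        assert truncate_to_device(vals, spec).mean() > vals.mean()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DeviceSpec("dev", "total", 6.0, 3.0)
        with pytest.raises(ValueError):
            DeviceSpec("dev", "total", 0.5, 6.0)  # outside plausibility window


def _lab_records(rng, n_strata=40, n_per=60, mean=5.0, sd=1.0, distort=None):
    """Synthetic laboratory strata; distort optionally maps full means."""
    rows = []
    meta = []
    for k in range(n_strata):
        sid = f"L{k:03d}"
        sex = "female" if k % 2 == 0 else "male"
        age = 20 + 10 * (k % 6)
        mu = mean + rng.normal(0, 0.6)
        vals = (mu + sd * rng.standard_normal(n_per)).clip(2.3, 12.0)
        rows.append(
            pd.DataFrame(
                {
                    "study_id": sid, "age": age, "sex": sex, "weight": 1.0,
                    "total": vals, "hdl": 1.3, "ldl": np.nan,
                }
            )
        )
        meta.append({"study_id": sid, "device_id": "laboratory"})
    return pd.concat(rows, ignore_index=True), pd.DataFrame(meta)


class TestTrainingPairs:
    def test_small_stratum_excluded(self):
        rng = np.random.default_rng(1)
        rec, meta = _lab_records(rng, n_strata=6, n_per=30)
        small = rec[rec["study_id"] == "L000"].head(24)
        rec = pd.concat([rec[rec["study_id"] != "L000"], small], ignore_index=True)
        pairs = make_training_pairs(rec, meta, SPEC, "total")
        assert "L000" not in set(pairs["study_id"])

    def test_covering_range_gives_identity_pairs(self):
        rng = np.random.default_rng(2)
        rec, meta = _lab_records(rng)
        wide = DeviceSpec("dev", "total", 1.8, 19.0)
        pairs = make_training_pairs(rec, meta, wide, "total")
        assert np.allclose(pairs["full_mean"], pairs["restricted_mean"])

    def test_truncated_mean_gap_matches_monte_carlo_oracle(self):
        # normal(5, 1) truncated above at 6.0: compare the restricted mean
        # with a large-sample Monte-Carlo oracle
        rng = np.random.default_rng(3)
        n = 400_000
        vals = 5.0 + rng.standard_normal(n)
        rec = pd.DataFrame(
            {
                "study_id": "L000", "age": 45, "sex": "female", "weight": 1.0,
                "total": vals, "hdl": 1.3, "ldl": np.nan,
            }
        )
        meta = pd.DataFrame([{"study_id": "L000", "device_id": "laboratory"}])
        spec = DeviceSpec("dev", "total", 1.8, 6.0)
        pairs = make_training_pairs(rec, meta, spec, "total")
        oracle_draws = 5.0 + np.random.default_rng(4).standard_normal(1_000_000)
        oracle = oracle_draws[oracle_draws < 6.0].mean()
        assert pairs.iloc[0]["restricted_mean"] == pytest.approx(oracle, abs=0.01)

    def test_empty_training_set_is_hard_error(self):
        rec = pd.DataFrame(
            {
                "study_id": ["L0"], "age": [40], "sex": ["female"],
                "weight": [1.0], "total": [5.0], "hdl": [1.3], "ldl": [np.nan],
            }
        )
        meta = pd.DataFrame([{"study_id": "L0", "device_id": "laboratory"}])
        with pytest.raises(ValueError, match="empty training set"):
            make_training_pairs(rec, meta, SPEC, "total")


def _ols_bic_oracle(y, X):
    """Independent Gaussian log-likelihood / BIC computation."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    s2 = resid @ resid / n
    loglik = -n / 2 * (np.log(2 * np.pi * s2) + 1)
    return len(beta) * np.log(n) - 2 * loglik


class TestFitConversion:
    def test_no_truncation_recovers_identity(self):
        rng = np.random.default_rng(5)
        rec, meta = _lab_records(rng)
        wide = DeviceSpec("dev", "total", 1.8, 19.0)
        pairs = make_training_pairs(rec, meta, wide, "total")
        model = fit_conversion(pairs, "total")
        coef = dict(zip(model.terms, model.params))
        assert coef["restricted_mean"] == pytest.approx(1.0, abs=1e-6)
        assert coef["const"] == pytest.approx(0.0, abs=1e-6)

    def test_known_affine_distortion_recovered(self):
        rng = np.random.default_rng(6)
        rec, meta = _lab_records(rng, n_strata=80)
        wide = DeviceSpec("dev", "total", 1.8, 19.0)
        pairs = make_training_pairs(rec, meta, wide, "total")
        noise_sd = 0.05
        pairs["full_mean"] = (
            0.4 + 0.9 * pairs["restricted_mean"]
            + noise_sd * rng.standard_normal(len(pairs))
        )
        model = fit_conversion(pairs, "total")
        coef = dict(zip(model.terms, model.params))
        se_slope = noise_sd / (
            np.sqrt(len(pairs)) * pairs["restricted_mean"].std()
        )
        assert coef["restricted_mean"] == pytest.approx(0.9, abs=2 * se_slope * 3)
        assert abs(coef["const"] - 0.4) < 0.2

    def test_selected_bic_not_beaten_by_any_candidate(self):
        from lipidtrends.device_adjust import _candidate_term_sets, _design

        rng = np.random.default_rng(7)
        rec, meta = _lab_records(rng, n_strata=60)
        spec = DeviceSpec("dev", "total", 3.5, 6.0)
        pairs = make_training_pairs(rec, meta, spec, "total")
        model = fit_conversion(pairs, "total")
        y = pairs["full_mean"].to_numpy()
        for terms in _candidate_term_sets("total"):
            X = _design(pairs, terms)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            assert model.bic <= _ols_bic_oracle(y, X) + 1e-8

    def test_selected_bic_matches_oracle(self):
        rng = np.random.default_rng(8)
        rec, meta = _lab_records(rng, n_strata=50)
        spec = DeviceSpec("dev", "total", 3.5, 6.0)
        pairs = make_training_pairs(rec, meta, spec, "total")
        model = fit_conversion(pairs, "total")
        from lipidtrends.device_adjust import _design

        X = _design(pairs, model.terms)
        assert model.bic == pytest.approx(
            _ols_bic_oracle(pairs["full_mean"].to_numpy(), X), rel=1e-10
        )


class TestApplyConversion:
    def _identity_model(self):
        return ConversionModel(
            metric="total", device_id="dev",
            terms=["const", "restricted_mean"],
            params=np.array([0.2, 1.0]),
            cov_params=np.zeros((2, 2)),
            resid_sd=0.0, n_obs=100, bic=0.0,
        )

    def test_degenerate_model_returns_point_prediction(self):
        model = self._identity_model()
        stratum = {"metric": "total", "mean": 5.0, "se": 0.0, "age_band": "40-49",
                   "sex": "female", "device_id": "dev"}
        draws = apply_conversion(stratum, model, n_draws=50, seed=1)
        assert np.allclose(draws, 5.2)

    def test_draw_spread_at_least_input_se(self):
        model = self._identity_model()
        model.resid_sd = 0.1
        stratum = {"metric": "total", "mean": 5.0, "se": 0.2, "age_band": "40-49",
                   "sex": "female", "device_id": "dev"}
        draws = apply_conversion(stratum, model, n_draws=4000, seed=2)
        assert draws.std() >= 0.2 * 0.9  # sampling + residual noise only adds

    def test_metric_mismatch_is_hard_error(self):
        model = self._identity_model()
        stratum = {"metric": "hdl", "mean": 1.0, "se": 0.1, "age_band": "40-49",
                   "sex": "female", "device_id": "dev"}
        with pytest.raises(ValueError, match="metric mismatch"):
            apply_conversion(stratum, model)

    def test_json_round_trip(self):
        model = self._identity_model()
        back = ConversionModel.from_json(model.to_json())
        assert back.terms == model.terms
        assert np.allclose(back.params, model.params)
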