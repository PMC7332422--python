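"""Portable-device analytical-range truncation and conversion regressions.

Portable lipid analyzers report values only inside their analytical
range; participants at or beyond a range limit are dropped before the
stratum mean is computed, which biases it toward the centre. Conversion
regressions map the restricted-range mean back to a laboratory-equivalent
full-range mean. Training pairs are built from laboratory studies: the
response is the full-data weighted stratum mean and the predictor is the
mean after mimicking the device truncation; strata with fewer than 25
individuals are excluded. Terms for age and sex are always included;
interactions are toggled by BIC. Non-HDL conversions additionally use the
stratum mean total and HDL cholesterol. Applying a conversion propagates
the input mean's sampling noise, coefficient uncertainty and residual
noise via repeated draws.

Device analytical ranges are configuration inputs; the fixtures shipped
with the package are illustrative synthetic values, not manufacturer
specifications.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bands import (
    AGE_BAND_LABELS,
    AGE_BAND_MIDPOINTS,
    PLAUSIBLE_RANGE,
    band_index_for_age,
)

logger = logging.getLogger(__name__)

_MIDPOINT = dict(zip(AGE_BAND_LABELS, AGE_BAND_MIDPOINTS))


@dataclass
class DeviceSpec:
    device_id: str
    metric: str
    range_min: float
    range_max: float

    def __post_init__(self):
        if not self.range_min < self.range_max:
            raise ValueError("analytical range requires min < max")
        # non-HDL has no plausibility window of its own (it is a difference
        # of two filtered metrics); constrain it only to be positive
        lo, hi = PLAUSIBLE_RANGE.get(self.metric, (0.0, 20.0))
        if self.range_min < lo or self.range_max > hi:
            raise ValueError(
                f"analytical range ({self.range_min}, {self.range_max}) must lie "
                f"within the {self.metric} plausibility window ({lo}, {hi})"
            )


def truncate_to_device(values: np.ndarray, spec: DeviceSpec) -> np.ndarray:
    """Keep values strictly inside the analytical range.

    Values below or at the minimum, and at or above the maximum, are
    dropped — at-limit readings are indistinguishable from out-of-range
    codes on these devices.
    """
    v = np.asarray(values, dtype=float)
    return v[(v > spec.range_min) & (v < spec.range_max)]


@dataclass
class ConversionModel:
    metric: str
    device_id: str
    terms: list
    params: np.ndarray
    cov_params: np.ndarray
    resid_sd: float
    n_obs: int
    bic: float
    age_scale: tuple = (50.0, 35.0)  # age standardized as (age - 50) / 35

    def design_row(self, restricted_mean, age_mid, sex_male, tc_mean=np.nan, hdl_mean=np.nan):
        z = (age_mid - self.age_scale[0]) / self.age_scale[1]
        feat = {
            "const": 1.0,
            "restricted_mean": restricted_mean,
            "age": z,
            "sex_male": float(sex_male),
            "tc_mean": tc_mean,
            "hdl_mean": hdl_mean,
            "restricted_mean:age": restricted_mean * z,
            "restricted_mean:sex_male": restricted_mean * float(sex_male),
            "tc_mean:sex_male": tc_mean * float(sex_male),
            "hdl_mean:sex_male": hdl_mean * float(sex_male),
        }
        return np.array([feat[t] for t in self.terms], dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "metric": self.metric,
                "device_id": self.device_id,
                "terms": self.terms,
                "params": self.params.tolist(),
                "cov_params": self.cov_params.tolist(),
                "resid_sd": self.resid_sd,
                "n_obs": self.n_obs,
                "bic": self.bic,
                "age_scale": list(self.age_scale),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ConversionModel":
        d = json.loads(text)
        return cls(
            metric=d["metric"],
            device_id=d["device_id"],
            terms=d["terms"],
            params=np.asarray(d["params"]),
            cov_params=np.asarray(d["cov_params"]),
            resid_sd=d["resid_sd"],
            n_obs=d["n_obs"],
            bic=d["bic"],
            age_scale=tuple(d["age_scale"]),
        )


def make_training_pairs(
    records: pd.DataFrame,
    studies_meta: pd.DataFrame,
    spec: DeviceSpec,
    metric: str,
    min_n: int = 25,
    companion_specs: dict | None = None,
) -> pd.DataFrame:
    """Build (full mean, restricted mean) pairs from laboratory studies.

    One row per laboratory study x sex x age band with at least ``min_n``
    individuals. The restricted predictor mimics the device by dropping
    values outside (range_min, range_max) before averaging. For non-HDL
    the stratum mean total and HDL cholesterol are carried as extra
    predictors; when ``companion_specs`` gives DeviceSpec entries for
    "total" and "hdl", those predictor means are restricted to the
    companion device ranges — matching what a device survey can supply
    at application time (without this, the full-range difference
    TC − HDL reproduces the response exactly and the regression
    degenerates to a deterministic identity).
    """
    lab_ids = set(
        studies_meta.loc[
            studies_meta["device_id"].isin([None, "laboratory"])
            | studies_meta["device_id"].isna(),
            "study_id",
        ]
    )
    df = records[records["study_id"].isin(lab_ids)].copy()
    df["age_band"] = np.array(AGE_BAND_LABELS, dtype=object)[
        band_index_for_age(df["age"].to_numpy())
    ]
    df["non_hdl"] = df["total"] - df["hdl"]

    rows = []
    for (study_id, sex, band), g in df.groupby(["study_id", "sex", "age_band"]):
        vals = g[metric].to_numpy(dtype=float)
        w = g["weight"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        vals, w = vals[ok], w[ok]
        if len(vals) < min_n:
            continue
        keep = (vals > spec.range_min) & (vals < spec.range_max)
        if keep.sum() < 2:
            continue
        full_mean = float(np.average(vals, weights=w))
        restricted_mean = float(np.average(vals[keep], weights=w[keep]))
        row = {
            "study_id": study_id,
            "sex": sex,
            "age_band": band,
            "age_mid": _MIDPOINT[band],
            "sex_male": 1.0 if sex == "male" else 0.0,
            "n": int(len(vals)),
            "full_mean": full_mean,
            "restricted_mean": restricted_mean,
        }
        if metric == "non_hdl":
            gtc = g["total"].to_numpy(dtype=float)[ok]
            ghdl = g["hdl"].to_numpy(dtype=float)[ok]
            ktc = np.ones(len(gtc), dtype=bool)
            khdl = np.ones(len(ghdl), dtype=bool)
            if companion_specs:
                if "total" in companion_specs:
                    cs = companion_specs["total"]
                    ktc = (gtc > cs.range_min) & (gtc < cs.range_max)
                if "hdl" in companion_specs:
                    cs = companion_specs["hdl"]
                    khdl = (ghdl > cs.range_min) & (ghdl < cs.range_max)
            if ktc.sum() < 2 or khdl.sum() < 2:
                continue
            row["tc_mean"] = float(np.average(gtc[ktc], weights=w[ktc]))
            row["hdl_mean"] = float(np.average(ghdl[khdl], weights=w[khdl]))
        rows.append(row)
    if not rows:
        raise ValueError(
            f"empty training set for device {spec.device_id} / {metric}: no "
            f"laboratory stratum with >= {min_n} individuals"
        )
    return pd.DataFrame(rows)


def _candidate_term_sets(metric: str):
    base = ["const", "restricted_mean", "age", "sex_male"]
    inter = ["restricted_mean:age", "restricted_mean:sex_male"]
    if metric == "non_hdl":
        base = base + ["tc_mean", "hdl_mean"]
        inter = inter + ["tc_mean:sex_male", "hdl_mean:sex_male"]
    for r in range(len(inter) + 1):
        for combo in itertools.combinations(inter, r):
            yield base + list(combo)


def _design(pairs: pd.DataFrame, terms, age_scale=(50.0, 35.0)):
    z = (pairs["age_mid"].to_numpy() - age_scale[0]) / age_scale[1]
    cols = {
        "const": np.ones(len(pairs)),
        "restricted_mean": pairs["restricted_mean"].to_numpy(),
        "age": z,
        "sex_male": pairs["sex_male"].to_numpy(),
    }
    if "tc_mean" in pairs:
        cols["tc_mean"] = pairs["tc_mean"].to_numpy()
        cols["hdl_mean"] = pairs["hdl_mean"].to_numpy()
    cols["restricted_mean:age"] = cols["restricted_mean"] * z
    cols["restricted_mean:sex_male"] = cols["restricted_mean"] * cols["sex_male"]
    if "tc_mean" in cols:
        cols["tc_mean:sex_male"] = cols["tc_mean"] * cols["sex_male"]
        cols["hdl_mean:sex_male"] = cols["hdl_mean"] * cols["sex_male"]
    return np.column_stack([cols[t] for t in terms])


def fit_conversion(
    pairs: pd.DataFrame, metric: str, device_id: str = "device"
) -> ConversionModel:
    """OLS conversion regression with exhaustive BIC interaction search.

    Base terms (intercept, restricted mean, age, sex, and for non-HDL the
    stratum total/HDL means) are always in; every subset of the candidate
    interactions is scored and the lowest BIC wins, ties broken toward
    fewer terms. Aliased columns in a rank-deficient design are dropped
    with a warning.
    """
    y = pairs["full_mean"].to_numpy(dtype=float)
    best = None
    for terms in _candidate_term_sets(metric):
        X = _design(pairs, terms)
        terms_used = list(terms)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # drop aliased columns via pivoted QR on the normal equations
            _, _, piv = _pivoted_qr(X)
            keep = sorted(piv[:rank])
            dropped = [terms_used[i] for i in range(len(terms_used)) if i not in keep]
            logger.warning("dropping aliased terms %s", dropped)
            terms_used = [terms_used[i] for i in keep]
            X = X[:, keep]
        if X.shape[0] < X.shape[1] + 2:
            continue
        res = sm.OLS(y, X).fit()
        key = (res.bic, len(terms_used))
        if best is None or key < best[0]:
            best = (key, terms_used, res)
    if best is None:
        raise ValueError("no candidate model could be fitted (too few pairs)")
    _, terms_used, res = best
    resid_sd = float(np.sqrt(res.mse_resid))
    return ConversionModel(
        metric=metric,
        device_id=device_id,
        terms=terms_used,
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        resid_sd=resid_sd,
        n_obs=int(res.nobs),
        bic=float(res.bic),
    )


def _pivoted_qr(X):
    from scipy.linalg import qr

    return qr(X, mode="economic", pivoting=True)


def apply_conversion(
    stratum: dict | pd.Series,
    model: ConversionModel,
    n_draws: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Draws of the laboratory-equivalent mean for one device stratum.

    Combines (i) sampling noise of the restricted-range input mean (its
    SE), (ii) regression-coefficient uncertainty, and (iii) residual
    noise. Returns ``n_draws`` samples; summarize downstream.
    """
    if stratum.get("metric", model.metric) != model.metric:
        raise ValueError(
            f"metric mismatch: stratum {stratum.get('metric')} vs model {model.metric}"
        )
    dev = stratum.get("device_id")
    if dev not in (model.device_id, None):
        raise ValueError(f"device mismatch: stratum {dev} vs model {model.device_id}")
    rng = np.random.default_rng(seed)
    se = float(stratum.get("se", 0.0) or 0.0)
    mean = float(stratum["mean"])
    x_draws = mean + se * rng.standard_normal(n_draws)
    sex_male = stratum.get("sex_male")
    if sex_male is None:
        sex_male = 1.0 if stratum.get("sex") == "male" else 0.0
    age_mid = stratum.get("age_mid") or _MIDPOINT[stratum["age_band"]]
    rows = np.stack(
        [
            model.design_row(
                x,
                age_mid,
                sex_male,
                stratum.get("tc_mean", np.nan),
                stratum.get("hdl_mean", np.nan),
            )
            for x in x_draws
        ]
    )
    cov = (model.cov_params + model.cov_params.T) / 2.0
    beta = rng.multivariate_normal(model.params, cov, size=n_draws, method="svd")
    preds = np.einsum("ij,ij->i", rows, beta)
    preds = preds + model.resid_sd * rng.standard_normal(n_draws)
    return preds


def adjust_device_strata(
    strata: pd.DataFrame,
    models: dict,
    n_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Replace device-measured stratum means with conversion-draw summaries.

    ``models`` maps (metric, device_id) to a ConversionModel. Laboratory
    strata pass through untouched; adjusted rows get provenance
    "device-adjusted" and SE = SD of the draws. Total and HDL strata are
    adjusted first; non-HDL conversions then use the (adjusted) total
    and HDL means of the same stratum as extra predictors.
    """
    out = strata.copy()
    out["provenance"] = "laboratory"
    rng = np.random.default_rng(seed)

    def is_device(dev):
        if dev in (None, "laboratory"):
            return False
        return not (isinstance(dev, float) and np.isnan(dev))

    # raw (pre-adjustment) total/HDL restricted means: the non-HDL
    # conversion was trained on device-restricted companion predictors
    companions = {}
    for _, row in out.iterrows():
        if row["metric"] in ("total", "hdl"):
            companions[
                (row["study_id"], row["sex"], row["age_band"], row["metric"])
            ] = row["mean"]
    for pass_metrics in (("total", "hdl"), ("non_hdl",)):
        for i, row in out.iterrows():
            if row["metric"] not in pass_metrics:
                continue
            dev = row.get("device_id")
            key = (row["metric"], dev)
            if not is_device(dev) or key not in models:
                continue
            stratum = dict(row)
            if row["metric"] == "non_hdl":
                k = (row["study_id"], row["sex"], row["age_band"])
                stratum["tc_mean"] = companions.get((*k, "total"), np.nan)
                stratum["hdl_mean"] = companions.get((*k, "hdl"), np.nan)
            draws = apply_conversion(
                stratum, models[key], n_draws=n_draws,
                seed=int(rng.integers(2**31 - 1)),
            )
            out.at[i, "mean"] = float(np.mean(draws))
            out.at[i, "se"] = float(np.std(draws, ddof=1))
            out.at[i, "provenance"] = "device-adjusted"
    return out
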