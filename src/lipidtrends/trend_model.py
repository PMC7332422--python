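"""Bayesian hierarchical model for country-year-sex-age mean cholesterol.

Observation unit: a study's sex x age-band stratum summary (mean, SE).
For one metric and one sex, the linear predictor is

    y_i = F(c_i, t_i) + A(c_i, a_i) + study terms_i + eps_i

with country-year level

    F(c, t) = a0 + a_sr + a_r + a_c                      (intercepts)
            + (b0 + b_sr + b_r + b_c) * tdec             (linear trends)
            + u_w(t) + u_sr(t) + u_r(t) + u_c(t)         (RW2 deviations)
            + g_urb * (urban share - 1/2)  [+ g_tc * TC covariate]

where tdec is the year centred and scaled to decades, and each RW2
deviation vector is parameterized as u = Z w with Z an orthonormal basis
of the subspace orthogonal to {1, t} — so sum-to-zero and detrending
constraints hold exactly in every draw and the linear slope stays
identified. The age curve A is a cubic B-spline over band midpoints with
a global coefficient vector plus hierarchically shrunk country
perturbations. Study terms are fixed effects for subnational and
community studies, fixed effects for rural-only (weight = country urban
proportion) and urban-only (weight = 1 - urban proportion) studies, and
one random intercept per subnational/community study. The observation
variance is SE_i^2 plus a study-type extra-variance component.

Inference is blocked Gibbs: all location parameters are updated jointly
from their exact multivariate-normal full conditional (sparse design
cross-product plus block prior precision, dense Cholesky); every standard
deviation (half-normal prior) is updated by univariate slice sampling on
the log scale. The estimand — the general national population mean —
excludes the study terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .bands import AGE_BAND_LABELS, AGE_BAND_MIDPOINTS, SEXES
from .synthetic_world import GeoHierarchy

logger = logging.getLogger(__name__)


@dataclass
class PriorSpec:
    """Half-normal scales for standard deviations; normal SD for fixed effects.

    All units are mmol/l (slopes: mmol/l per decade). These are weakly
    informative relative to observed between-country lipid variation.
    """

    fixed_sd: float = 10.0
    intercept_scale: tuple = (0.5, 0.5, 0.5)  # super-region, region, country
    slope_scale: tuple = (0.2, 0.2, 0.2)
    rw2_scale: tuple = (0.03, 0.03, 0.03, 0.03)  # world, sr, region, country
    age_perturb_scale: float = 0.2
    study_re_scale: tuple = (0.3, 0.3)  # subnational, community
    extra_sd_scale: tuple = (0.3, 0.3)  # subnational, community


@dataclass
class MCMCSettings:
    n_burn: int = 2000
    n_draws: int = 5000  # post-burn-in draws retained
    rhat_threshold: float = 1.05


@dataclass
class ModelSpec:
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    age_interior_knots: tuple = (35.0, 45.0, 55.0, 65.0)
    age_boundary: tuple = (18.5, 85.0)


def age_spline_basis(spec: ModelSpec) -> np.ndarray:
    """Cubic B-spline design over band midpoints, first column dropped and
    columns centred (the global intercept carries the level)."""
    lo, hi = spec.age_boundary
    t = np.r_[[lo] * 4, list(spec.age_interior_knots), [hi] * 4]
    n_basis = len(t) - 4
    B = BSpline.design_matrix(
        np.clip(AGE_BAND_MIDPOINTS, lo, hi), t, 3, extrapolate=False
    ).toarray()
    assert B.shape == (len(AGE_BAND_MIDPOINTS), n_basis)
    B = B[:, 1:]
    return B - B.mean(axis=0, keepdims=True)


def _constraint_basis(n: int) -> np.ndarray:
    """Orthonormal basis of the complement of span{1, t} in R^n."""
    from scipy.linalg import null_space

    t = np.arange(n, dtype=float)
    A = np.vstack([np.ones(n), t - t.mean()])
    Z = null_space(A)
    assert Z.shape == (n, n - 2)
    return Z


def _rw2_penalty(n: int, Z: np.ndarray) -> np.ndarray:
    D = np.diff(np.eye(n), n=2, axis=0)
    K = Z.T @ D.T @ D @ Z
    return (K + K.T) / 2.0


@dataclass
class AssembledModel:
    """Design, priors and index maps, ready for the sampler."""

    X: sp.csr_matrix
    y: np.ndarray
    se2: np.ndarray
    obs_type: np.ndarray  # 0 national, 1 subnational, 2 community
    blocks: dict  # name -> (start, stop) slice into the parameter vector
    n_params: int
    spec: ModelSpec
    metric: str
    sex: str
    countries: list
    years: np.ndarray
    sr_ids: list
    region_ids: list
    sr_of_country: np.ndarray  # index into sr_ids per country
    region_of_country: np.ndarray
    tdec: np.ndarray
    Z: np.ndarray | None
    K: np.ndarray | None
    B_age: np.ndarray
    urb_centered: np.ndarray  # (n_c, n_t)
    tc_cov: np.ndarray | None
    re_study_type: np.ndarray  # per RE column: 1 sub / 2 com
    study_ids_re: list
    has_tc_cov: bool


def build_design(
    strata: pd.DataFrame,
    hierarchy: GeoHierarchy,
    spec: ModelSpec,
    metric: str,
    sex: str,
    tc_covariate: np.ndarray | None = None,
) -> AssembledModel:
    """Assemble the sparse observation design and parameter blocks.

    ``strata`` must carry columns study_id, country, year, sex, age_band,
    metric, mean, se, coverage, urbanicity. ``tc_covariate`` (countries x
    years, same order as the hierarchy) is required for the non-HDL and
    HDL models and forbidden for the total-cholesterol model.
    """
    df = strata[(strata["metric"] == metric) & (strata["sex"] == sex)].copy()
    df = df[np.isfinite(df["se"]) & (df["se"] > 0)]
    if len(df) == 0:
        raise ValueError(f"no usable strata for metric={metric}, sex={sex}")
    for c in df["country"].unique():
        if c not in hierarchy.region_of:
            raise ValueError(f"country {c!r} not in hierarchy")
    years = hierarchy.years
    if (df["year"] < years[0]).any() or (df["year"] > years[-1]).any():
        bad = df.loc[(df["year"] < years[0]) | (df["year"] > years[-1]), "year"]
        raise ValueError(f"years outside model range: {sorted(bad.unique())}")
    if metric in ("hdl", "non_hdl") and tc_covariate is None:
        logger.warning("%s model fitted without total-cholesterol covariate", metric)

    countries = list(hierarchy.country_ids)
    region_ids = hierarchy.region_ids
    sr_ids = hierarchy.super_region_ids
    n_c, n_r, n_sr, n_t = len(countries), len(region_ids), len(sr_ids), len(years)
    c_idx = {c: i for i, c in enumerate(countries)}
    r_idx = {r: i for i, r in enumerate(region_ids)}
    s_idx = {s: i for i, s in enumerate(sr_ids)}
    region_of_country = np.array([r_idx[hierarchy.region_of[c]] for c in countries])
    sr_of_country = np.array(
        [s_idx[hierarchy.super_region_of(c)] for c in countries]
    )

    tdec = (years - years.mean()) / 10.0
    use_rw2 = n_t >= 5
    Z = _constraint_basis(n_t) if use_rw2 else None
    K = _rw2_penalty(n_t, Z) if use_rw2 else None
    k_rw = n_t - 2 if use_rw2 else 0
    B_age = age_spline_basis(spec)
    k_age = B_age.shape[1]

    has_tc = tc_covariate is not None
    if has_tc:
        tc_cov = np.asarray(tc_covariate, dtype=float)
        if tc_cov.shape != (n_c, n_t):
            raise ValueError("tc_covariate must be (n_countries, n_years)")
        if not np.all(np.isfinite(tc_cov)):
            raise ValueError("tc_covariate has non-finite cells")
        tc_cov = tc_cov - tc_cov.mean()
    else:
        tc_cov = None
    urb_centered = hierarchy.urbanization - 0.5

    # random-effect columns: one per subnational/community study present
    type_of = {"national": 0, "subnational": 1, "community": 2}
    df["_type"] = df["coverage"].map(type_of)
    re_studies = sorted(df.loc[df["_type"] > 0, "study_id"].unique())
    re_col = {s: j for j, s in enumerate(re_studies)}
    re_study_type = np.array(
        [int(df.loc[df["study_id"] == s, "_type"].iloc[0]) for s in re_studies]
    )

    # --- parameter layout -------------------------------------------------
    blocks = {}
    pos = 0

    def add(name, k):
        nonlocal pos
        blocks[name] = (pos, pos + k)
        pos += k

    # fixed block: a0, b0, g_urb, [g_tc], fe_sub, fe_com, fe_rural, fe_urban
    n_fixed = 7 + (1 if has_tc else 0)
    add("fixed", n_fixed)
    add("int_sr", n_sr)
    add("int_r", n_r)
    add("int_c", n_c)
    add("slope_sr", n_sr)
    add("slope_r", n_r)
    add("slope_c", n_c)
    if use_rw2:
        add("rw2_world", k_rw)
        add("rw2_sr", n_sr * k_rw)
        add("rw2_r", n_r * k_rw)
        add("rw2_c", n_c * k_rw)
    add("age_global", k_age)
    add("age_c", n_c * k_age)
    add("re_study", len(re_studies))
    n_params = pos

    fx = blocks["fixed"][0]
    i_a0, i_b0, i_urb = fx, fx + 1, fx + 2
    i_tc = fx + 3 if has_tc else None
    off = 4 if has_tc else 3
    i_fsub, i_fcom, i_frur, i_furb = fx + off, fx + off + 1, fx + off + 2, fx + off + 3

    # --- observation rows -------------------------------------------------
    rows, cols, vals = [], [], []
    y = df["mean"].to_numpy(dtype=float)
    # floor the SE: a numerically zero SE would give one observation
    # unbounded weight and break the precision Cholesky
    se2 = np.maximum(df["se"].to_numpy(dtype=float), 1e-3) ** 2
    obs_type = df["_type"].to_numpy(dtype=int)
    band_idx = df["age_band"].map({b: i for i, b in enumerate(AGE_BAND_LABELS)}).to_numpy()
    ci_arr = df["country"].map(c_idx).to_numpy()
    ti_arr = (df["year"].to_numpy(dtype=int) - years[0]).astype(int)

    def put(i, j, v):
        if v != 0.0:
            rows.append(i)
            cols.append(j)
            vals.append(float(v))

    for i in range(len(df)):
        ci, ti, ai = int(ci_arr[i]), int(ti_arr[i]), int(band_idx[i])
        ri, si = int(region_of_country[ci]), int(sr_of_country[ci])
        td = tdec[ti]
        put(i, i_a0, 1.0)
        put(i, i_b0, td)
        put(i, blocks["int_sr"][0] + si, 1.0)
        put(i, blocks["int_r"][0] + ri, 1.0)
        put(i, blocks["int_c"][0] + ci, 1.0)
        put(i, blocks["slope_sr"][0] + si, td)
        put(i, blocks["slope_r"][0] + ri, td)
        put(i, blocks["slope_c"][0] + ci, td)
        if use_rw2:
            for j in range(k_rw):
                z = Z[ti, j]
                put(i, blocks["rw2_world"][0] + j, z)
                put(i, blocks["rw2_sr"][0] + si * k_rw + j, z)
                put(i, blocks["rw2_r"][0] + ri * k_rw + j, z)
                put(i, blocks["rw2_c"][0] + ci * k_rw + j, z)
        for j in range(k_age):
            b = B_age[ai, j]
            put(i, blocks["age_global"][0] + j, b)
            put(i, blocks["age_c"][0] + ci * k_age + j, b)
        put(i, i_urb, urb_centered[ci, ti])
        if has_tc:
            put(i, i_tc, tc_cov[ci, ti])
        row = df.iloc[i]
        if row["_type"] == 1:
            put(i, i_fsub, 1.0)
        elif row["_type"] == 2:
            put(i, i_fcom, 1.0)
        urbanicity = row.get("urbanicity", "mixed")
        if urbanicity == "rural":
            put(i, i_frur, hierarchy.urbanization[ci, ti])
        elif urbanicity == "urban":
            put(i, i_furb, 1.0 - hierarchy.urbanization[ci, ti])
        if row["_type"] > 0:
            put(i, blocks["re_study"][0] + re_col[row["study_id"]], 1.0)

    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(df), n_params), dtype=float
    )
    return AssembledModel(
        X=X,
        y=y,
        se2=se2,
        obs_type=obs_type,
        blocks=blocks,
        n_params=n_params,
        spec=spec,
        metric=metric,
        sex=sex,
        countries=countries,
        years=years,
        sr_ids=sr_ids,
        region_ids=region_ids,
        sr_of_country=sr_of_country,
        region_of_country=region_of_country,
        tdec=tdec,
        Z=Z,
        K=K,
        B_age=B_age,
        urb_centered=urb_centered,
        tc_cov=tc_cov,
        re_study_type=re_study_type,
        study_ids_re=re_studies,
        has_tc_cov=has_tc,
    )


# ---------------------------------------------------------------------------
# sampler


def _slice_sample(logpost, x0, rng, width=1.0, max_steps=30):
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    f0 = logpost(x0)
    if not np.isfinite(f0):
        raise RuntimeError("slice sampler started at zero-density point")
    y = f0 - rng.exponential()
    L = x0 - width * rng.random()
    R = L + width
    for _ in range(max_steps):
        if logpost(L) <= y:
            break
        L -= width
    for _ in range(max_steps):
        if logpost(R) <= y:
            break
        R += width
    for _ in range(200):
        x1 = rng.uniform(L, R)
        if logpost(x1) > y:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


def _sd_logpost_factory(Q, k, prior_scale):
    """log posterior of theta = log(sd) for a Gaussian group with
    sum-of-squares Q over k children and half-normal(prior_scale) prior,
    including the Jacobian of the log transform."""

    def logpost(theta):
        if theta < -20 or theta > 20:
            return -np.inf
        s2 = np.exp(2 * theta)
        return -k * theta - 0.5 * Q / s2 - 0.5 * s2 / prior_scale**2 + theta

    return logpost


@dataclass
class TrendFit:
    """Posterior draws and diagnostics for one (metric, sex) fit."""

    metric: str
    sex: str
    countries: list
    years: np.ndarray
    bands: tuple
    surface: np.ndarray  # (n_draws, n_c, n_t, n_bands), study terms excluded
    beta: np.ndarray  # (n_draws, n_params) float32
    sd_draws: dict  # name -> (n_draws,)
    blocks: dict
    diagnostics: dict
    flagged: bool
    model: AssembledModel

    @property
    def n_draws(self) -> int:
        return self.surface.shape[0]

    def country_slopes(self) -> pd.DataFrame:
        """Per-draw country linear slopes (mmol/l per decade), summarized."""
        am = self.model
        b = self.beta.astype(float)
        fx = am.blocks["fixed"][0]
        slopes = (
            b[:, fx + 1][:, None]
            + b[:, slice(*am.blocks["slope_sr"])][:, am.sr_of_country]
            + b[:, slice(*am.blocks["slope_r"])][:, am.region_of_country]
            + b[:, slice(*am.blocks["slope_c"])]
        )
        return pd.DataFrame(
            {
                "country": am.countries,
                "slope_mean": slopes.mean(axis=0),
                "slope_sd": slopes.std(axis=0),
            }
        )


def _surface_from_beta(am: AssembledModel, beta: np.ndarray) -> np.ndarray:
    """Evaluate the estimand surface (no study terms) for one draw."""
    n_c, n_t = len(am.countries), len(am.years)
    bl = am.blocks
    fx = bl["fixed"][0]
    has_tc = am.has_tc_cov
    a0, b0, g_urb = beta[fx], beta[fx + 1], beta[fx + 2]
    g_tc = beta[fx + 3] if has_tc else 0.0
    int_sr = beta[slice(*bl["int_sr"])]
    int_r = beta[slice(*bl["int_r"])]
    int_c = beta[slice(*bl["int_c"])]
    sl_sr = beta[slice(*bl["slope_sr"])]
    sl_r = beta[slice(*bl["slope_r"])]
    sl_c = beta[slice(*bl["slope_c"])]
    level = a0 + int_sr[am.sr_of_country] + int_r[am.region_of_country] + int_c
    slope = b0 + sl_sr[am.sr_of_country] + sl_r[am.region_of_country] + sl_c
    F = level[:, None] + np.outer(slope, am.tdec)
    if am.Z is not None:
        k_rw = am.Z.shape[1]
        u_w = am.Z @ beta[slice(*bl["rw2_world"])]
        W_sr = beta[slice(*bl["rw2_sr"])].reshape(-1, k_rw)
        W_r = beta[slice(*bl["rw2_r"])].reshape(-1, k_rw)
        W_c = beta[slice(*bl["rw2_c"])].reshape(-1, k_rw)
        U = (
            u_w[None, :]
            + (W_sr @ am.Z.T)[am.sr_of_country]
            + (W_r @ am.Z.T)[am.region_of_country]
            + W_c @ am.Z.T
        )
        F = F + U
    F = F + g_urb * am.urb_centered
    if has_tc:
        F = F + g_tc * am.tc_cov
    k_age = am.B_age.shape[1]
    alpha = beta[slice(*bl["age_global"])]
    alpha_c = beta[slice(*bl["age_c"])].reshape(n_c, k_age)
    A = (alpha[None, :] + alpha_c) @ am.B_age.T  # (n_c, n_bands)
    return F[:, :, None] + A[:, None, :]


_SD_NAMES = (
    "sd_int_sr", "sd_int_r", "sd_int_c",
    "sd_slope_sr", "sd_slope_r", "sd_slope_c",
    "sd_rw_world", "sd_rw_sr", "sd_rw_r", "sd_rw_c",
    "sd_age", "tau_sub", "tau_com", "nu_sub", "nu_com",
)


def fit_mcmc(
    am: AssembledModel,
    seed: int,
    n_burn: int | None = None,
    n_draws: int | None = None,
) -> TrendFit:
    """Blocked Gibbs sampler; returns exactly the configured post-burn draws.

    Raises RuntimeError (with the iteration index) if the sampler state
    goes non-finite; flags (but completes) a run whose split-chain
    convergence statistic exceeds the configured threshold.
    """
    spec = am.spec
    pr = spec.priors
    n_burn = spec.mcmc.n_burn if n_burn is None else n_burn
    n_draws = spec.mcmc.n_draws if n_draws is None else n_draws
    rng = np.random.default_rng([int(seed), 404])

    bl = am.blocks
    p = am.n_params
    X = am.X
    y = am.y
    rowmap = np.repeat(np.arange(X.shape[0]), np.diff(X.indptr))
    use_rw2 = am.Z is not None
    k_rw = am.Z.shape[1] if use_rw2 else 0
    k_age = am.B_age.shape[1]
    n_c = len(am.countries)

    # current variance state (standard deviations)
    sd = {
        "sd_int_sr": pr.intercept_scale[0] / 2,
        "sd_int_r": pr.intercept_scale[1] / 2,
        "sd_int_c": pr.intercept_scale[2] / 2,
        "sd_slope_sr": pr.slope_scale[0] / 2,
        "sd_slope_r": pr.slope_scale[1] / 2,
        "sd_slope_c": pr.slope_scale[2] / 2,
        "sd_rw_world": pr.rw2_scale[0] / 2,
        "sd_rw_sr": pr.rw2_scale[1] / 2,
        "sd_rw_r": pr.rw2_scale[2] / 2,
        "sd_rw_c": pr.rw2_scale[3] / 2,
        "sd_age": pr.age_perturb_scale / 2,
        "tau_sub": pr.study_re_scale[0] / 2,
        "tau_com": pr.study_re_scale[1] / 2,
        "nu_sub": pr.extra_sd_scale[0] / 2,
        "nu_com": pr.extra_sd_scale[1] / 2,
    }
    prior_scale = {
        "sd_int_sr": pr.intercept_scale[0],
        "sd_int_r": pr.intercept_scale[1],
        "sd_int_c": pr.intercept_scale[2],
        "sd_slope_sr": pr.slope_scale[0],
        "sd_slope_r": pr.slope_scale[1],
        "sd_slope_c": pr.slope_scale[2],
        "sd_rw_world": pr.rw2_scale[0],
        "sd_rw_sr": pr.rw2_scale[1],
        "sd_rw_r": pr.rw2_scale[2],
        "sd_rw_c": pr.rw2_scale[3],
        "sd_age": pr.age_perturb_scale,
        "tau_sub": pr.study_re_scale[0],
        "tau_com": pr.study_re_scale[1],
        "nu_sub": pr.extra_sd_scale[0],
        "nu_com": pr.extra_sd_scale[1],
    }

    fixed_prec = 1.0 / pr.fixed_sd**2
    sub_obs = am.obs_type == 1
    com_obs = am.obs_type == 2
    re_sub = am.re_study_type == 1
    re_com = am.re_study_type == 2

    def prior_matrix():
        """Block prior precision: diagonal part and RW2 dense blocks."""
        d = np.zeros(p)
        d[slice(*bl["fixed"])] = fixed_prec
        d[slice(*bl["int_sr"])] = 1 / sd["sd_int_sr"] ** 2
        d[slice(*bl["int_r"])] = 1 / sd["sd_int_r"] ** 2
        d[slice(*bl["int_c"])] = 1 / sd["sd_int_c"] ** 2
        d[slice(*bl["slope_sr"])] = 1 / sd["sd_slope_sr"] ** 2
        d[slice(*bl["slope_r"])] = 1 / sd["sd_slope_r"] ** 2
        d[slice(*bl["slope_c"])] = 1 / sd["sd_slope_c"] ** 2
        d[slice(*bl["age_global"])] = fixed_prec
        d[slice(*bl["age_c"])] = 1 / sd["sd_age"] ** 2
        if bl["re_study"][1] > bl["re_study"][0]:
            re_prec = np.where(
                re_sub, 1 / sd["tau_sub"] ** 2, 1 / sd["tau_com"] ** 2
            )
            d[slice(*bl["re_study"])] = re_prec
        return d

    def obs_weights():
        extra = np.zeros(len(y))
        extra[sub_obs] = sd["nu_sub"] ** 2
        extra[com_obs] = sd["nu_com"] ** 2
        return 1.0 / (am.se2 + extra)

    beta = np.zeros(p)
    beta[bl["fixed"][0]] = float(np.average(y, weights=1 / am.se2))

    surface = np.empty(
        (n_draws, n_c, len(am.years), len(AGE_BAND_LABELS)), dtype=np.float32
    )
    beta_store = np.empty((n_draws, p), dtype=np.float32)
    sd_store = {k: np.empty(n_draws) for k in _SD_NAMES}

    total_iter = n_burn + n_draws
    for it in range(total_iter):
        w = obs_weights()
        Xw = X.copy()
        Xw.data = X.data * w[rowmap]
        M = (Xw.T @ X).toarray()
        M[np.diag_indices(p)] += prior_matrix()
        if use_rw2:
            for name, prec in (
                ("rw2_world", 1 / sd["sd_rw_world"] ** 2),
                ("rw2_sr", 1 / sd["sd_rw_sr"] ** 2),
                ("rw2_r", 1 / sd["sd_rw_r"] ** 2),
                ("rw2_c", 1 / sd["sd_rw_c"] ** 2),
            ):
                start, stop = bl[name]
                for u0 in range(start, stop, k_rw):
                    M[u0 : u0 + k_rw, u0 : u0 + k_rw] += prec * am.K
        b = X.T @ (w * y)
        try:
            cf = cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError as e:
            raise RuntimeError(f"Cholesky failure at iteration {it}: {e}") from e
        mean = cho_solve(cf, b, check_finite=False)
        z = rng.standard_normal(p)
        beta = mean + solve_triangular(
            cf[0].T, z, lower=False, check_finite=False
        )
        if not np.all(np.isfinite(beta)):
            raise RuntimeError(f"non-finite sampler state at iteration {it}")

        # --- variance components ---------------------------------------
        def ss(name):
            v = beta[slice(*bl[name])]
            return float(v @ v), len(v)

        updates = [
            ("sd_int_sr", *ss("int_sr")),
            ("sd_int_r", *ss("int_r")),
            ("sd_int_c", *ss("int_c")),
            ("sd_slope_sr", *ss("slope_sr")),
            ("sd_slope_r", *ss("slope_r")),
            ("sd_slope_c", *ss("slope_c")),
            ("sd_age", *ss("age_c")),
        ]
        if use_rw2:
            for name, key in (
                ("rw2_world", "sd_rw_world"),
                ("rw2_sr", "sd_rw_sr"),
                ("rw2_r", "sd_rw_r"),
                ("rw2_c", "sd_rw_c"),
            ):
                W = beta[slice(*bl[name])].reshape(-1, k_rw)
                Q = float(np.einsum("ij,jk,ik->", W, am.K, W))
                updates.append((key, Q, W.size))
        re = beta[slice(*bl["re_study"])]
        if re_sub.any():
            updates.append(("tau_sub", float(re[re_sub] @ re[re_sub]), int(re_sub.sum())))
        if re_com.any():
            updates.append(("tau_com", float(re[re_com] @ re[re_com]), int(re_com.sum())))
        for key, Q, k in updates:
            lp = _sd_logpost_factory(Q, k, prior_scale[key])
            sd[key] = float(np.exp(_slice_sample(lp, np.log(sd[key]), rng)))

        resid = y - X @ beta
        for key, mask in (("nu_sub", sub_obs), ("nu_com", com_obs)):
            if not mask.any():
                continue
            r2 = resid[mask] ** 2
            s2obs = am.se2[mask]
            scale = prior_scale[key]

            def lp_nu(theta, r2=r2, s2obs=s2obs, scale=scale):
                if theta < -20 or theta > 6:
                    return -np.inf
                nu2 = np.exp(2 * theta)
                tot = s2obs + nu2
                return (
                    -0.5 * float(np.sum(np.log(tot)) + np.sum(r2 / tot))
                    - 0.5 * nu2 / scale**2
                    + theta
                )

            sd[key] = float(np.exp(_slice_sample(lp_nu, np.log(sd[key]), rng)))

        if it >= n_burn:
            j = it - n_burn
            surface[j] = _surface_from_beta(am, beta)
            beta_store[j] = beta
            for k in _SD_NAMES:
                sd_store[k][j] = sd[k]

    diagnostics, flagged = _diagnostics(am, beta_store, sd_store, spec)
    return TrendFit(
        metric=am.metric,
        sex=am.sex,
        countries=am.countries,
        years=am.years,
        bands=AGE_BAND_LABELS,
        surface=surface,
        beta=beta_store,
        sd_draws=sd_store,
        blocks=bl,
        diagnostics=diagnostics,
        flagged=flagged,
        model=am,
    )


def _diagnostics(am, beta_store, sd_store, spec):
    """Split-chain R-hat and ESS for top-level parameters via arviz."""
    import arviz as az

    n = beta_store.shape[0]
    half = n // 2
    fx = am.blocks["fixed"][0]
    names = {"a0": fx, "b0": fx + 1, "g_urb": fx + 2}
    series = {k: beta_store[: 2 * half, i].astype(float) for k, i in names.items()}
    for k in ("sd_int_c", "sd_rw_c", "tau_sub", "nu_sub"):
        series[k] = sd_store[k][: 2 * half]
    rhat, ess = {}, {}
    for k, v in series.items():
        chains = v.reshape(2, half)
        data = az.convert_to_dataset(chains[:, :, None].squeeze(-1))
        rhat[k] = float(az.rhat(data)["x"].values)
        ess[k] = float(az.ess(data)["x"].values)
    worst = max(rhat.values())
    flagged = bool(worst > spec.mcmc.rhat_threshold)
    if flagged:
        logger.warning("convergence flag: max split R-hat %.3f", worst)
    return {"rhat": rhat, "ess": ess, "max_rhat": worst}, flagged


def predict_surface(fit: TrendFit, country: str, year: int, age_band: str) -> np.ndarray:
    """Per-draw general-population mean at one (country, year, band)."""
    ci = fit.countries.index(country)
    ti = int(np.searchsorted(fit.years, year))
    if ti >= len(fit.years) or fit.years[ti] != year:
        raise IndexError(f"year {year} outside fitted range")
    ai = AGE_BAND_LABELS.index(age_band)
    return fit.surface[:, ci, ti, ai].astype(float)


def predictive_observation_draws(
    fit: TrendFit,
    country: str,
    year: int,
    age_band: str,
    coverage: str = "national",
    urbanicity: str = "mixed",
    se: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior-predictive draws for a hypothetical observed stratum.

    Unlike :func:`predict_surface` (the general-population estimand),
    this includes the study-type fixed effects, the study random-effect
    and extra-variance components for the given coverage level, and the
    stratum's own sampling noise — the right reference distribution when
    comparing held-out stratum summaries with model estimates.
    """
    rng = rng or np.random.default_rng(0)
    draws = predict_surface(fit, country, year, age_band).copy()
    am = fit.model
    fx = am.blocks["fixed"][0]
    off = fx + (4 if am.has_tc_cov else 3)
    beta = fit.beta.astype(float)
    n = len(draws)
    tau = np.zeros(n)
    nu = np.zeros(n)
    if coverage == "subnational":
        draws += beta[:, off]
        tau, nu = fit.sd_draws["tau_sub"], fit.sd_draws["nu_sub"]
    elif coverage == "community":
        draws += beta[:, off + 1]
        tau, nu = fit.sd_draws["tau_com"], fit.sd_draws["nu_com"]
    ci = fit.countries.index(country)
    ti = int(np.searchsorted(fit.years, year))
    urb = am.urb_centered[ci, ti] + 0.5
    if urbanicity == "rural":
        draws += beta[:, off + 2] * urb
    elif urbanicity == "urban":
        draws += beta[:, off + 3] * (1.0 - urb)
    noise_sd = np.sqrt(se**2 + nu**2)
    return draws + rng.standard_normal(n) * noise_sd + rng.standard_normal(n) * tau


def fit_metric(
    strata: pd.DataFrame,
    hierarchy: GeoHierarchy,
    metric: str,
    sex: str,
    spec: ModelSpec | None = None,
    seed: int = 0,
    tc_covariate: np.ndarray | None = None,
    n_burn: int | None = None,
    n_draws: int | None = None,
) -> TrendFit:
    """Convenience wrapper: assemble and sample one (metric, sex) model."""
    spec = spec or ModelSpec()
    am = build_design(strata, hierarchy, spec, metric, sex, tc_covariate)
    return fit_mcmc(am, seed=seed, n_burn=n_burn, n_draws=n_draws)


def fit_sequence(
    strata: pd.DataFrame,
    hierarchy: GeoHierarchy,
    spec: ModelSpec | None = None,
    seed: int = 0,
    sexes: tuple = SEXES,
    metrics: tuple = ("total", "non_hdl", "hdl"),
    n_burn: int | None = None,
    n_draws: int | None = None,
) -> dict:
    """Sequential covariate pipeline: total cholesterol first, then the
    lipid-fraction models with the age-standardized posterior-mean total
    cholesterol per country-year as covariate."""
    from .postprocess import standard_weights

    spec = spec or ModelSpec()
    wts = standard_weights()
    fits = {}
    for si, sex in enumerate(sexes):
        tc_fit = None
        if "total" in metrics:
            tc_fit = fit_metric(
                strata, hierarchy, "total", sex, spec,
                seed=seed * 4 + si, n_burn=n_burn, n_draws=n_draws,
            )
            fits[("total", sex)] = tc_fit
        tc_cov = None
        if tc_fit is not None:
            tc_cov = np.einsum("dcta,a->ct", tc_fit.surface.astype(float), wts)
            tc_cov /= tc_fit.surface.shape[0]
        for metric in metrics:
            if metric == "total":
                continue
            fits[(metric, sex)] = fit_metric(
                strata, hierarchy, metric, sex, spec,
                seed=seed * 4 + si + 1000, tc_covariate=tc_cov,
                n_burn=n_burn, n_draws=n_draws,
            )
    return fits
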