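"""Synthetic survey world with known ground truth.

Generates a geographic hierarchy (countries nested in regions nested in
super-regions), smooth true cholesterol surfaces by country, year, sex and
age band, a portfolio of survey studies of mixed coverage (national /
subnational / community) and urbanicity (rural / urban / mixed), and
individual measurement records drawn around the truth — including
injected implausible values and portable-device assignment — so that the
cleaning, adjustment, modelling, post-processing, validation and burden
stages can all be exercised against stored ground truth.

True time trends are a linear term plus a second-order random walk
(cumulatively-summed-twice i.i.d. innovations, then centred and detrended
so the linear slope stays identified). Age patterns are cubic polynomials
per sex with small country-level coefficient perturbations, which keeps
them inside the cubic-spline family fitted by the trend model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import AGE_BANDS, AGE_BAND_LABELS, AGE_BAND_MIDPOINTS, PLAUSIBLE_RANGE, SEXES

COVERAGE_LEVELS = ("national", "subnational", "community")
URBANICITY_LEVELS = ("rural", "urban", "mixed")
SAMPLING_FRAMES = ("probabilistic", "school", "insurance", "primary-care")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SurfaceParams:
    """True-surface components for one metric (mmol/l).

    Age enters through a cubic polynomial in z = (age - 50) / 35 with
    sex-specific coefficients; country perturbations are i.i.d. normal on
    the three polynomial coefficients.
    """

    intercept: dict = field(default_factory=dict)  # sex -> level at age 50
    slope_per_decade: dict = field(default_factory=dict)  # sex -> mmol/l per decade
    sd_intercept: tuple = (0.25, 0.20, 0.30)  # (super-region, region, country)
    sd_slope_per_decade: tuple = (0.04, 0.04, 0.07)
    rw2_innovation_sd: tuple = (0.002, 0.002, 0.003, 0.004)  # (world, sr, r, c)
    age_coef: dict = field(default_factory=dict)  # sex -> (c1, c2, c3)
    sd_age_perturb: float = 0.04
    urban_effect: float = 0.0  # per unit urban proportion, centred at 0.5


def _default_total() -> SurfaceParams:
    return SurfaceParams(
        intercept={"female": 4.8, "male": 4.7},
        slope_per_decade={"female": -0.03, "male": -0.05},
        age_coef={
            "female": (0.55, -0.25, -0.20),
            "male": (0.45, -0.35, -0.15),
        },
        urban_effect=0.20,
    )


def _default_hdl() -> SurfaceParams:
    return SurfaceParams(
        intercept={"female": 1.35, "male": 1.15},
        slope_per_decade={"female": 0.00, "male": -0.02},
        sd_intercept=(0.08, 0.06, 0.10),
        sd_slope_per_decade=(0.01, 0.01, 0.02),
        rw2_innovation_sd=(0.0006, 0.0006, 0.0009, 0.0012),
        age_coef={"female": (0.06, 0.02, 0.0), "male": (0.04, 0.02, 0.0)},
        sd_age_perturb=0.015,
        urban_effect=0.02,
    )


@dataclass
class StudyConfig:
    """How the study portfolio is composed.

    Coverage mixture defaults to the observed composition of large
    multi-source lipid databases (36.3% national, 22.2% subnational,
    41.5% community); 10% of studies use a portable device.
    """

    mean_studies_per_country: float = 4.0
    studies_per_country: dict | None = None  # country id -> count, overrides Poisson
    coverage_probs: tuple = (0.363, 0.222, 0.415)
    # urbanicity of subnational/community studies; national studies are mixed
    urbanicity_probs: tuple = (0.3, 0.3, 0.4)  # rural, urban, mixed
    frame_probs: tuple = (0.90, 0.03, 0.03, 0.04)
    device_prob: float = 0.10
    device_ids: tuple = ("pd-narrow", "pd-wide")
    # study-level offsets (bias, mmol/l on total cholesterol scale)
    offset_mean: dict = field(
        default_factory=lambda: {"national": 0.0, "subnational": 0.05, "community": 0.10}
    )
    offset_sd: dict = field(
        default_factory=lambda: {"national": 0.0, "subnational": 0.10, "community": 0.15}
    )
    hdl_offset_scale: float = 0.3  # HDL offsets are this fraction of total offsets
    extra_sd: dict = field(
        default_factory=lambda: {"national": 0.0, "subnational": 0.05, "community": 0.08}
    )
    stratum_n_log_mean: float = np.log(100.0)
    stratum_n_log_sd: float = 0.5
    hdl_measured_prob: float = 0.85
    ldl_measured_prob: float = 0.14


@dataclass
class RecordConfig:
    """Individual-level generation around the stratum-true means."""

    within_sd: dict = field(default_factory=lambda: {"total": 1.0, "hdl": 0.30})
    #: individual-level correlation between total and HDL cholesterol; the
    #: source literature does not pin this down, so it is a free parameter.
    tc_hdl_corr: float = 0.2
    injection_rate: float = 0.005
    pregnancy_rate: float = 0.02  # among women aged 18-49
    under18_rate: float = 0.01  # extra minors per adult record
    weight_log_sd: float = 0.3
    vldl_mean: float = 0.7  # LDL = total - HDL - VLDL-like remainder
    vldl_sd: float = 0.15


@dataclass
class WorldConfig:
    n_super_regions: int = 2
    n_regions: int = 4
    n_countries: int = 12
    year_start: int = 1980
    year_end: int = 2018
    total: SurfaceParams = field(default_factory=_default_total)
    hdl: SurfaceParams = field(default_factory=_default_hdl)
    studies: StudyConfig = field(default_factory=StudyConfig)
    records: RecordConfig = field(default_factory=RecordConfig)
    max_clip_fraction: float = 0.01

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# domain objects


@dataclass
class GeoHierarchy:
    """Countries nested in regions nested in super-regions.

    population has shape (n_countries, n_years, n_sexes, n_bands) and
    urbanization (n_countries, n_years), with rows aligned to
    ``country_ids`` and columns to ``years``.
    """

    country_ids: list
    region_of: dict  # country id -> region id
    super_region_of_region: dict  # region id -> super-region id
    years: np.ndarray
    population: np.ndarray
    urbanization: np.ndarray

    @property
    def region_ids(self) -> list:
        return sorted(set(self.region_of.values()))

    @property
    def super_region_ids(self) -> list:
        return sorted(set(self.super_region_of_region.values()))

    def super_region_of(self, country: str) -> str:
        return self.super_region_of_region[self.region_of[country]]

    def countries_in_region(self, region: str) -> list:
        return [c for c in self.country_ids if self.region_of[c] == region]

    def validate(self) -> None:
        if not np.all(self.population > 0):
            raise ValueError("populations must be strictly positive")
        if np.any(self.urbanization < 0) or np.any(self.urbanization > 1):
            raise ValueError("urbanization must lie in [0, 1]")
        for c in self.country_ids:
            if c not in self.region_of:
                raise ValueError(f"country {c} has no region")
            if self.region_of[c] not in self.super_region_of_region:
                raise ValueError(f"region {self.region_of[c]} has no super-region")

    def year_index(self, year) -> np.ndarray:
        return np.searchsorted(self.years, year)

    def country_index(self, country) -> int:
        return self.country_ids.index(country)


@dataclass
class TrueSurface:
    """True mean cholesterol, (n_countries, n_years, n_sexes, n_bands)."""

    metric: str
    values: np.ndarray
    decomposition: dict = field(default_factory=dict)

    def at(self, hierarchy: GeoHierarchy, country, year, sex, band_label) -> float:
        ci = hierarchy.country_index(country)
        ti = int(hierarchy.year_index(year))
        si = SEXES.index(sex)
        ai = AGE_BAND_LABELS.index(band_label)
        return float(self.values[ci, ti, si, ai])


@dataclass
class StudySource:
    study_id: str
    country: str
    year: int
    coverage: str
    urbanicity: str
    frame: str
    device_id: str | None  # None means laboratory measurement
    stratum_n: dict  # (sex, band label) -> target count
    offsets: dict  # metric -> true study-level bias (mmol/l)
    extra_sd: float
    hdl_measured: bool = True
    ldl_measured: bool = False


# ---------------------------------------------------------------------------
# generation


def _rw2_deviation(rng, n: int, innovation_sd: float) -> np.ndarray:
    """Doubly-cumulated innovations, centred and detrended.

    The residual after projecting out {1, t} has zero mean, zero linear
    trend and finite second differences; with innovation_sd = 0 it is
    identically zero, forcing an exactly linear trend.
    """
    if n < 3 or innovation_sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, innovation_sd, size=n)
    x = np.cumsum(np.cumsum(innov))
    t = np.arange(n, dtype=float)
    basis = np.column_stack([np.ones(n), t - t.mean()])
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ coef


def _age_curve(coef, z: np.ndarray) -> np.ndarray:
    c1, c2, c3 = coef
    return c1 * z + c2 * z**2 + c3 * z**3


def generate_world(config: WorldConfig, seed: int):
    """Build the hierarchy and true total/HDL/non-HDL surfaces.

    Deterministic in (config, seed). Raises ValueError if the configured
    variance components push more than ``max_clip_fraction`` of surface
    cells outside the plausibility windows.
    """
    rng = np.random.default_rng([int(seed), 101])
    n_c, n_r, n_sr = config.n_countries, config.n_regions, config.n_super_regions
    if not (1 <= n_sr <= n_r <= n_c):
        raise ValueError("need n_super_regions <= n_regions <= n_countries")
    years = config.years
    n_t = len(years)

    country_ids = [f"C{i:03d}" for i in range(n_c)]
    region_ids = [f"R{i:02d}" for i in range(n_r)]
    sr_ids = [f"SR{i}" for i in range(n_sr)]
    region_of = {c: region_ids[i % n_r] for i, c in enumerate(country_ids)}
    sr_of_region = {r: sr_ids[i % n_sr] for i, r in enumerate(region_ids)}

    # urbanization: rising logistic curves, one per country
    a = rng.normal(0.0, 0.8, size=n_c)
    b = rng.normal(1.2, 0.4, size=n_c)
    tt = (years - years.mean()) / (n_t / 2.0)
    urb = 1.0 / (1.0 + np.exp(-(a[:, None] + b[:, None] * tt[None, :])))

    # population: lognormal country sizes, mild growth, fixed age structure
    base = rng.lognormal(np.log(2e6), 1.0, size=n_c)
    growth = (1.015) ** (years - years[0])
    age_struct = np.array([0.05, 0.22, 0.20, 0.17, 0.14, 0.11, 0.07, 0.04])
    age_struct = age_struct / age_struct.sum()
    pop = (
        base[:, None, None, None]
        * growth[None, :, None, None]
        * np.array([0.5, 0.5])[None, None, :, None]
        * age_struct[None, None, None, :]
    )

    hierarchy = GeoHierarchy(
        country_ids=country_ids,
        region_of=region_of,
        super_region_of_region=sr_of_region,
        years=years,
        population=pop,
        urbanization=urb,
    )
    hierarchy.validate()

    surfaces = {}
    for metric, params in (("total", config.total), ("hdl", config.hdl)):
        surfaces[metric] = _generate_surface(rng, hierarchy, config, metric, params)

    non_hdl = TrueSurface(
        metric="non_hdl",
        values=surfaces["total"].values - surfaces["hdl"].values,
        decomposition={"derived": "total - hdl"},
    )
    surfaces["non_hdl"] = non_hdl
    return hierarchy, surfaces


def _generate_surface(rng, hierarchy, config, metric, params: SurfaceParams):
    country_ids = hierarchy.country_ids
    region_ids = hierarchy.region_ids
    sr_ids = hierarchy.super_region_ids
    years = hierarchy.years
    n_c, n_t = len(country_ids), len(years)
    tdec = (years - years.mean()) / 10.0

    off_sr = {u: rng.normal(0, params.sd_intercept[0]) for u in sr_ids}
    off_r = {u: rng.normal(0, params.sd_intercept[1]) for u in region_ids}
    off_c = {u: rng.normal(0, params.sd_intercept[2]) for u in country_ids}
    sl_sr = {u: rng.normal(0, params.sd_slope_per_decade[0]) for u in sr_ids}
    sl_r = {u: rng.normal(0, params.sd_slope_per_decade[1]) for u in region_ids}
    sl_c = {u: rng.normal(0, params.sd_slope_per_decade[2]) for u in country_ids}

    rw_world = _rw2_deviation(rng, n_t, params.rw2_innovation_sd[0])
    rw_sr = {u: _rw2_deviation(rng, n_t, params.rw2_innovation_sd[1]) for u in sr_ids}
    rw_r = {u: _rw2_deviation(rng, n_t, params.rw2_innovation_sd[2]) for u in region_ids}
    rw_c = {u: _rw2_deviation(rng, n_t, params.rw2_innovation_sd[3]) for u in country_ids}

    z = (AGE_BAND_MIDPOINTS - 50.0) / 35.0
    zbasis = np.column_stack([z, z**2, z**3])
    age_perturb = {
        u: rng.normal(0.0, params.sd_age_perturb, size=3) for u in country_ids
    }

    values = np.empty((n_c, n_t, len(SEXES), len(AGE_BANDS)))
    slope_by_country = {}
    for ci, c in enumerate(country_ids):
        r = hierarchy.region_of[c]
        sr = hierarchy.super_region_of_region[r]
        time_common = rw_world + rw_sr[sr] + rw_r[r] + rw_c[c]
        urb_term = params.urban_effect * (hierarchy.urbanization[ci] - 0.5)
        for si, sex in enumerate(SEXES):
            slope = (
                params.slope_per_decade[sex] + sl_sr[sr] + sl_r[r] + sl_c[c]
            )
            level = params.intercept[sex] + off_sr[sr] + off_r[r] + off_c[c]
            age_eff = _age_curve(params.age_coef[sex], z) + zbasis @ age_perturb[c]
            fy = level + slope * tdec + time_common + urb_term
            values[ci, :, si, :] = fy[:, None] + age_eff[None, :]
            slope_by_country[(c, sex)] = slope

    lo, hi = PLAUSIBLE_RANGE["total" if metric == "total" else "hdl"]
    n_out = np.sum((values < lo) | (values > hi))
    frac = n_out / values.size
    if frac > config.max_clip_fraction:
        raise ValueError(
            f"{metric}: {frac:.1%} of true surface cells fall outside the "
            f"plausibility window ({lo}, {hi}); reduce variance components"
        )
    values = np.clip(values, lo, hi)

    return TrueSurface(
        metric=metric,
        values=values,
        decomposition={
            "intercept": params.intercept,
            "offsets": {"super_region": off_sr, "region": off_r, "country": off_c},
            "slopes": {
                "global": params.slope_per_decade,
                "super_region": sl_sr,
                "region": sl_r,
                "country": sl_c,
                "by_country_sex": slope_by_country,
            },
            "rw2": {"world": rw_world, "super_region": rw_sr, "region": rw_r, "country": rw_c},
            "age_perturb": age_perturb,
        },
    )


def generate_studies(hierarchy: GeoHierarchy, config: StudyConfig, seed: int):
    """Draw the study portfolio: coverage, urbanicity, frame, device, bias."""
    rng = np.random.default_rng([int(seed), 202])
    p_cov = np.asarray(config.coverage_probs, dtype=float)
    if p_cov.min() < 0 or abs(p_cov.sum() - 1) > 1e-9:
        raise ValueError("coverage_probs must be a probability vector")
    studies = []
    k = 0
    for c in hierarchy.country_ids:
        if config.studies_per_country is not None:
            n_s = int(config.studies_per_country.get(c, 0))
        else:
            n_s = int(rng.poisson(config.mean_studies_per_country))
        for _ in range(n_s):
            coverage = COVERAGE_LEVELS[rng.choice(3, p=p_cov)]
            if coverage == "national":
                urbanicity = "mixed"
            else:
                urbanicity = URBANICITY_LEVELS[
                    rng.choice(3, p=np.asarray(config.urbanicity_probs))
                ]
            frame = SAMPLING_FRAMES[rng.choice(4, p=np.asarray(config.frame_probs))]
            device = None
            if rng.random() < config.device_prob:
                device = config.device_ids[rng.integers(len(config.device_ids))]
            year = int(rng.integers(hierarchy.years[0], hierarchy.years[-1] + 1))
            off_tc = rng.normal(
                config.offset_mean[coverage], config.offset_sd[coverage]
            )
            off_hdl = off_tc * config.hdl_offset_scale
            n_per = {}
            for sex in SEXES:
                for band in AGE_BAND_LABELS:
                    n_per[(sex, band)] = int(
                        np.round(
                            rng.lognormal(
                                config.stratum_n_log_mean, config.stratum_n_log_sd
                            )
                        )
                    )
            studies.append(
                StudySource(
                    study_id=f"S{k:04d}",
                    country=c,
                    year=year,
                    coverage=coverage,
                    urbanicity=urbanicity,
                    frame=frame,
                    device_id=device,
                    stratum_n=n_per,
                    offsets={"total": off_tc, "hdl": off_hdl},
                    extra_sd=config.extra_sd[coverage],
                    hdl_measured=bool(rng.random() < config.hdl_measured_prob),
                    ldl_measured=bool(rng.random() < config.ldl_measured_prob),
                )
            )
            k += 1
    return studies


def _band_age_range(band_idx: int) -> tuple[int, int]:
    lo, hi = AGE_BANDS[band_idx]
    return lo, 89 if hi is None else hi


def generate_records(
    hierarchy: GeoHierarchy,
    surfaces: dict,
    studies: list,
    config: RecordConfig,
    seed: int,
) -> pd.DataFrame:
    """Draw individual records around (true surface + study offset).

    Hidden ground-truth columns (prefixed ``_``) record injected-value
    flags and the effective true stratum means; they exist only for
    testing and are never read by the pipeline stages.
    """
    rng = np.random.default_rng([int(seed), 303])
    sd_t = config.within_sd["total"]
    sd_h = config.within_sd["hdl"]
    rho = config.tc_hdl_corr
    cov = np.array([[sd_t**2, rho * sd_t * sd_h], [rho * sd_t * sd_h, sd_h**2]])
    chol = np.linalg.cholesky(cov)

    rows = []
    for study in studies:
        ci = hierarchy.country_index(study.country)
        ti = int(hierarchy.year_index(study.year))
        for si, sex in enumerate(SEXES):
            for ai, band in enumerate(AGE_BAND_LABELS):
                n = study.stratum_n[(sex, band)]
                if n <= 0:
                    continue
                mu_t = surfaces["total"].values[ci, ti, si, ai] + study.offsets["total"]
                mu_h = surfaces["hdl"].values[ci, ti, si, ai] + study.offsets["hdl"]
                if study.extra_sd > 0:
                    jit = rng.normal(0.0, study.extra_sd)
                    mu_t += jit
                    mu_h += jit * 0.3
                tc, hdl = _draw_plausible_pairs(rng, mu_t, mu_h, chol, n)
                lo, hi = _band_age_range(ai)
                ages = rng.integers(lo, hi + 1, size=n)
                weights = rng.lognormal(0.0, config.weight_log_sd, size=n)
                preg = np.zeros(n, dtype=bool)
                if sex == "female":
                    young = ages <= 49
                    preg[young] = rng.random(young.sum()) < config.pregnancy_rate
                inj_t = rng.random(n) < config.injection_rate
                inj_h = rng.random(n) < config.injection_rate
                tc[inj_t] = _implausible_draw(rng, "total", inj_t.sum())
                hdl[inj_h] = _implausible_draw(rng, "hdl", inj_h.sum())
                if not study.hdl_measured:
                    hdl = np.full(n, np.nan)
                    inj_h = np.zeros(n, dtype=bool)
                if study.ldl_measured and study.hdl_measured:
                    vldl = np.clip(
                        rng.normal(config.vldl_mean, config.vldl_sd, size=n), 0.1, None
                    )
                    ldl = tc - hdl - vldl
                else:
                    ldl = np.full(n, np.nan)
                rows.append(
                    pd.DataFrame(
                        {
                            "study_id": study.study_id,
                            "age": ages,
                            "sex": sex,
                            "pregnant": preg,
                            "weight": weights,
                            "total": tc,
                            "hdl": hdl,
                            "ldl": ldl,
                            "device_id": study.device_id,
                            "_injected_total": inj_t,
                            "_injected_hdl": inj_h,
                            "_true_mean_total": mu_t,
                            "_true_mean_hdl": mu_h,
                        }
                    )
                )
        # under-18 records, only to exercise the age filter
        n_adult = sum(study.stratum_n.values())
        n_minor = int(np.round(config.under18_rate * n_adult))
        if n_minor > 0:
            ages = rng.integers(13, 18, size=n_minor)
            ci0 = hierarchy.country_index(study.country)
            mu_t = surfaces["total"].values[ci0, ti, 0, 0] + study.offsets["total"]
            mu_h = surfaces["hdl"].values[ci0, ti, 0, 0] + study.offsets["hdl"]
            tc_m, hdl_m = _draw_plausible_pairs(rng, mu_t, mu_h, chol, n_minor)
            rows.append(
                pd.DataFrame(
                    {
                        "study_id": study.study_id,
                        "age": ages,
                        "sex": rng.choice(SEXES, size=n_minor),
                        "pregnant": False,
                        "weight": rng.lognormal(0.0, config.weight_log_sd, size=n_minor),
                        "total": tc_m,
                        "hdl": hdl_m,
                        "ldl": np.nan,
                        "device_id": study.device_id,
                        "_injected_total": False,
                        "_injected_hdl": False,
                        "_true_mean_total": mu_t,
                        "_true_mean_hdl": mu_h,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "study_id", "person_id", "age", "sex", "pregnant", "weight",
                "total", "hdl", "ldl", "device_id",
                "_injected_total", "_injected_hdl",
                "_true_mean_total", "_true_mean_hdl",
            ]
        )
    out = pd.concat(rows, ignore_index=True)
    out.insert(1, "person_id", np.arange(len(out)))
    return out


def _draw_plausible_pairs(rng, mu_t, mu_h, chol, n):
    """Correlated (total, HDL) draws truncated to the plausibility windows.

    The synthetic clean population contains no genuinely implausible
    values — implausible records are measurement errors, which the
    generator represents solely through explicit injection — so filter
    ground truth is exact. The truncation displaces stratum means from
    the nominal truth by well under 0.01 mmol/l at default settings.
    """
    lo_t, hi_t = PLAUSIBLE_RANGE["total"]
    lo_h, hi_h = PLAUSIBLE_RANGE["hdl"]
    tc = np.empty(n)
    hdl = np.empty(n)
    todo = np.arange(n)
    for _ in range(100):
        zs = rng.standard_normal((len(todo), 2)) @ chol.T
        t_new = mu_t + zs[:, 0]
        h_new = mu_h + zs[:, 1]
        tc[todo] = t_new
        hdl[todo] = h_new
        # total cholesterol physically includes the HDL fraction
        bad = (
            (t_new <= lo_t) | (t_new >= hi_t) | (h_new <= lo_h) | (h_new >= hi_h)
            | (t_new <= h_new)
        )
        todo = todo[bad]
        if len(todo) == 0:
            break
    else:
        raise RuntimeError("rejection sampling failed: window too improbable")
    return tc, hdl


def _implausible_draw(rng, metric, n):
    """Uniform draw outside the plausibility window (guaranteed filter hit)."""
    lo, hi = PLAUSIBLE_RANGE[metric]
    below_lo = 0.5 if metric == "total" else 0.05
    above_hi = 30.0 if metric == "total" else 8.0
    out = np.empty(n)
    low = rng.random(n) < 0.5
    out[low] = rng.uniform(below_lo, lo - 0.01, size=low.sum())
    out[~low] = rng.uniform(hi + 0.01, above_hi, size=(~low).sum())
    return out


# ---------------------------------------------------------------------------
# serialization


def studies_to_frame(studies: list) -> pd.DataFrame:
    rows = []
    for s in studies:
        rows.append(
            {
                "study_id": s.study_id,
                "country": s.country,
                "year": s.year,
                "coverage": s.coverage,
                "urbanicity": s.urbanicity,
                "frame": s.frame,
                "device_id": s.device_id if s.device_id is not None else "laboratory",
                "offset_total": s.offsets["total"],
                "offset_hdl": s.offsets["hdl"],
                "extra_sd": s.extra_sd,
                "hdl_measured": s.hdl_measured,
                "ldl_measured": s.ldl_measured,
            }
        )
    return pd.DataFrame(rows)


def truth_to_frame(hierarchy: GeoHierarchy, surfaces: dict) -> pd.DataFrame:
    """Long-format truth table keyed by (metric, country, year, sex, band)."""
    recs = []
    for metric, surf in surfaces.items():
        v = surf.values
        for ci, c in enumerate(hierarchy.country_ids):
            for ti, year in enumerate(hierarchy.years):
                for si, sex in enumerate(SEXES):
                    for ai, band in enumerate(AGE_BAND_LABELS):
                        recs.append((metric, c, int(year), sex, band, v[ci, ti, si, ai]))
    return pd.DataFrame(
        recs, columns=["metric", "country", "year", "sex", "age_band", "true_mean"]
    )
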