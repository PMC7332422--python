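"""Age-standardization, aggregation, trend summaries.

Turns posterior surfaces into reported quantities: age-standardized
means (WHO standard population collapsed onto the analysis bands),
population-weighted regional and global aggregates, 2.5/50/97.5
percentile credible intervals, change per decade over the analysis
period, and posterior probabilities of decline/increase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_world import GeoHierarchy
from .trend_model import TrendFit

#: WHO world standard population (2000-2025), percent by 5-year group,
#: for the groups overlapping the adult analysis bands. The 18-19 band
#: takes two fifths of the 15-19 weight; 10-year bands sum two 5-year
#: groups; 80+ pools 80-84 and 85+.
_WHO_5YR = {
    "15-19": 8.47, "20-24": 8.22, "25-29": 7.93, "30-34": 7.61,
    "35-39": 7.15, "40-44": 6.59, "45-49": 6.04, "50-54": 5.37,
    "55-59": 4.55, "60-64": 3.72, "65-69": 2.96, "70-74": 2.21,
    "75-79": 1.52, "80-84": 0.91, "85+": 0.63,
}


def standard_weights() -> np.ndarray:
    """Standard-population weights on the analysis bands, renormalized to 1."""
    w = np.array(
        [
            _WHO_5YR["15-19"] * 2.0 / 5.0,
            _WHO_5YR["20-24"] + _WHO_5YR["25-29"],
            _WHO_5YR["30-34"] + _WHO_5YR["35-39"],
            _WHO_5YR["40-44"] + _WHO_5YR["45-49"],
            _WHO_5YR["50-54"] + _WHO_5YR["55-59"],
            _WHO_5YR["60-64"] + _WHO_5YR["65-69"],
            _WHO_5YR["70-74"] + _WHO_5YR["75-79"],
            _WHO_5YR["80-84"] + _WHO_5YR["85+"],
        ]
    )
    return w / w.sum()


def age_standardize(surface: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted average over the trailing age-band axis, per draw.

    ``surface`` has shape (..., n_bands); raises if the weight vector does
    not cover every band.
    """
    weights = standard_weights() if weights is None else np.asarray(weights, dtype=float)
    if surface.shape[-1] != len(weights):
        raise ValueError(
            f"surface has {surface.shape[-1]} bands but {len(weights)} weights given"
        )
    return surface @ weights


def aggregate(
    surface: np.ndarray,
    hierarchy: GeoHierarchy,
    grouping: dict,
    sex: str | None = None,
) -> dict:
    """Population-weighted aggregate surfaces for groups of countries.

    ``surface`` is (n_draws, n_c, n_t, n_bands) aligned to the hierarchy;
    ``grouping`` maps group id -> list of country ids. Weighting happens
    at band level with country-year-band populations (summed over sexes
    unless ``sex`` is given), so aggregation and age-standardization
    commute with further grouping. Returns group id -> (n_draws, n_t,
    n_bands).
    """
    pop = hierarchy.population  # (n_c, n_t, n_sex, n_bands)
    pop = pop.sum(axis=2) if sex is None else pop[:, :, 0 if sex == "female" else 1, :]
    out = {}
    for gid, members in grouping.items():
        if not members:
            raise ValueError(f"empty group {gid!r}")
        idx = [hierarchy.country_index(c) for c in members]
        w = pop[idx]  # (k, n_t, n_bands)
        v = surface[:, idx]  # (n_draws, k, n_t, n_bands)
        out[gid] = np.einsum("dktb,ktb->dtb", v, w) / w.sum(axis=0)[None]
    return out


def change_per_decade(
    series: np.ndarray,
    years: np.ndarray,
    start: int | None = None,
    end: int | None = None,
    decade_divisor: float | None = None,
) -> np.ndarray:
    """Per-draw (value at end - value at start) / elapsed decades.

    ``series`` is (n_draws, n_t) aligned to ``years``. The divisor
    defaults to elapsed years / 10 (3.8 for 1980-2018); an inclusive
    year-count convention can be imposed via ``decade_divisor``.
    """
    years = np.asarray(years)
    start = int(years[0]) if start is None else start
    end = int(years[-1]) if end is None else end
    i0 = int(np.searchsorted(years, start))
    i1 = int(np.searchsorted(years, end))
    if i0 >= len(years) or i1 >= len(years) or years[i0] != start or years[i1] != end:
        raise ValueError("series does not cover both endpoints")
    div = (end - start) / 10.0 if decade_divisor is None else decade_divisor
    return (series[:, i1] - series[:, i0]) / div


def trend_probability(changes: np.ndarray) -> tuple[float, float]:
    """(pp decline, pp increase): fractions of draws below / above zero."""
    changes = np.asarray(changes)
    if changes.size == 0:
        raise ValueError("need at least one draw")
    return float(np.mean(changes < 0)), float(np.mean(changes > 0))


def percentiles(draws: np.ndarray, axis: int = 0) -> dict:
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5], axis=axis)
    return {"lo": lo, "median": med, "hi": hi}


def summarize_fit(
    fit: TrendFit,
    hierarchy: GeoHierarchy,
    weights: np.ndarray | None = None,
    decade_divisor: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimates and trends tables for countries, regions and the world.

    Returns (estimates, trends): estimates rows are (metric, entity_type,
    entity, sex, year, mean, lo, hi) of age-standardized means; trends
    rows add change per decade with credible interval and posterior
    probabilities of decline and increase.
    """
    weights = standard_weights() if weights is None else weights
    surf = fit.surface.astype(float)
    groupings = {}
    for r in hierarchy.region_ids:
        groupings[("region", r)] = hierarchy.countries_in_region(r)
    groupings[("world", "world")] = list(fit.countries)

    series = {}
    for ci, c in enumerate(fit.countries):
        series[("country", c)] = age_standardize(surf[:, ci], weights)
    agg = aggregate(surf, hierarchy, {k: v for k, v in groupings.items()}, sex=fit.sex)
    for key, band_surface in agg.items():
        series[key] = age_standardize(band_surface, weights)

    est_rows, trend_rows = [], []
    for (etype, eid), s in series.items():
        pct = percentiles(s)
        for ti, year in enumerate(fit.years):
            est_rows.append(
                {
                    "metric": fit.metric, "entity_type": etype, "entity": eid,
                    "sex": fit.sex, "year": int(year),
                    "mean": float(np.mean(s[:, ti])),
                    "lo": float(pct["lo"][ti]), "hi": float(pct["hi"][ti]),
                }
            )
        ch = change_per_decade(s, fit.years, decade_divisor=decade_divisor)
        ppd, ppi = trend_probability(ch)
        cpct = percentiles(ch)
        trend_rows.append(
            {
                "metric": fit.metric, "entity_type": etype, "entity": eid,
                "sex": fit.sex,
                "change_per_decade": float(np.mean(ch)),
                "lo": float(cpct["lo"]), "hi": float(cpct["hi"]),
                "pp_decline": ppd, "pp_increase": ppi,
            }
        )
    return pd.DataFrame(est_rows), pd.DataFrame(trend_rows)
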