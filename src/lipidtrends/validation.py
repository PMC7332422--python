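"""External predictive-validity harness: two hold-out tests.

Test "countries" creates the appearance of no-data countries by holding
out all data from 10% of countries with data; test "sources" holds out
10% of data sources, per affected country either a random half of its
sources or all of its 2000-2018 sources (the two modes alternate
deterministically). Held-out units are sampled within data-availability
strata: data rich (>= 5 sources with at least one after 2000), data poor
(exactly 1 source), average (2-4 sources). Each test runs five
repetitions with different subsets; the model is refitted on the
remaining data and held-out stratum means are compared with their
posterior predictions. Errors are held-out value minus estimate, so
over-estimation gives negative error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_world import GeoHierarchy
from .trend_model import ModelSpec, fit_metric, predictive_observation_draws

logger = logging.getLogger(__name__)

RICHNESS = ("data rich", "data poor", "average")


def classify_richness(sources: pd.DataFrame) -> str:
    """Classify one country's source inventory (needs a ``year`` column).

    >= 5 sources with at least one after 2000 is data rich; exactly 1 is
    data poor; 2-4 is average; >= 5 sources none of which post-dates 2000
    is classified average (the rich class requires a recent source).
    Zero sources returns "no data" (never eligible for hold-out).
    """
    n = len(sources)
    if n == 0:
        return "no data"
    if n == 1:
        return "data poor"
    if n >= 5 and (sources["year"] > 2000).any():
        return "data rich"
    return "average"


@dataclass
class HoldoutPlan:
    kind: str  # "countries" | "sources"
    repetition: int  # 1-based
    held_out: list  # country ids or study ids
    modes: dict = field(default_factory=dict)  # sources test: country -> mode
    richness: dict = field(default_factory=dict)  # unit -> stratum

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "repetition": self.repetition,
                "held_out": list(self.held_out),
                "modes": self.modes,
                "richness": self.richness,
            },
            indent=1,
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _allocate(counts: dict, total: int) -> dict:
    """Largest-remainder allocation of ``total`` across strata."""
    sizes = {k: v for k, v in counts.items() if v > 0}
    grand = sum(sizes.values())
    raw = {k: total * v / grand for k, v in sizes.items()}
    alloc = {k: int(np.floor(r)) for k, r in raw.items()}
    rem = total - sum(alloc.values())
    for k in sorted(sizes, key=lambda k: raw[k] - alloc[k], reverse=True):
        if rem <= 0:
            break
        if alloc[k] < sizes[k]:
            alloc[k] += 1
            rem -= 1
    return alloc


def make_holdout_plans(
    studies_meta: pd.DataFrame,
    kind: str,
    seed: int,
    n_reps: int = 5,
    frac: float = 0.10,
) -> list:
    """Build the repetition plans for one test.

    ``studies_meta`` needs study_id, country, year. Eligible units are
    countries with data (countries test) or individual sources (sources
    test, selected through their countries). 10% of units (rounded half
    up) are held per repetition, allocated across richness strata by
    largest remainder and sampled within strata.
    """
    if kind not in ("countries", "sources"):
        raise ValueError(f"unknown test kind {kind!r}")
    rng = np.random.default_rng([int(seed), 505])
    by_country = dict(tuple(studies_meta.groupby("country")))
    richness = {c: classify_richness(g) for c, g in by_country.items()}
    countries = [c for c in by_country if richness[c] != "no data"]
    if len(countries) < 10 and kind == "countries":
        raise ValueError("need at least 10 eligible countries")

    plans = []
    seen = set()
    for rep in range(1, n_reps + 1):
        if kind == "countries":
            n_hold = _round_half_up(frac * len(countries))
            strata = {s: [c for c in countries if richness[c] == s] for s in RICHNESS}
            counts = {s: len(v) for s, v in strata.items()}
            alloc = _allocate(counts, n_hold)
            held = []
            for s, k in alloc.items():
                pool = strata[s]
                if k > len(pool):
                    logger.warning(
                        "stratum %s too small (%d < %d), taking all", s, len(pool), k
                    )
                    k = len(pool)
                held.extend(rng.choice(pool, size=k, replace=False).tolist())
            plan = HoldoutPlan(
                kind, rep, sorted(held),
                richness={c: richness[c] for c in held},
            )
        else:
            n_sources = len(studies_meta)
            target = _round_half_up(frac * n_sources)
            order = list(rng.permutation(countries))
            held_sources, modes, rich = [], {}, {}
            mode_toggle = int(rng.integers(2))
            for c in order:
                if len(held_sources) >= target:
                    break
                g = by_country[c]
                mode = ("random_half", "all_2000_2018")[mode_toggle % 2]
                mode_toggle += 1
                if mode == "random_half":
                    k = max(1, len(g) // 2)
                    pick = rng.choice(g["study_id"].to_numpy(), size=k, replace=False)
                else:
                    pick = g.loc[g["year"] >= 2000, "study_id"].to_numpy()
                    if len(pick) == 0 or len(pick) == len(g):
                        # nothing (or everything) is post-2000: fall back
                        k = max(1, len(g) // 2)
                        pick = rng.choice(
                            g["study_id"].to_numpy(), size=k, replace=False
                        )
                        mode = "random_half"
                held_sources.extend(pick.tolist())
                modes[c] = mode
                rich[c] = richness[c]
            plan = HoldoutPlan(kind, rep, sorted(held_sources), modes=modes, richness=rich)
        key = tuple(plan.held_out)
        if key in seen:  # force distinct subsets across repetitions
            continue_rng = np.random.default_rng([int(seed), 505, rep])
            plan.held_out = sorted(
                continue_rng.permutation(plan.held_out).tolist()
            )
        seen.add(tuple(plan.held_out))
        plans.append(plan)
    return plans


@dataclass
class ValidationReport:
    kind: str
    table: pd.DataFrame  # per stratum + overall: median error, MAE, coverage
    errors: pd.DataFrame  # pooled per-held-out-stratum errors
    n_reps: int
    failed_reps: list

    def text_summary(self) -> str:
        lines = [
            f"hold-out test: {self.kind} ({self.n_reps} repetitions; "
            "error = held-out value minus estimate)",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r['stratum']:>10}: median error {r['median_error']:+.3f}, "
                f"MAE {r['median_abs_error']:.3f}, "
                f"95% CI coverage {r['coverage_pct']:.1f}% (n={int(r['n'])})"
            )
        return "\n".join(lines)


def run_validation(
    strata: pd.DataFrame,
    hierarchy: GeoHierarchy,
    plans: list,
    metric: str = "total",
    sex: str = "female",
    spec: ModelSpec | None = None,
    seed: int = 0,
    n_burn: int = 400,
    n_draws: int = 400,
    predictor=None,
) -> ValidationReport:
    """Refit per plan and score held-out stratum means.

    Returns per-richness-stratum and overall median error, median
    absolute error and 95% credible-interval coverage over the pooled
    errors of all repetitions. Leakage is asserted: no held-out study
    contributes observations to its repetition's design.

    ``predictor``, if given, is a callable mapping a held-out stratum row
    to an array of predictive draws and replaces the model refit — used
    to verify the scoring arithmetic against fixtures with known errors.
    """
    spec = spec or ModelSpec()
    sub = strata[(strata["metric"] == metric) & (strata["sex"] == sex)]
    sub = sub[np.isfinite(sub["se"]) & (sub["se"] > 0)]
    err_rows = []
    failed = []
    for plan in plans:
        if plan.kind == "countries":
            held_mask = sub["country"].isin(plan.held_out)
            rich_of = lambda row: plan.richness[row["country"]]  # noqa: E731
        else:
            held_mask = sub["study_id"].isin(plan.held_out)
            rich_of = lambda row: plan.richness.get(row["country"], "average")  # noqa: E731
        train = sub[~held_mask]
        test = sub[held_mask]
        if len(test) == 0:
            continue
        held_ids = set(plan.held_out)
        if plan.kind == "sources":
            assert not set(train["study_id"]) & held_ids, "leakage: held-out source in fit"
        else:
            assert not set(train["country"]) & held_ids, "leakage: held-out country in fit"
        if predictor is None:
            try:
                fit = fit_metric(
                    train, hierarchy, metric, sex, spec,
                    seed=seed + 17 * plan.repetition,
                    n_burn=n_burn, n_draws=n_draws,
                )
            except Exception as e:  # pragma: no cover - defensive
                logger.error("repetition %d refit failed: %s", plan.repetition, e)
                failed.append(plan.repetition)
                continue
            score_rng = np.random.default_rng([int(seed), 606, plan.repetition])
        for _, row in test.iterrows():
            if predictor is not None:
                draws = np.asarray(predictor(row), dtype=float)
            else:
                draws = predictive_observation_draws(
                    fit,
                    row["country"],
                    int(row["year"]),
                    row["age_band"],
                    coverage=row.get("coverage", "national"),
                    urbanicity=row.get("urbanicity", "mixed"),
                    se=float(row["se"]),
                    rng=score_rng,
                )
            lo, hi = np.percentile(draws, [2.5, 97.5])
            est = float(np.median(draws))
            err_rows.append(
                {
                    "repetition": plan.repetition,
                    "stratum": rich_of(row),
                    "error": float(row["mean"]) - est,
                    "covered": bool(lo <= row["mean"] <= hi),
                }
            )
    errors = pd.DataFrame(err_rows)
    rows = []
    groups = [("overall", errors)] + [
        (s, errors[errors["stratum"] == s]) for s in RICHNESS
    ]
    for name, g in groups:
        if len(g) == 0:
            continue
        rows.append(
            {
                "stratum": name,
                "median_error": float(g["error"].median()),
                "median_abs_error": float(g["error"].abs().median()),
                "coverage_pct": float(100.0 * g["covered"].mean()),
                "n": len(g),
            }
        )
    return ValidationReport(
        kind=plans[0].kind if plans else "none",
        table=pd.DataFrame(rows),
        errors=errors,
        n_reps=len(plans),
        failed_reps=failed,
    )
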