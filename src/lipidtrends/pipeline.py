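"""End-to-end orchestration: simulate, clean, adjust, fit, summarize,
burden, validate — with a run manifest, config hashing and per-stage
seeds so a rerun with the same config reproduces every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import device_adjust, ingest_clean, postprocess, synthetic_world, trend_model
from . import validation as validation_mod
from .bands import AGE_BAND_LABELS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "adjust", "fit", "summarize", "burden", "validate")
_DEPS = {
    "simulate": (),
    "clean": ("simulate",),
    "adjust": ("clean",),
    "fit": ("adjust",),
    "summarize": ("fit",),
    "burden": ("summarize",),
    "validate": ("adjust",),
}


def default_device_specs() -> list:
    """Illustrative synthetic analytical ranges (not manufacturer values)."""
    return [
        device_adjust.DeviceSpec("pd-narrow", "total", 3.0, 6.5),
        device_adjust.DeviceSpec("pd-narrow", "hdl", 0.65, 2.6),
        device_adjust.DeviceSpec("pd-narrow", "non_hdl", 1.8, 5.8),
        device_adjust.DeviceSpec("pd-wide", "total", 2.2, 8.5),
        device_adjust.DeviceSpec("pd-wide", "hdl", 0.5, 3.5),
        device_adjust.DeviceSpec("pd-wide", "non_hdl", 1.4, 7.5),
    ]


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 1
    stages: tuple = STAGES
    world: synthetic_world.WorldConfig = field(
        default_factory=synthetic_world.WorldConfig
    )
    metrics: tuple = ("total", "non_hdl", "hdl")
    sexes: tuple = ("female", "male")
    n_burn: int = 400
    n_draws: int = 400
    decade_divisor: float | None = None
    validation_kinds: tuple = ("countries", "sources")
    validation_reps: int = 5
    log_level: str = "INFO"

    def semantic_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("log_level")
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        world_raw = kwargs.pop("world", {})
        wc_kwargs = dict(world_raw)
        studies = wc_kwargs.pop("studies", {})
        records = wc_kwargs.pop("records", {})
        total = wc_kwargs.pop("total", None)
        hdl = wc_kwargs.pop("hdl", None)
        world = synthetic_world.WorldConfig(
            **wc_kwargs,
            studies=synthetic_world.StudyConfig(**studies),
            records=synthetic_world.RecordConfig(**records),
        )
        if total:
            world.total = dataclasses.replace(world.total, **total)
        if hdl:
            world.hdl = dataclasses.replace(world.hdl, **hdl)
        for key in ("stages", "metrics", "sexes", "validation_kinds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(world=world, **kwargs)


def _truncate_device_records(records, studies_meta, specs):
    """Emulate analytical-range truncation for device-measured studies.

    Values outside a device's per-metric range are set missing, exactly
    mirroring how conversion training pairs restrict laboratory values.
    """
    df = records.copy()
    df["non_hdl"] = df["total"] - df["hdl"]
    by_key = {(s.metric, s.device_id): s for s in specs}
    for metric in ("total", "hdl", "non_hdl"):
        for dev in df["device_id"].dropna().unique():
            if dev == "laboratory":
                continue
            spec = by_key.get((metric, dev))
            if spec is None:
                continue
            m = (df["device_id"] == dev) & (
                (df[metric] <= spec.range_min) | (df[metric] >= spec.range_max)
            )
            df.loc[m, metric] = np.nan
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; return the manifest.

    A stage failure halts its dependents but independent branches
    complete; the (partial) manifest is always written to
    ``<out_dir>/manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    ctx: dict = {}
    enabled = [s for s in STAGES if s in config.stages]
    status = {}

    def stage_ok(name):
        return all(status.get(d) == "ok" for d in _DEPS[name])

    runners = {
        "simulate": _stage_simulate,
        "clean": _stage_clean,
        "adjust": _stage_adjust,
        "fit": _stage_fit,
        "summarize": _stage_summarize,
        "burden": _stage_burden,
        "validate": _stage_validate,
    }
    for name in enabled:
        if not stage_ok(name):
            status[name] = "skipped (dependency failed or disabled)"
            manifest["stages"][name] = {"status": status[name]}
            continue
        try:
            artifacts = runners[name](config, ctx, out)
            status[name] = "ok"
            manifest["stages"][name] = {
                "status": "ok",
                "seed": config.seed,
                "artifacts": artifacts,
            }
            manifest["artifacts"].update(
                {k: str(v) for k, v in (artifacts or {}).items()}
            )
        except Exception as e:
            logger.error("stage %s failed: %s", name, e)
            status[name] = "failed"
            manifest["stages"][name] = {
                "status": "failed",
                "error": f"{type(e).__name__}: {e}",
                "traceback": traceback.format_exc(limit=5),
            }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash()
    return df


def _stage_simulate(config, ctx, out):
    hierarchy, surfaces = synthetic_world.generate_world(config.world, config.seed)
    studies = synthetic_world.generate_studies(
        hierarchy, config.world.studies, config.seed
    )
    records = synthetic_world.generate_records(
        hierarchy, surfaces, studies, config.world.records, config.seed
    )
    ctx.update(hierarchy=hierarchy, surfaces=surfaces, studies=studies, records=records)
    ctx["studies_meta"] = synthetic_world.studies_to_frame(studies)
    paths = {
        "records": out / "records.csv",
        "studies": out / "studies.csv",
        "truth": out / "truth.csv",
    }
    _stamp(records.drop(columns=[c for c in records if c.startswith("_")]), config).to_csv(
        paths["records"], index=False
    )
    _stamp(ctx["studies_meta"], config).to_csv(paths["studies"], index=False)
    _stamp(
        synthetic_world.truth_to_frame(hierarchy, surfaces), config
    ).to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}


def _stage_clean(config, ctx, out):
    retained, log = ingest_clean.filter_participants(ctx["records"])
    ctx["clean_records"] = retained
    ctx["exclusion_log"] = log
    paths = {"exclusion_log": out / "exclusion_log.csv"}
    _stamp(log.per_rule.reset_index(), config).to_csv(paths["exclusion_log"], index=False)
    return {k: str(v) for k, v in paths.items()}


def _stage_adjust(config, ctx, out):
    specs = default_device_specs()
    truncated = _truncate_device_records(ctx["clean_records"], ctx["studies_meta"], specs)
    strata = ingest_clean.summarize_strata(
        truncated, studies_meta=ctx["studies_meta"], metrics=tuple(config.metrics)
    )
    models = {}
    device_metrics = {
        (s.metric, s.device_id)
        for s in specs
        if s.metric in config.metrics
    }
    present = set(
        strata.loc[~strata["device_id"].isin(["laboratory"]), "device_id"].dropna()
    )
    for metric, dev in sorted(device_metrics):
        if dev not in present:
            continue
        spec = next(s for s in specs if s.metric == metric and s.device_id == dev)
        companions = None
        if metric == "non_hdl":
            companions = {
                s.metric: s for s in specs
                if s.device_id == dev and s.metric in ("total", "hdl")
            }
        try:
            pairs = device_adjust.make_training_pairs(
                ctx["clean_records"], ctx["studies_meta"], spec, metric,
                companion_specs=companions,
            )
            models[(metric, dev)] = device_adjust.fit_conversion(pairs, metric, dev)
        except ValueError as e:
            logger.warning("no conversion model for %s/%s: %s", metric, dev, e)
    adjusted = device_adjust.adjust_device_strata(
        strata, models, seed=config.seed + 7
    )
    adjusted = adjusted[np.isfinite(adjusted["se"]) & (adjusted["se"] > 0)]
    ctx["strata"] = adjusted
    ctx["conversion_models"] = models
    paths = {"strata": out / "strata.csv", "conversions": out / "conversion_models.json"}
    _stamp(adjusted, config).to_csv(paths["strata"], index=False)
    paths["conversions"].write_text(
        json.dumps({f"{m}/{d}": json.loads(v.to_json()) for (m, d), v in models.items()},
                   indent=1)
    )
    return {k: str(v) for k, v in paths.items()}


def _stage_fit(config, ctx, out):
    spec = trend_model.ModelSpec()
    fits = trend_model.fit_sequence(
        ctx["strata"], ctx["hierarchy"], spec,
        seed=config.seed,
        sexes=tuple(config.sexes),
        metrics=tuple(config.metrics),
        n_burn=config.n_burn,
        n_draws=config.n_draws,
    )
    ctx["fits"] = fits
    diag = {
        f"{m}/{s}": fit.diagnostics | {"flagged": fit.flagged}
        for (m, s), fit in fits.items()
    }
    path = out / "mcmc_diagnostics.json"
    path.write_text(json.dumps(diag, indent=1))
    return {"mcmc_diagnostics": str(path)}


def _stage_summarize(config, ctx, out):
    est_all, trend_all = [], []
    for (m, s), fit in ctx["fits"].items():
        est, trend = postprocess.summarize_fit(
            fit, ctx["hierarchy"], decade_divisor=config.decade_divisor
        )
        est_all.append(est)
        trend_all.append(trend)
    estimates = pd.concat(est_all, ignore_index=True)
    trends = pd.concat(trend_all, ignore_index=True)
    ctx["estimates"] = estimates
    ctx["trends"] = trends
    paths = {"estimates": out / "estimates.csv", "trends": out / "trends.csv"}
    _stamp(estimates, config).to_csv(paths["estimates"], index=False)
    _stamp(trends, config).to_csv(paths["trends"], index=False)
    return {k: str(v) for k, v in paths.items()}


def _stage_burden(config, ctx, out):
    """PAF and attributable deaths for the latest year, using the fitted
    non-HDL surfaces (falling back to total cholesterol if non-HDL was
    not fitted) and a synthetic deaths table proportional to population."""
    metric = "non_hdl" if ("non_hdl" in config.metrics) else config.metrics[0]
    rows, deaths_rows = [], []
    hierarchy = ctx["hierarchy"]
    year = int(hierarchy.years[-1])
    rr = burden_mod.illustrative_rr_curves()
    for (m, s), fit in ctx["fits"].items():
        if m != metric:
            continue
        post_mean = fit.surface.astype(float).mean(axis=0)  # (c, t, bands)
        ti = len(fit.years) - 1
        si = 0 if s == "female" else 1
        for ci, c in enumerate(fit.countries):
            for ai, band in enumerate(AGE_BAND_LABELS):
                rows.append(
                    {
                        "country": c, "year": year, "sex": s, "age_band": band,
                        "mean": post_mean[ci, ti, ai], "sd": 0.9,
                    }
                )
                pop = hierarchy.population[ci, ti, si, ai]
                for cause, rate in (("ihd", 2e-3), ("ischaemic_stroke", 8e-4)):
                    deaths_rows.append(
                        {
                            "cause": cause, "country": c, "year": year, "sex": s,
                            "age_band": band, "deaths": pop * rate,
                        }
                    )
    exposure = pd.DataFrame(rows)
    deaths = pd.DataFrame(deaths_rows)
    pafs = burden_mod.paf_table(exposure, rr)
    attrib = burden_mod.attributable_deaths(pafs, deaths)
    ctx["attributable"] = attrib
    paths = {"attributable_deaths": out / "attributable_deaths.csv"}
    _stamp(attrib, config).to_csv(paths["attributable_deaths"], index=False)
    return {k: str(v) for k, v in paths.items()}


def _stage_validate(config, ctx, out):
    reports = {}
    artifacts = {}
    for kind in config.validation_kinds:
        plans = validation_mod.make_holdout_plans(
            ctx["studies_meta"].merge(
                ctx["strata"][["study_id"]].drop_duplicates(), on="study_id"
            ),
            kind,
            seed=config.seed,
            n_reps=config.validation_reps,
        )
        report = validation_mod.run_validation(
            ctx["strata"], ctx["hierarchy"], plans,
            metric=config.metrics[0], sex=config.sexes[0],
            seed=config.seed, n_burn=config.n_burn, n_draws=config.n_draws,
        )
        reports[kind] = report
        path = out / f"validation_{kind}.csv"
        _stamp(report.table, config).to_csv(path, index=False)
        (out / f"validation_{kind}.txt").write_text(report.text_summary() + "\n")
        artifacts[f"validation_{kind}"] = str(path)
    ctx["validation"] = reports
    return artifacts
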