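"""Source eligibility, participant plausibility filters, stratum summaries.

Participant-level rules: adults (18+) who are not pregnant; total
cholesterol inside (1.75, 20) mmol/l; HDL inside (0.4, 5) mmol/l; total
not below HDL; and, when LDL is present, a cross-metric consistency rule
built from allowable measurement-error limits (8.9% total, 13% HDL, 12%
LDL): a record is removed when

    LDL * (1 - eLDL) + HDL * (1 - eHDL) > TC * (1 + eTC)

i.e. the HDL + LDL sum still exceeds total cholesterol after shifting
every component to its error-limit extreme in the record's favour — the
most permissive reading of "more than is plausible given measurement
error". Bounds are strict: a value exactly at a window edge is retained.
Missing values pass the rules that need them.

Cleaned records are collapsed into survey-weighted sex x age-band stratum
summaries (mean, SE, effective sample size), the observational unit of
the trend model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import AGE_BAND_LABELS, PLAUSIBLE_RANGE, band_index_for_age

#: Order in which rules are applied; a removed record is attributed to the
#: first rule it violates, so per-rule counts sum to the total removed.
RULE_ORDER = (
    "under_18",
    "pregnant",
    "total_out_of_range",
    "hdl_out_of_range",
    "total_below_hdl",
    "crmln_sum",
)


@dataclass
class PlausibilityRules:
    total_range: tuple = PLAUSIBLE_RANGE["total"]
    hdl_range: tuple = PLAUSIBLE_RANGE["hdl"]
    e_total: float = 0.089
    e_hdl: float = 0.13
    e_ldl: float = 0.12

    def __post_init__(self):
        for lo, hi in (self.total_range, self.hdl_range):
            if not lo < hi:
                raise ValueError("plausibility window requires lower < upper")
        for e in (self.e_total, self.e_hdl, self.e_ldl):
            if not 0 < e < 1:
                raise ValueError("error limits must lie in (0, 1)")


@dataclass
class EligibilityResult:
    status: str  # "eligible" | "ineligible" | "undeterminable"
    reasons: list = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return self.status == "eligible"


def check_source_eligibility(
    study,
    school_enrolment_pct: float | None = None,
    insured_pct: float | None = None,
) -> EligibilityResult:
    """Apply the source-level inclusion rules.

    Probabilistic frames are eligible. School-based frames require
    secondary-school enrolment of at least 70%; insurance frames require
    at least 80% of the population insured; primary-care frames are
    accepted (they are used only where contact with primary care matches
    survey response rates, a context judgement outside this function).
    Missing context for a frame that needs it yields "undeterminable".
    """
    frame = getattr(study, "frame", None)
    if frame in ("probabilistic", "primary-care"):
        return EligibilityResult("eligible")
    if frame == "school":
        if school_enrolment_pct is None:
            return EligibilityResult(
                "undeterminable", ["school frame but enrolment unknown"]
            )
        if school_enrolment_pct < 70.0:
            return EligibilityResult(
                "ineligible",
                [f"school frame with enrolment {school_enrolment_pct:g}% < 70%"],
            )
        return EligibilityResult("eligible")
    if frame == "insurance":
        if insured_pct is None:
            return EligibilityResult(
                "undeterminable", ["insurance frame but insured share unknown"]
            )
        if insured_pct < 80.0:
            return EligibilityResult(
                "ineligible",
                [f"insurance frame with insured share {insured_pct:g}% < 80%"],
            )
        return EligibilityResult("eligible")
    return EligibilityResult("ineligible", [f"non-probabilistic frame {frame!r}"])


@dataclass
class ExclusionLog:
    per_rule: pd.DataFrame  # index: study_id, columns: rules + retained
    n_input: int

    @property
    def n_removed(self) -> int:
        return int(self.per_rule[list(RULE_ORDER)].to_numpy().sum())

    @property
    def n_retained(self) -> int:
        return int(self.per_rule["retained"].sum())

    def reconciles(self) -> bool:
        per_study = self.per_rule[list(RULE_ORDER)].sum(axis=1) + self.per_rule["retained"]
        return (
            self.n_removed + self.n_retained == self.n_input
            and bool((per_study == self.per_rule["n_input"]).all())
        )


def _violation_masks(df: pd.DataFrame, rules: PlausibilityRules) -> dict:
    tc = df["total"].to_numpy(dtype=float)
    hdl = df["hdl"].to_numpy(dtype=float) if "hdl" in df else np.full(len(df), np.nan)
    ldl = df["ldl"].to_numpy(dtype=float) if "ldl" in df else np.full(len(df), np.nan)
    lo_t, hi_t = rules.total_range
    lo_h, hi_h = rules.hdl_range
    preg = (
        df["pregnant"].fillna(False).to_numpy(dtype=bool)
        if "pregnant" in df
        else np.zeros(len(df), dtype=bool)
    )
    masks = {
        "under_18": df["age"].to_numpy() < 18,
        "pregnant": preg,
        "total_out_of_range": (tc < lo_t) | (tc > hi_t),
        "hdl_out_of_range": (hdl < lo_h) | (hdl > hi_h),
        "total_below_hdl": tc < hdl,
        "crmln_sum": ldl * (1 - rules.e_ldl) + hdl * (1 - rules.e_hdl)
        > tc * (1 + rules.e_total),
    }
    # NaN comparisons are already False, so missing values pass.
    return {k: np.nan_to_num(v.astype(bool)) for k, v in masks.items()}


def filter_participants(
    records: pd.DataFrame, rules: PlausibilityRules | None = None
):
    """Remove implausible participants; return (retained, ExclusionLog)."""
    rules = rules or PlausibilityRules()
    masks = _violation_masks(records, rules)
    any_removed = np.zeros(len(records), dtype=bool)
    attributed = {}
    for rule in RULE_ORDER:
        hit = masks[rule] & ~any_removed
        attributed[rule] = hit
        any_removed |= masks[rule]
    retained = records.loc[~any_removed].copy()

    study = records["study_id"] if "study_id" in records else pd.Series("all", index=records.index)
    log_df = pd.DataFrame({rule: attributed[rule] for rule in RULE_ORDER})
    log_df["retained"] = ~any_removed
    log_df["n_input"] = 1
    log_df["study_id"] = study.to_numpy()
    per_rule = log_df.groupby("study_id").sum()
    return retained, ExclusionLog(per_rule=per_rule, n_input=len(records))


def _weighted_summary(x: np.ndarray, w: np.ndarray):
    """Weighted mean, SE and Kish effective sample size.

    SE uses the weighted sample variance with an (n/(n-1)) small-sample
    correction divided by the effective sample size, which collapses to
    the textbook sd/sqrt(n) under equal weights. Returns SE = NaN for
    n = 1 strata (no within-stratum variance information).
    """
    n = len(x)
    sw = w.sum()
    mean = float(np.sum(w * x) / sw)
    n_eff = float(sw**2 / np.sum(w**2))
    if n < 2:
        return mean, np.nan, n_eff, n
    s2 = float(np.sum(w * (x - mean) ** 2) / sw) * n / (n - 1)
    se = float(np.sqrt(s2 / n_eff))
    return mean, se, n_eff, n


def summarize_strata(
    records: pd.DataFrame,
    studies_meta: pd.DataFrame | None = None,
    metrics: tuple = ("total", "hdl", "non_hdl"),
) -> pd.DataFrame:
    """Collapse cleaned records to per-study sex x age-band summaries.

    Non-HDL is summarized as the weighted mean of per-person (total - HDL)
    over persons with both values. Strata with no observations for a
    metric are omitted. ``studies_meta`` (from the study table) attaches
    country, year, coverage, urbanicity and device columns.
    """
    if (records["weight"] <= 0).any() or records["weight"].isna().any():
        bad = records.loc[
            (records["weight"] <= 0) | records["weight"].isna(), "study_id"
        ].unique()
        raise ValueError(f"non-positive survey weights in studies: {sorted(bad)}")
    df = records.copy()
    df["age_band"] = np.array(AGE_BAND_LABELS, dtype=object)[
        band_index_for_age(df["age"].to_numpy())
    ]
    if "non_hdl" not in df.columns:
        df["non_hdl"] = df["total"] - df["hdl"]

    rows = []
    for (study_id, sex, band), g in df.groupby(["study_id", "sex", "age_band"], sort=True):
        for metric in metrics:
            vals = g[metric].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.sum() == 0:
                continue
            mean, se, n_eff, n = _weighted_summary(
                vals[ok], g["weight"].to_numpy(dtype=float)[ok]
            )
            rows.append(
                {
                    "study_id": study_id,
                    "sex": sex,
                    "age_band": band,
                    "metric": metric,
                    "mean": mean,
                    "se": se,
                    "n": n,
                    "n_eff": n_eff,
                }
            )
    out = pd.DataFrame(rows)
    if studies_meta is not None and len(out):
        cols = [
            c
            for c in ("study_id", "country", "year", "coverage", "urbanicity", "device_id")
            if c in studies_meta.columns
        ]
        out = out.merge(studies_meta[cols], on="study_id", how="left")
    return out
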