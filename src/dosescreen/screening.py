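"""Cohort action limits, plan screening and cross-source correlation.

Action limits follow the TG-119 confidence-limit formalism: for each
criterion the cohort mean and standard deviation (n-1 denominator) of the
secondary-vs-TPS percentage difference give

    CL = |mean| + 1.96 x SD,

the band expected to contain ~95% of future differences.  The gamma
criterion is handled on the *failure-rate* scale (100 - pass rate), and its
limit is reported equivalently as a minimum acceptable pass rate.  Dose
limits round to the nearest integer percent, gamma limits to one decimal
(ties away from zero).

A plan is flagged for phantom measurement when any criterion exceeds its
limit; a difference exactly at the limit passes.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CohortError, ConfigurationError, DomainError
from .metrics import Criterion, CriterionId, MetricComparison

__all__ = [
    "Scale",
    "Rounding",
    "ActionLimit",
    "ActionLimitTable",
    "ScreeningDecision",
    "CorrelationReport",
    "confidence_limit",
    "confidence_limit_from_moments",
    "derive_action_limits",
    "screen_case",
    "correlate",
]

#: two-sided 95% normal quantile used by the TG-119 confidence limit
CL_FACTOR = 1.96


class Scale(str, enum.Enum):
    PCT_DIFF = "PCT_DIFF"
    GAMMA_FAIL = "GAMMA_FAIL"


class Rounding(str, enum.Enum):
    INT = "INT"
    ONE_DECIMAL = "ONE_DECIMAL"
    NONE = "NONE"


def _round_half_away(x: float, decimals: int) -> float:
    f = 10.0**decimals
    return math.copysign(math.floor(abs(x) * f + 0.5), x) / f


def _apply_rounding(x: float, rounding: Rounding) -> float:
    if rounding == Rounding.INT:
        return _round_half_away(x, 0)
    if rounding == Rounding.ONE_DECIMAL:
        return _round_half_away(x, 1)
    return x


@dataclass
class ActionLimit:
    """Per-criterion cohort statistics and the resulting action limit.

    For ``Scale.GAMMA_FAIL`` the limit lives on the failure-rate scale;
    :attr:`min_pass_rate` re-expresses it as the lowest acceptable gamma
    pass rate.
    """

    criterion: str
    cohort_mean: float
    cohort_sd: float
    cl_raw: float
    limit: float
    scale: Scale = Scale.PCT_DIFF
    n: int = 0
    simplified: bool = False

    @property
    def min_pass_rate(self) -> float | None:
        if self.scale == Scale.GAMMA_FAIL:
            return 100.0 - self.limit
        return None


def confidence_limit_from_moments(
    mean: float,
    sd: float,
    rounding: Rounding = Rounding.INT,
    *,
    scale: Scale = Scale.PCT_DIFF,
    criterion: str = "",
    n: int = 0,
) -> ActionLimit:
    """TG-119 confidence limit |mean| + 1.96 x SD from given cohort moments."""
    if sd < 0:
        raise DomainError("standard deviation must be non-negative")
    cl_raw = abs(mean) + CL_FACTOR * sd
    return ActionLimit(
        criterion=criterion,
        cohort_mean=float(mean),
        cohort_sd=float(sd),
        cl_raw=float(cl_raw),
        limit=_apply_rounding(cl_raw, rounding),
        scale=scale,
        n=n,
    )


def confidence_limit(
    values,
    rounding: Rounding = Rounding.INT,
    *,
    scale: Scale = Scale.PCT_DIFF,
    criterion: str = "",
) -> ActionLimit:
    """TG-119 confidence limit from a cohort of signed % differences (or
    failure rates).  Requires at least two values; SD uses the n-1
    denominator."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise CohortError(f"confidence limit needs >= 2 values, got {v.size}")
    return confidence_limit_from_moments(
        float(v.mean()), float(v.std(ddof=1)), rounding,
        scale=scale, criterion=criterion, n=int(v.size),
    )


@dataclass
class ActionLimitTable:
    """Action limits keyed by criterion name, with provenance."""

    limits: dict[str, ActionLimit]
    site: str = ""
    uniform_simplification: float | None = None

    def __getitem__(self, criterion: str) -> ActionLimit:
        return self.limits[criterion]

    def __contains__(self, criterion: str) -> bool:
        return criterion in self.limits

    def to_json(self) -> str:
        payload = {
            "schema": "dosescreen/limits/1",
            "site": self.site,
            "uniform_simplification": self.uniform_simplification,
            "limits": {
                k: {
                    "criterion": v.criterion,
                    "cohort_mean": v.cohort_mean,
                    "cohort_sd": v.cohort_sd,
                    "cl_raw": v.cl_raw,
                    "limit": v.limit,
                    "scale": v.scale.value,
                    "n": v.n,
                    "simplified": v.simplified,
                }
                for k, v in self.limits.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ActionLimitTable":
        payload = json.loads(text)
        if payload.get("schema") != "dosescreen/limits/1":
            raise ConfigurationError("unrecognized limits-table schema")
        limits = {
            k: ActionLimit(
                criterion=d["criterion"],
                cohort_mean=d["cohort_mean"],
                cohort_sd=d["cohort_sd"],
                cl_raw=d["cl_raw"],
                limit=d["limit"],
                scale=Scale(d["scale"]),
                n=d["n"],
                simplified=d["simplified"],
            )
            for k, d in payload["limits"].items()
        }
        return cls(limits, payload.get("site", ""), payload.get("uniform_simplification"))


def derive_action_limits(
    cohort: list[list[MetricComparison]],
    *,
    site: str = "",
    dose_rounding: Rounding = Rounding.INT,
    gamma_rounding: Rounding = Rounding.ONE_DECIMAL,
    uniform_simplification: float | None = None,
) -> ActionLimitTable:
    """Derive per-criterion action limits from a cohort of comparison sets.

    Per-target criteria are pooled over all targets of all plans (each lesion
    contributes one sample), matching how multi-lesion cohorts are tabulated.
    Gamma pass rates are converted to failure rates before the confidence
    limit is computed.  With ``uniform_simplification`` every dose-criterion
    limit is replaced by that single value (marked ``simplified``); the gamma
    limit is left as derived.
    """
    if len(cohort) < 2:
        raise CohortError("a cohort of at least 2 cases is required")
    by_criterion: dict[str, list[float]] = {}
    for comps in cohort:
        for c in comps:
            key = c.criterion.name.value
            if c.is_gamma:
                by_criterion.setdefault(key, []).append(100.0 - c.secondary_value)
            else:
                by_criterion.setdefault(key, []).append(float(c.pct_diff))
    names = set(by_criterion)
    offenders = []
    for i, comps in enumerate(cohort):
        have = {c.criterion.name.value for c in comps}
        if have != names:
            offenders.append(f"case {i} missing {sorted(names - have)}")
    if offenders:
        raise CohortError("inconsistent cohort: " + "; ".join(offenders))
    limits: dict[str, ActionLimit] = {}
    for key, vals in by_criterion.items():
        is_gamma = key == Criterion.GAMMA_3D.value
        al = confidence_limit(
            vals,
            gamma_rounding if is_gamma else dose_rounding,
            scale=Scale.GAMMA_FAIL if is_gamma else Scale.PCT_DIFF,
            criterion=key,
        )
        if uniform_simplification is not None and not is_gamma:
            al.limit = float(uniform_simplification)
            al.simplified = True
        limits[key] = al
    return ActionLimitTable(limits, site=site, uniform_simplification=uniform_simplification)


@dataclass
class CriterionCheck:
    criterion: CriterionId
    observed: float
    limit: float
    scale: Scale
    passed: bool


@dataclass
class ScreeningDecision:
    """Outcome of screening one plan against an action-limit table."""

    case_id: str
    checks: list[CriterionCheck]
    flagged: bool
    flagged_targets: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "dosescreen/screening/1",
                "case_id": self.case_id,
                "flagged": self.flagged,
                "flagged_targets": self.flagged_targets,
                "checks": [
                    {
                        "criterion": str(c.criterion),
                        "observed": c.observed,
                        "limit": c.limit,
                        "scale": c.scale.value,
                        "passed": c.passed,
                    }
                    for c in self.checks
                ],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"case {self.case_id}: " + ("FLAGGED for measurement" if self.flagged else "pass")]
        for c in self.checks:
            if c.scale == Scale.GAMMA_FAIL:
                rule = f"pass rate {c.observed:.1f}% vs minimum {100 - c.limit:.1f}%"
            else:
                rule = f"{c.observed:+.2f}% vs +/-{c.limit:g}%"
            lines.append(f"  {'PASS' if c.passed else 'FAIL':4} {c.criterion}: {rule}")
        if self.flagged_targets:
            lines.append("  targets to measure: " + ", ".join(map(str, self.flagged_targets)))
        return "\n".join(lines)


def screen_case(
    comparisons: list[MetricComparison],
    limits: ActionLimitTable,
    case_id: str = "case",
) -> ScreeningDecision:
    """Screen one plan: flag it when any criterion exceeds its action limit.

    Dose criteria fail when |pct_diff| > limit; the gamma criterion fails
    when the pass rate falls below 100 - limit.  A value exactly at the
    limit passes (the limit itself is acceptable)."""
    checks: list[CriterionCheck] = []
    flagged_targets: set[int] = set()
    for c in comparisons:
        key = c.criterion.name.value
        if key not in limits:
            raise ConfigurationError(f"no action limit configured for criterion {key}")
        al = limits[key]
        if c.is_gamma:
            observed = c.secondary_value  # pass rate
            ok = observed >= 100.0 - al.limit
        else:
            observed = float(c.pct_diff)
            ok = abs(observed) <= al.limit
        checks.append(CriterionCheck(c.criterion, observed, al.limit, al.scale, ok))
        if not ok and c.criterion.target_id is not None:
            flagged_targets.add(c.criterion.target_id)
    flagged = any(not ch.passed for ch in checks)
    return ScreeningDecision(case_id, checks, flagged, sorted(flagged_targets))


@dataclass
class CorrelationReport:
    """Pearson correlations per criterion between two verification sources."""

    per_criterion: dict[str, float | None]
    n_pairs: dict[str, int]

    @property
    def mean_r(self) -> float | None:
        vals = [r for r in self.per_criterion.values() if r is not None]
        return float(np.mean(vals)) if vals else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": list(self.per_criterion),
                "r": [self.per_criterion[k] for k in self.per_criterion],
                "n_pairs": [self.n_pairs[k] for k in self.per_criterion],
            }
        )


def correlate(source_a: pd.DataFrame, source_b: pd.DataFrame) -> CorrelationReport:
    """Correlate two sources' criterion values across a cohort.

    Each frame needs columns ``case_id``, ``criterion``, ``target_id`` and a
    value column (``pct_diff`` for dose criteria is conventional, but any
    single ``value``/``secondary_value`` column is accepted).  Pairs are
    matched on (case_id, criterion, target_id); Pearson r is computed per
    criterion.  Criteria with fewer than 3 pairs raise; zero variance in
    either source yields an explicit ``None`` for that criterion.
    """

    def _prep(df: pd.DataFrame, tag: str) -> pd.DataFrame:
        df = df.copy()
        if "value" in df.columns:
            df[f"value_{tag}"] = df["value"]
        elif "pct_diff" in df.columns and "secondary_value" in df.columns:
            # dose criteria carry pct_diff; gamma rows carry the pass rate
            df[f"value_{tag}"] = df["pct_diff"].fillna(df["secondary_value"])
        elif "pct_diff" in df.columns:
            df[f"value_{tag}"] = df["pct_diff"]
        elif "secondary_value" in df.columns:
            df[f"value_{tag}"] = df["secondary_value"]
        else:
            raise ConfigurationError("no value column found (value/pct_diff/secondary_value)")
        if "target_id" not in df.columns:
            df["target_id"] = None
        df["target_id"] = df["target_id"].astype(object).where(df["target_id"].notna(), -1)
        return df[["case_id", "criterion", "target_id", f"value_{tag}"]]

    a = _prep(source_a, "a")
    b = _prep(source_b, "b")
    merged = a.merge(b, on=["case_id", "criterion", "target_id"], how="inner")
    per: dict[str, float | None] = {}
    n_pairs: dict[str, int] = {}
    for crit, g in merged.groupby("criterion", sort=False):
        x = g["value_a"].to_numpy(dtype=float)
        y = g["value_b"].to_numpy(dtype=float)
        n_pairs[crit] = len(g)
        if len(g) < 3:
            raise CohortError(f"criterion {crit} has only {len(g)} pairs (need >= 3)")
        if np.std(x) == 0 or np.std(y) == 0:
            per[crit] = None
            continue
        per[crit] = float(sps.pearsonr(x, y).statistic)
    if not per:
        raise CohortError("no overlapping (case, criterion) pairs between the sources")
    return CorrelationReport(per, n_pairs)
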