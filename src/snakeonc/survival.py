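"""Treatment grouping, survival medians, Kaplan-Meier curves and log-rank
comparisons for registry cases.

Because therapies other than surgery were too rare to analyze one by one,
cases involving chemotherapy and/or radiation (with or without surgery)
are pooled into a single multi-modality group; surgical excision with at
most a short (<5 day) NSAID course stays surgery-only. The registry never
marks censored animals, so fixture survival times are all treated as
observed deaths, but the API accepts censoring flags for synthetic or
extended registries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .registry import CaseRecord

GROUPS = ("none", "surgery_only", "multi_modality", "supportive_only", "unknown")

#: groups counted as "treated" for the treated-vs-untreated comparison
TREATED_GROUPS = ("surgery_only", "multi_modality", "supportive_only")


@dataclass(frozen=True)
class SurvivalRecord:
    case_id: str
    group: str
    time: float  # months since diagnosis
    event: bool = True

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"{self.case_id}: survival time must be > 0")


@dataclass(frozen=True)
class KMCurve:
    times: tuple[float, ...]  # distinct event times, increasing
    at_risk: tuple[int, ...]
    n_events: tuple[int, ...]
    survival: tuple[float, ...]  # S(t) just after each event time


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def treatment_group(case: CaseRecord) -> str:
    """Map a case's recorded therapy to its analysis group."""
    if case.treatment in ("chemotherapy", "surgery_and_chemotherapy") or case.radiation:
        return "multi_modality"
    if case.treatment == "surgery_only":
        return "surgery_only"
    if case.treatment == "supportive_care":
        return "supportive_only"
    if case.treatment == "none":
        return "none"
    return "unknown"


def assign_treatment_groups(cases: list[CaseRecord]) -> dict[str, str]:
    """case_id -> treatment group for every case."""
    return {c.case_id: treatment_group(c) for c in cases}


def survival_records(cases: list[CaseRecord]) -> list[SurvivalRecord]:
    """One record per case with a reported survival time (all events:
    the registry records no censoring)."""
    return [
        SurvivalRecord(case_id=c.case_id, group=treatment_group(c),
                       time=float(c.survival_months))
        for c in cases
        if c.survival_months is not None
    ]


def median_survival(records: list[SurvivalRecord]) -> float:
    """Plain sample median of survival times (average-of-middle-two for
    even n); the registry has no censoring, so this equals the KM median."""
    if not records:
        raise ValueError("empty group")
    return float(np.median([r.time for r in records]))


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i);
    censored records leave the risk set without contributing a step."""
    if not records:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.time for r in records],
        event_observed=[r.event for r in records],
    )
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    times = tuple(float(t) for t in ev.index)
    surv = tuple(float(kmf.survival_function_at_times(t).iloc[0]) for t in times)
    return KMCurve(
        times=times,
        at_risk=tuple(int(n) for n in ev["at_risk"]),
        n_events=tuple(int(d) for d in ev["observed"]),
        survival=surv,
    )


def log_rank(group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]) -> LogRankResult:
    """Two-group log-rank test (pooled-risk-set hypergeometric form),
    df = 1, chi-square upper-tail p."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        raise ValueError("log-rank undefined: no events in either group")
    res = logrank_test(
        [r.time for r in group_a], [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return LogRankResult(
        statistic=float(res.test_statistic), df=1, p_value=float(res.p_value)
    )


def export_curves(curves: dict[str, KMCurve], path) -> pd.DataFrame:
    """Write the step functions as a long table (group, time, at_risk,
    n_events, survival); returns the frame that was written."""
    if not curves:
        raise ValueError("no curves to export")
    rows = [
        {
            "group": name,
            "time": t,
            "at_risk": n,
            "n_events": d,
            "survival": s,
        }
        for name, curve in curves.items()
        for t, n, d, s in zip(curve.times, curve.at_risk, curve.n_events, curve.survival)
    ]
    df = pd.DataFrame(rows, columns=["group", "time", "at_risk", "n_events", "survival"])
    df.to_csv(path, index=False)
    return df


def treated_vs_untreated(cases: list[CaseRecord]) -> tuple[LogRankResult, dict[str, KMCurve]]:
    """Log-rank comparison (and curves) of treated snakes — surgery-only,
    multi-modality or supportive-care-only — against untreated ones; cases
    with unknown treatment are excluded from both arms."""
    recs = survival_records(cases)
    treated = [r for r in recs if r.group in TREATED_GROUPS]
    untreated = [r for r in recs if r.group == "none"]
    curves = {"treated": km_estimate(treated), "untreated": km_estimate(untreated)}
    return log_rank(treated, untreated), curves


__all__ = [
    "GROUPS", "TREATED_GROUPS",
    "SurvivalRecord", "KMCurve", "LogRankResult",
    "treatment_group", "assign_treatment_groups", "survival_records",
    "median_survival", "km_estimate", "log_rank", "export_curves",
    "treated_vs_untreated",
]
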