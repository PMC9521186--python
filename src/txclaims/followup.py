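"""Follow-up construction, person-time, incidence rates, survival.

Follow-up runs from 30 days after transplant discharge until the first
of: death, the outcome of interest (outcome-specific runs), transfer out
of the region, five years of follow-up, or the administrative study end
(2019-12-31). Under the as-treated rule, follow-up is additionally
truncated at the first treatment change (within-class switch, add-on, or
discontinuation). Persons whose outcome occurred before follow-up start
are prevalent cases and are excluded from that outcome's risk set.

Incidence rates are events per 100 person-years with exact Poisson
(chi-square inversion) confidence limits; person-years use a 365.25-day
year. The survival curve is the product-limit (Kaplan-Meier) estimator
with right censoring, events processed before censorings at tied times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cdm import AnalyticalDataset
from .simulate import OUTCOME_DX_CODE
from .utils import DAYS_PER_YEAR, round_half_up

STUDY_END = pd.Timestamp("2019-12-31")
FOLLOWUP_CAP_DAYS = int(round(5 * DAYS_PER_YEAR))

DX_COLS = [f"dx_{i}" for i in range(1, 7)]


def outcome_event_dates(dataset: AnalyticalDataset, outcome: str) -> pd.Series:
    """First hospitalization date carrying the outcome's diagnosis code,
    per person (death comes from the mortality registry instead)."""
    if outcome == "death":
        return dataset.deaths.set_index("pid")["death_date"]
    code = OUTCOME_DX_CODE[outcome]
    hosp = dataset.hospitalizations
    mask = np.zeros(len(hosp), dtype=bool)
    for col in DX_COLS:
        mask |= hosp[col].fillna("").astype(str).str.startswith(code)
    hits = hosp.loc[mask, ["pid", "admission_date"]]
    return hits.groupby("pid")["admission_date"].min()


def build_followup(cohort: pd.DataFrame, dataset: AnalyticalDataset,
                   mode: str = "ITT", outcome: str | None = None,
                   treatment_change: pd.Series | None = None,
                   study_end: pd.Timestamp = STUDY_END) -> pd.DataFrame:
    """Per-person observation interval with an end reason.

    `treatment_change` (pid -> first change date) is required for
    mode="as-treated". Returns a frame (pid, organ, start, end,
    end_reason, mode); prevalent cases for the requested outcome are
    dropped and listed in `.attrs['prevalent_excluded']`.
    """
    if mode not in ("ITT", "as-treated"):
        raise ValueError(f"unknown analysis mode: {mode}")
    if mode == "as-treated" and treatment_change is None:
        raise ValueError("as-treated analysis needs treatment-change dates")

    deaths = dataset.deaths.set_index("pid")["death_date"]
    reg = dataset.registration.sort_values("registration_start") \
        .groupby("pid").last()
    event = outcome_event_dates(dataset, outcome) if outcome else None

    rows = []
    prevalent: list[str] = []
    for _, person in cohort.iterrows():
        pid = person["pid"]
        start = person["fup_start"]
        death = deaths.get(pid, pd.NaT)

        candidates: list[tuple[pd.Timestamp, str]] = []
        if outcome is not None:
            ev = event.get(pid, pd.NaT)
            if pd.notna(ev):
                if ev < start:
                    prevalent.append(pid)
                    continue
                candidates.append((ev, "outcome"))
        if pd.notna(death):
            candidates.append((death, "death"))
        if mode == "as-treated":
            change = treatment_change.get(pid, pd.NaT)
            if pd.notna(change) and change > start:
                candidates.append((change, "treatment-change"))
        reg_end = reg["registration_end"].get(pid, pd.NaT)
        if pd.notna(reg_end) and (pd.isna(death) or reg_end < death):
            candidates.append((reg_end, "transfer-out"))
        candidates.append((start + pd.Timedelta(days=FOLLOWUP_CAP_DAYS),
                           "5-years"))
        candidates.append((study_end, "end-of-study"))

        priority = {"outcome": 0, "death": 1, "treatment-change": 2,
                    "transfer-out": 3, "5-years": 4, "end-of-study": 5}
        end, reason = min(candidates, key=lambda c: (c[0], priority[c[1]]))
        if end <= start:
            continue  # zero-length interval (late-December discharges)
        rows.append({"pid": pid, "organ": person["organ"], "start": start,
                     "end": end, "end_reason": reason, "mode": mode})

    records = pd.DataFrame(rows, columns=["pid", "organ", "start", "end",
                                          "end_reason", "mode"])
    records.attrs["prevalent_excluded"] = prevalent
    return records


def person_years(records: pd.DataFrame) -> pd.DataFrame:
    """Person-years split by calendar year and organ (exact day counts).

    Returns a tidy frame (year, organ, person_years) whose total equals
    sum(end-start)/365.25 to floating precision; a cumulative column is
    added per organ for plotting the accrual series.
    """
    rows = []
    for _, r in records.iterrows():
        start, end = r["start"], r["end"]
        y = start.year
        while True:
            year_end = pd.Timestamp(f"{y + 1}-01-01")
            seg_end = min(end, year_end)
            days = (seg_end - max(start, pd.Timestamp(f"{y}-01-01"))).days
            if days > 0:
                rows.append({"year": y, "organ": r["organ"],
                             "days": days})
            if seg_end >= end:
                break
            y += 1
    if not rows:
        return pd.DataFrame(columns=["year", "organ", "person_years",
                                     "cumulative_py"])
    table = pd.DataFrame(rows).groupby(["year", "organ"], as_index=False)[
        "days"].sum()
    table["person_years"] = table["days"] / DAYS_PER_YEAR
    table = table.drop(columns="days").sort_values(["organ", "year"])
    table["cumulative_py"] = table.groupby("organ")["person_years"].cumsum()
    return table.reset_index(drop=True)


def total_person_years(records: pd.DataFrame) -> float:
    return float((records["end"] - records["start"]).dt.days.sum()
                 / DAYS_PER_YEAR)


@dataclass(frozen=True)
class IncidenceRateResult:
    outcome: str
    n_at_risk: int
    cases: int
    person_years: float
    rate_per_100py: float      # half-up, two decimals
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.cases > self.n_at_risk >= 0:
            raise ValueError("cases cannot exceed persons at risk")


def incidence_rate(cases: int, person_years_total: float,
                   outcome: str = "", n_at_risk: int | None = None
                   ) -> IncidenceRateResult:
    """Events per 100 person-years with an exact Poisson 95% CI."""
    if person_years_total <= 0:
        raise ValueError("person-years must be positive")
    rate = round_half_up(cases / person_years_total * 100.0, 2)
    low = 0.0 if cases == 0 else \
        stats.chi2.ppf(0.025, 2 * cases) / 2 / person_years_total * 100.0
    high = stats.chi2.ppf(0.975, 2 * (cases + 1)) / 2 / person_years_total * 100.0
    return IncidenceRateResult(
        outcome=outcome, n_at_risk=n_at_risk if n_at_risk is not None else cases,
        cases=int(cases), person_years=float(person_years_total),
        rate_per_100py=rate, ci_low=round_half_up(low, 2),
        ci_high=round_half_up(high, 2))


def estimate_incidence(records: pd.DataFrame, outcome: str,
                       event_reasons: tuple[str, ...] = ("outcome",)
                       ) -> IncidenceRateResult:
    """Rate from follow-up records: cases are records ending in the event."""
    if outcome == "death":
        event_reasons = tuple(set(event_reasons) | {"death"})
    cases = int(records["end_reason"].isin(event_reasons).sum())
    return incidence_rate(cases, total_person_years(records),
                          outcome=outcome, n_at_risk=len(records))


@dataclass
class SurvivalCurve:
    """Product-limit estimate: step coordinates plus risk-set bookkeeping."""

    table: pd.DataFrame  # time, at_risk, events, censored, survival

    def survival_at(self, t: float) -> float:
        past = self.table[self.table["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


def kaplan_meier(durations, events) -> SurvivalCurve:
    """Kaplan-Meier estimator over durations (days) and event indicators.

    At tied times events are processed before censorings: the risk set at
    an event time includes every subject censored at that same time.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("at least one record required")
    order = np.argsort(durations)
    durations, events = durations[order], events[order]

    rows = []
    surv = 1.0
    n = durations.size
    at_risk = n
    for t in np.unique(durations):
        here = durations == t
        d = int((here & events).sum())
        c = int((here & ~events).sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": int(at_risk), "events": d,
                     "censored": c, "survival": surv})
        at_risk -= d + c
    return SurvivalCurve(table=pd.DataFrame(rows))


def km_from_records(records: pd.DataFrame,
                    event_reasons: tuple[str, ...] = ("outcome", "death")
                    ) -> SurvivalCurve:
    durations = (records["end"] - records["start"]).dt.days
    events = records["end_reason"].isin(event_reasons)
    return kaplan_meier(durations.to_numpy(), events.to_numpy())
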