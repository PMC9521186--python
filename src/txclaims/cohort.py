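"""Incident-transplant cohort selection with an attrition report.

The index episode is a person's first transplant hospitalization whose
discharge falls in the enrolment window (2009-01-01 .. 2019-12-01);
episodes are scanned from 2007 so the two-year prior-transplant washout
can look back into pre-enrolment claims. Organ is determined from
ICD-9-CM procedure codes in the principal and all five secondary
positions: kidney 55.6x excluding 55.61, liver 50.5x, heart 37.5x, lung
33.5x, pancreas 52.8x. The intestine code is shipped as 46.97: source
material in this field sometimes prints "469.7", which is not a valid
ICD-9-CM procedure code; 46.97 is the intestinal-transplant procedure.

Eligibility (each step logged):
  1. index transplant discharge inside the enrolment window;
  2. single-organ index admission;
  3. no transplant hospitalization discharged in the 730 days before the
     index discharge (half-open [discharge-730d, admission));
  4. registered in the regional system and alive through day 30 after
     discharge (registration interval must cover [discharge, discharge+30]);
  5. no immunosuppressant (ATC L04) dispensing in the 180 days before
     discharge;
  6. at least one maintenance-dictionary dispensing (L04 or H02AB steroid)
     in the 30 days after discharge.

Step 6 accepts steroids as well as L04 agents: a steroid-only maintenance
regimen is a real (if minor) category and would otherwise be unobservable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cdm import AnalyticalDataset
from .dictionary import STEROID_ATCS
from .utils import share_percent

SCAN_START = pd.Timestamp("2007-01-01")
ENROL_START = pd.Timestamp("2009-01-01")
ENROL_END = pd.Timestamp("2019-12-01")
LANDMARK_DAYS = 30
PRIOR_TX_LOOKBACK_DAYS = 730
L04_LOOKBACK_DAYS = 180

# organ -> ICD-9-CM procedure prefix(es); kidney excludes 55.61 (rejected
# transplanted kidney), handled explicitly.
ORGAN_PROC_PREFIXES: dict[str, tuple[str, ...]] = {
    "kidney": ("55.6",),
    "liver": ("50.5",),
    "heart": ("37.5",),
    "lung": ("33.5",),
    "pancreas": ("52.8",),
    "intestine": ("46.97",),
}
KIDNEY_EXCLUDED_CODE = "55.61"

PROC_COLS = [f"proc_{i}" for i in range(1, 7)]


def organ_of_code(code: str) -> str | None:
    """Map one ICD-9-CM procedure code to a transplant organ, or None."""
    code = (code or "").strip()
    if not code:
        return None
    if code.startswith(KIDNEY_EXCLUDED_CODE):
        return None
    for organ, prefixes in ORGAN_PROC_PREFIXES.items():
        if any(code.startswith(p) for p in prefixes):
            return organ
    return None


def _transplant_admissions(hosp: pd.DataFrame) -> pd.DataFrame:
    """All hospitalization rows carrying >=1 transplant procedure, with the
    set of distinct organs found across the six procedure positions."""
    rows = []
    proc_values = hosp[PROC_COLS].fillna("").astype(str)
    for idx, procs in proc_values.iterrows():
        organs = sorted({o for o in (organ_of_code(c) for c in procs) if o})
        if organs:
            rows.append({"row": idx, "organs": organs})
    if not rows:
        return pd.DataFrame(columns=["pid", "region", "admission_date",
                                     "discharge_date", "hospital_code",
                                     "organ", "n_organs"])
    found = pd.DataFrame(rows).set_index("row")
    out = hosp.loc[found.index,
                   ["pid", "region", "admission_date", "discharge_date",
                    "hospital_code"]].copy()
    out["organ"] = [o[0] for o in found["organs"]]
    out["n_organs"] = [len(o) for o in found["organs"]]
    return out.reset_index(drop=True)


def find_index_episodes(dataset: AnalyticalDataset) -> pd.DataFrame:
    """One index transplant episode per person.

    The index is the first (by admission date) transplant hospitalization
    discharged in the enrolment window; persons whose transplants all fall
    in the 2007-2008 scan margin keep their first episode with
    in_window=False so attrition can count them.
    """
    tx = _transplant_admissions(dataset.hospitalizations)
    tx = tx[(tx["discharge_date"] >= SCAN_START)
            & (tx["discharge_date"] <= ENROL_END)]
    if tx.empty:
        tx["in_window"] = pd.Series(dtype=bool)
        return tx
    tx = tx.sort_values(["pid", "admission_date", "discharge_date"])
    tx["in_window"] = tx["discharge_date"] >= ENROL_START

    in_win_first = tx[tx["in_window"]].groupby("pid", as_index=False).first()
    rest = tx[~tx["pid"].isin(in_win_first["pid"])]
    out_win_first = rest.groupby("pid", as_index=False).first()
    episodes = pd.concat([in_win_first, out_win_first], ignore_index=True)
    return episodes.sort_values("pid").reset_index(drop=True)


@dataclass
class AttritionReport:
    """Ordered eligibility log: (step label, remaining, removed)."""

    initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def log(self, label: str, remaining: int) -> None:
        prev = self.steps[-1][1] if self.steps else self.initial
        removed = prev - remaining
        if removed < 0:
            raise ValueError("attrition must be non-increasing")
        self.steps.append((label, remaining, removed))

    @property
    def final(self) -> int:
        return self.steps[-1][1] if self.steps else self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "remaining", "removed"])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"initial": self.initial,
                              "steps": [list(s) for s in self.steps],
                              "final": self.final}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_text(self) -> str:
        lines = [f"{'step':<46}{'remaining':>10}{'removed':>9}",
                 f"{'discharged with a transplant procedure':<46}"
                 f"{self.initial:>10}{'':>9}"]
        for label, remaining, removed in self.steps:
            lines.append(f"{label:<46}{remaining:>10}{removed:>9}")
        return "\n".join(lines)


def attrition_proportion(report: AttritionReport) -> float:
    """Final cohort / initially discharged, as a one-decimal percentage."""
    if report.initial == 0:
        raise ValueError("proportion undefined: no discharged persons")
    return share_percent(report.final, report.initial)


def apply_eligibility(episodes: pd.DataFrame,
                      dataset: AnalyticalDataset
                      ) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply the six inclusion/exclusion steps; returns (cohort, attrition).

    The cohort frame keeps one row per eligible person (their index
    episode) with a follow-up anchor column `fup_start` at discharge+30.
    """
    report = AttritionReport(initial=len(episodes))
    cur = episodes.copy()

    cur = cur[cur["in_window"]]
    report.log("index discharge in enrolment window", len(cur))

    cur = cur[cur["n_organs"] == 1]
    report.log("single-organ transplant", len(cur))

    tx_all = _transplant_admissions(dataset.hospitalizations)
    merged = cur[["pid", "admission_date", "discharge_date"]].merge(
        tx_all[["pid", "discharge_date"]].rename(
            columns={"discharge_date": "other_discharge"}), on="pid")
    prior = merged[
        (merged["other_discharge"]
         >= merged["discharge_date"] - pd.Timedelta(days=PRIOR_TX_LOOKBACK_DAYS))
        & (merged["other_discharge"] < merged["admission_date"])]
    cur = cur[~cur["pid"].isin(prior["pid"])]
    report.log("no transplant in prior 2 years", len(cur))

    end30 = cur["discharge_date"] + pd.Timedelta(days=LANDMARK_DAYS)
    deaths = dataset.deaths.set_index("pid")["death_date"]
    death = cur["pid"].map(deaths)
    alive = death.isna() | (death.values >= end30.values)

    reg = dataset.registration.sort_values("registration_start") \
        .groupby("pid").last()
    reg_start = cur["pid"].map(reg["registration_start"])
    reg_end = cur["pid"].map(reg["registration_end"])
    registered = (reg_start.notna()
                  & (reg_start.values <= cur["discharge_date"].values)
                  & (reg_end.isna() | (reg_end.values >= end30.values)))
    cur = cur[alive.values & registered.values]
    report.log("registered and alive through day 30", len(cur))

    disp = dataset.dispensings
    l04 = disp[disp["atc_code"].astype(str).str.startswith("L04")]
    m = cur[["pid", "discharge_date"]].merge(
        l04[["pid", "dispensing_date"]], on="pid")
    washout_hit = m[
        (m["dispensing_date"]
         >= m["discharge_date"] - pd.Timedelta(days=L04_LOOKBACK_DAYS))
        & (m["dispensing_date"] < m["discharge_date"])]
    cur = cur[~cur["pid"].isin(washout_hit["pid"])]
    report.log("no L04 dispensing in prior 180 days", len(cur))

    maint = disp[disp["atc_code"].astype(str).str.startswith("L04")
                 | disp["atc_code"].isin(STEROID_ATCS)]
    m = cur[["pid", "discharge_date"]].merge(
        maint[["pid", "dispensing_date"]], on="pid")
    index_hit = m[
        (m["dispensing_date"] >= m["discharge_date"])
        & (m["dispensing_date"]
           < m["discharge_date"] + pd.Timedelta(days=LANDMARK_DAYS))]
    cur = cur[cur["pid"].isin(index_hit["pid"])]
    report.log("maintenance dispensing within 30 days", len(cur))

    cohort = cur.drop(columns=["in_window", "n_organs"]).reset_index(drop=True)
    cohort["fup_start"] = cohort["discharge_date"] + pd.Timedelta(
        days=LANDMARK_DAYS)
    return cohort, report


def build_cohort(dataset: AnalyticalDataset
                 ) -> tuple[pd.DataFrame, AttritionReport]:
    """Convenience: index episodes + eligibility in one call."""
    return apply_eligibility(find_index_episodes(dataset), dataset)
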