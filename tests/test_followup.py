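"""Follow-up intervals, person-years, incidence rates, Kaplan-Meier."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import txclaims as tx
from txclaims.followup import FOLLOWUP_CAP_DAYS, STUDY_END

D = pd.Timestamp


def _mini_dataset(pid="p1", death=None, reg_end=None, outcome_rows=()):
    deaths = pd.DataFrame(
        [{"pid": pid, "region": "ra", "death_date": D(death)}]
        if death else [], columns=["pid", "region", "death_date"])
    hosp_cols = (["pid", "region", "admission_date", "discharge_date",
                  "hospital_code"]
                 + [f"dx_{i}" for i in range(1, 7)]
                 + [f"proc_{i}" for i in range(1, 7)])
    rows = []
    for date, dx in outcome_rows:
        row = dict.fromkeys(hosp_cols, "")
        row.update({"pid": pid, "region": "ra", "admission_date": D(date),
                    "discharge_date": D(date) + pd.Timedelta(days=2),
                    "hospital_code": "H1", "dx_1": dx})
        rows.append(row)
    hosp = pd.DataFrame(rows, columns=hosp_cols)
    registration = pd.DataFrame([{
        "pid": pid, "region": "ra", "registration_start": D("2000-01-01"),
        "registration_end": D(reg_end) if reg_end else pd.NaT}])
    return tx.AnalyticalDataset(
        schema_version=1, regions=["ra"],
        persons=pd.DataFrame([{"pid": pid, "region": "ra", "sex": "M",
                               "birth_date": D("1970-01-01")}]),
        hospitalizations=hosp,
        dispensings=pd.DataFrame(columns=["pid", "region", "dispensing_date",
                                          "atc_code", "aic_code",
                                          "n_packages"]),
        deaths=deaths, registration=registration)


def _cohort(pid="p1", discharge="2012-01-01"):
    dis = D(discharge)
    return pd.DataFrame([{"pid": pid, "organ": "kidney",
                          "admission_date": dis - pd.Timedelta(days=10),
                          "discharge_date": dis, "hospital_code": "H1",
                          "region": "ra",
                          "fup_start": dis + pd.Timedelta(days=30)}])


def test_death_ends_followup():
    cohort = _cohort()
    ds = _mini_dataset(death="2013-02-05")   # day 400 after discharge
    rec = tx.build_followup(cohort, ds, mode="ITT")
    assert rec.iloc[0]["end_reason"] == "death"
    assert rec.iloc[0]["end"] == D("2013-02-05")


def test_as_treated_censors_at_treatment_change():
    cohort = _cohort()
    ds = _mini_dataset(death="2013-02-05")
    change = pd.Series({"p1": D("2012-07-19")})  # day 200
    rec = tx.build_followup(cohort, ds, mode="as-treated",
                            treatment_change=change)
    assert rec.iloc[0]["end_reason"] == "treatment-change"
    assert rec.iloc[0]["end"] == D("2012-07-19")
    with pytest.raises(ValueError, match="treatment-change"):
        tx.build_followup(cohort, ds, mode="as-treated")


def test_no_events_caps_at_five_years_or_study_end():
    rec = tx.build_followup(_cohort(), _mini_dataset(), mode="ITT")
    start = D("2012-01-31")
    assert rec.iloc[0]["end"] == start + pd.Timedelta(days=FOLLOWUP_CAP_DAYS)
    assert rec.iloc[0]["end_reason"] == "5-years"

    rec = tx.build_followup(_cohort(discharge="2018-06-01"),
                            _mini_dataset(), mode="ITT")
    assert rec.iloc[0]["end"] == STUDY_END
    assert rec.iloc[0]["end_reason"] == "end-of-study"


def test_outcome_specific_run_and_prevalent_exclusion():
    ds = _mini_dataset(outcome_rows=[("2013-06-01", "250.00")])
    rec = tx.build_followup(_cohort(), ds, mode="ITT", outcome="diabetes")
    assert rec.iloc[0]["end_reason"] == "outcome"
    assert rec.attrs["prevalent_excluded"] == []

    prevalent = _mini_dataset(outcome_rows=[("2011-06-01", "250.00")])
    rec = tx.build_followup(_cohort(), prevalent, mode="ITT",
                            outcome="diabetes")
    assert rec.empty
    assert rec.attrs["prevalent_excluded"] == ["p1"]


def test_transfer_out_uses_registration_end():
    ds = _mini_dataset(reg_end="2014-03-01")
    rec = tx.build_followup(_cohort(), ds, mode="ITT")
    assert rec.iloc[0]["end_reason"] == "transfer-out"


def test_person_years_arithmetic():
    rec = pd.DataFrame([{"pid": "p1", "organ": "kidney",
                         "start": D("2012-01-01"), "end": D("2016-01-01"),
                         "end_reason": "5-years", "mode": "ITT"}])
    # 1461 days including one leap year = exactly 4 Julian years
    assert tx.total_person_years(rec) == pytest.approx(4.0)
    table = tx.person_years(rec)
    assert table["person_years"].sum() == pytest.approx(4.0)
    assert set(table["year"]) == {2012, 2013, 2014, 2015}
    assert table["cumulative_py"].is_monotonic_increasing


def test_person_years_conserved_on_simulated_records(sim):
    rec = tx.build_followup(sim["cohort"], sim["pooled"], mode="ITT")
    table = tx.person_years(rec)
    brute = (rec["end"] - rec["start"]).dt.days.sum() / 365.25
    assert table["person_years"].sum() == pytest.approx(brute, abs=1e-9)


@pytest.mark.parametrize("cases,py,rate", [
    (269, 13720.5, 1.96),
    (42, 1452.8, 2.89),
    (67, 620.8, 10.79),
    (362, 6085.7, 5.95),
    (0, 100.0, 0.0),
])
def test_incidence_rate_worked_examples(cases, py, rate):
    result = tx.incidence_rate(cases, py)
    assert result.rate_per_100py == rate
    assert result.ci_low <= rate <= result.ci_high


def test_incidence_rate_rejects_nonpositive_person_years():
    with pytest.raises(ValueError):
        tx.incidence_rate(5, 0.0)


def test_poisson_ci_matches_chi2_inversion():
    from scipy.stats import chi2
    r = tx.incidence_rate(10, 100.0)
    assert r.ci_low == pytest.approx(chi2.ppf(0.025, 20) / 2, abs=0.005)
    assert r.ci_high == pytest.approx(chi2.ppf(0.975, 22) / 2, abs=0.005)


def test_km_no_events_is_flat():
    curve = tx.kaplan_meier([5, 10, 20], [False, False, False])
    assert (curve.table["survival"] == 1.0).all()
    assert curve.survival_at(15) == 1.0


def test_km_single_death_closed_form():
    curve = tx.kaplan_meier([1, 5, 6, 7], [True, False, False, False])
    assert curve.survival_at(1) == pytest.approx(0.75)


def test_km_equals_hand_computed_product_limit():
    """10-subject fixture: durations/events chosen so risk sets shrink by
    both deaths and censorings, with one tied time."""
    durations = [2, 3, 3, 5, 7, 7, 8, 10, 12, 12]
    events = [1, 1, 0, 1, 1, 1, 0, 1, 0, 0]
    # hand product-limit: t=2 d=1 n=10 -> 0.9; t=3 d=1 n=9 (censor same t
    # stays in risk set) -> 0.8; t=5 d=1 n=7 -> 0.685714...;
    # t=7 d=2 n=6 -> 0.457142...; t=10 d=1 n=3 -> 0.304762...
    expected = {2: 0.9, 3: 0.8, 5: 0.9 * (8 / 9) * (6 / 7),
                7: 0.9 * (8 / 9) * (6 / 7) * (4 / 6),
                10: 0.9 * (8 / 9) * (6 / 7) * (4 / 6) * (2 / 3)}
    curve = tx.kaplan_meier(durations, list(map(bool, events)))
    for t, s in expected.items():
        assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)


def test_km_agrees_with_lifelines(sim):
    from lifelines import KaplanMeierFitter
    rec = tx.build_followup(sim["cohort"], sim["pooled"], mode="ITT")
    curve = tx.km_from_records(rec)
    durations = (rec["end"] - rec["start"]).dt.days
    events = rec["end_reason"].isin(("outcome", "death"))
    kmf = KaplanMeierFitter().fit(durations, events)
    for t in (100, 500, 1000, 1500):
        assert curve.survival_at(t) == pytest.approx(
            float(kmf.predict(t)), abs=1e-10)


def test_itt_person_time_dominates_as_treated(sim, dictionary):
    cohort = sim["cohort"].head(80)
    disp = sim["pooled"].dispensings
    changes = {}
    for _, person in cohort.iterrows():
        d = disp[disp["pid"] == person["pid"]]
        events = tx.detect_switches(d, dictionary, person["fup_start"],
                                    horizon_days=FOLLOWUP_CAP_DAYS)
        if len(events):
            changes[person["pid"]] = events.iloc[0]["date"]
    itt = tx.build_followup(cohort, sim["pooled"], mode="ITT")
    at = tx.build_followup(cohort, sim["pooled"], mode="as-treated",
                           treatment_change=pd.Series(changes))
    merged = itt.merge(at, on="pid", suffixes=("_itt", "_at"))
    assert (merged["end_itt"] >= merged["end_at"]).all()
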