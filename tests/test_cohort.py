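"""Index-episode detection and eligibility against the planted truth."""

from __future__ import annotations

import pandas as pd
import pytest

import txclaims as tx
from txclaims.cohort import (
    ENROL_START,
    PROC_COLS,
    _transplant_admissions,
    find_index_episodes,
)

D = pd.Timestamp


def _dataset(hosp_rows, persons=None, dispensings=None, deaths=None,
             registration=None):
    """Hand-built minimal AnalyticalDataset for fixtures."""
    def hosp_row(pid, adm, dis, procs=(), hospital="RAH01"):
        row = {"pid": pid, "region": "ra", "admission_date": D(adm),
               "discharge_date": D(dis), "hospital_code": hospital,
               **{f"dx_{i}": "" for i in range(1, 7)},
               **{c: "" for c in PROC_COLS}}
        for pos, code in procs:
            row[f"proc_{pos}"] = code
        return row

    hosp = pd.DataFrame([hosp_row(*r[:3], procs=r[3]) for r in hosp_rows])
    pids = sorted(hosp["pid"].unique())
    persons = persons if persons is not None else pd.DataFrame(
        {"pid": pids, "region": "ra", "sex": "M",
         "birth_date": D("1970-06-15")})
    registration = registration if registration is not None else pd.DataFrame(
        {"pid": pids, "region": "ra", "registration_start": D("2000-01-01"),
         "registration_end": pd.NaT})
    dispensings = dispensings if dispensings is not None else pd.DataFrame(
        columns=["pid", "region", "dispensing_date", "atc_code", "aic_code",
                 "n_packages"])
    deaths = deaths if deaths is not None else pd.DataFrame(
        columns=["pid", "region", "death_date"])
    return tx.AnalyticalDataset(
        schema_version=1, regions=["ra"], persons=persons,
        hospitalizations=hosp, dispensings=dispensings, deaths=deaths,
        registration=registration)


@pytest.mark.parametrize("code,organ", [
    ("55.69", "kidney"), ("55.6", "kidney"), ("55.61", None),
    ("50.59", "liver"), ("37.51", "heart"), ("33.50", "lung"),
    ("52.80", "pancreas"), ("46.97", "intestine"), ("99.04", None),
    ("", None),
])
def test_organ_code_map(code, organ):
    assert tx.organ_of_code(code) == organ


def test_first_event_rule_picks_earliest_in_window():
    ds = _dataset([
        ("p1", "2010-03-01", "2010-03-20", [(1, "55.69")]),
        ("p1", "2011-04-01", "2011-04-15", [(1, "50.59")]),
    ])
    eps = find_index_episodes(ds)
    assert len(eps) == 1
    assert eps.iloc[0]["organ"] == "kidney"
    assert eps.iloc[0]["in_window"]


def test_excluded_kidney_code_yields_no_episode():
    ds = _dataset([("p1", "2010-03-01", "2010-03-20", [(1, "55.61")])])
    assert find_index_episodes(ds).empty


@pytest.mark.parametrize("position", range(1, 7))
def test_procedure_found_in_any_position(position):
    ds = _dataset([("p1", "2012-05-01", "2012-06-10",
                    [(position, "37.51")])])
    eps = find_index_episodes(ds)
    assert eps.iloc[0]["organ"] == "heart"


def test_pre_enrolment_episode_flagged():
    ds = _dataset([("p1", "2008-02-01", "2008-02-20", [(1, "55.69")])])
    eps = find_index_episodes(ds)
    assert len(eps) == 1
    assert not eps.iloc[0]["in_window"]


def test_eligibility_removes_exactly_planted_negatives(sim):
    """Set equality between the final cohort and the truth manifest's
    non-planted persons, plus per-step removal counts."""
    truth = sim["truth"]
    cohort, attrition = sim["cohort"], sim["attrition"]
    assert set(cohort["pid"]) == set(truth.eligible["pid"])

    counts = truth.planted_counts()
    removed = dict(zip([s[0] for s in attrition.steps],
                       [s[2] for s in attrition.steps]))
    assert removed["index discharge in enrolment window"] \
        == counts["out_of_window_index"]
    assert removed["single-organ transplant"] == counts["multi_organ"]
    assert removed["no transplant in prior 2 years"] \
        == counts["prior_transplant"]
    assert removed["registered and alive through day 30"] \
        == counts["early_death"] + counts["deregistered"]
    assert removed["no L04 dispensing in prior 180 days"] \
        == counts["prior_l04"]
    assert removed["maintenance dispensing within 30 days"] \
        == counts["no_index_dispensing"]


@pytest.mark.parametrize("seed", [1, 23, 404])
def test_attrition_monotone_on_random_bundles(seed, schema):
    cfg = tx.SimulationConfig(n_persons=150, seed=seed)
    bundles, _ = tx.generate_regional_claims(cfg)
    pooled = tx.pool_regions([tx.build_analytical_dataset(b, schema)
                              for b in bundles.values()])
    _, att = tx.build_cohort(pooled)
    remaining = [att.initial] + [s[1] for s in att.steps]
    assert all(a >= b for a, b in zip(remaining, remaining[1:]))
    for i, (_, rem, removed) in enumerate(att.steps):
        assert removed == remaining[i] - rem


def test_final_cohort_is_order_stable(sim):
    """The final membership equals episodes minus the union of per-rule
    violator sets computed independently, so any step permutation yields
    the same final set."""
    pooled = sim["pooled"]
    episodes = find_index_episodes(pooled)
    violators: set[str] = set()

    violators |= set(episodes.loc[~episodes["in_window"], "pid"])
    violators |= set(episodes.loc[episodes["n_organs"] > 1, "pid"])

    tx_all = _transplant_admissions(pooled.hospitalizations)
    deaths = pooled.deaths.set_index("pid")["death_date"]
    reg = pooled.registration.set_index("pid")
    disp = pooled.dispensings
    for _, ep in episodes.iterrows():
        pid, dis = ep["pid"], ep["discharge_date"]
        own_tx = tx_all[tx_all["pid"] == pid]
        if ((own_tx["discharge_date"] >= dis - pd.Timedelta(days=730))
                & (own_tx["discharge_date"] < ep["admission_date"])).any():
            violators.add(pid)
        death = deaths.get(pid, pd.NaT)
        if pd.notna(death) and death < dis + pd.Timedelta(days=30):
            violators.add(pid)
        r = reg.loc[pid]
        if not (r["registration_start"] <= dis
                and (pd.isna(r["registration_end"])
                     or r["registration_end"] >= dis + pd.Timedelta(days=30))):
            violators.add(pid)
        own = disp[disp["pid"] == pid]
        l04 = own[own["atc_code"].str.startswith("L04")]
        if ((l04["dispensing_date"] >= dis - pd.Timedelta(days=180))
                & (l04["dispensing_date"] < dis)).any():
            violators.add(pid)
        maint = own[own["atc_code"].str.startswith(("L04", "H02AB"))]
        if not ((maint["dispensing_date"] >= dis)
                & (maint["dispensing_date"]
                   < dis + pd.Timedelta(days=30))).any():
            violators.add(pid)

    expected = set(episodes["pid"]) - violators
    assert set(sim["cohort"]["pid"]) == expected


def test_attrition_proportion_helpers():
    report = tx.AttritionReport(initial=14765)
    report.log("inclusion", 7369)
    assert tx.attrition_proportion(report) == 49.9
    assert tx.share_percent(4029, 6914) == 58.3

    full = tx.AttritionReport(initial=100)
    full.log("inclusion", 100)
    assert tx.attrition_proportion(full) == 100.0

    empty = tx.AttritionReport(initial=0)
    with pytest.raises(ValueError):
        tx.attrition_proportion(empty)


def test_no_planted_negatives_means_no_removals(schema):
    cfg = tx.SimulationConfig(
        n_persons=40, seed=9,
        planted_negative_rates={})
    bundles, truth = tx.generate_regional_claims(cfg)
    pooled = tx.pool_regions([tx.build_analytical_dataset(b, schema)
                              for b in bundles.values()])
    cohort, att = tx.build_cohort(pooled)
    assert len(cohort) == 40
    assert all(s[2] == 0 for s in att.steps)
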