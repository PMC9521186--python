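"""Synthetic regional claims and national transplant-registry generator.

Emulates the seven administrative source tables of an Italian regional
claims system (hospital discharges with ICD-9-CM procedure/diagnosis
codes, ATC/AIC-coded drug dispensings, inhabitant registry, mortality
registry, emergency visits, co-payment exemptions, outpatient tests)
plus a national transplant registry carrying quasi-identifiers and
physician-reported maintenance therapy.

Every run is seeded and returns a TruthManifest with the ground truth
(organ, index regimen, outcome event dates, registry match id, planted
eligibility violations), so each downstream pipeline stage can be tested
exactly. Planted negatives are persons deliberately constructed to
violate exactly one cohort-eligibility rule; everyone else is eligible
by construction (deaths and outcomes are drawn from constant hazards
starting at the day-30 landmark, so they can never trip the
alive-through-day-30 rule by accident).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    PLANT_RULES,
    SimulationConfig,
    parse_regimen_label,
)
from .dictionary import DrugDictionary, default_dictionary

STUDY_END = pd.Timestamp("2019-12-31")
ENROL_START = pd.Timestamp("2009-01-01")
ENROL_END = pd.Timestamp("2019-12-01")
FOLLOWUP_CAP_DAYS = int(round(5 * 365.25))
LANDMARK_DAYS = 30

# Concrete procedure codes the generator writes, one per organ.
ORGAN_PROC_CODE = {
    "kidney": "55.69", "liver": "50.59", "heart": "37.51",
    "lung": "33.50", "pancreas": "52.80", "intestine": "46.97",
}

# Diagnosis codes used both for outcome events and prevalent comorbidity.
OUTCOME_DX_CODE = {
    "reject": "996.80", "infection": "038.9",
    "diabetes": "250.00", "cancer": "199.1",
}
COMORBIDITY_DX = {"hypertension": "401.9", "diabetes": "250.00",
                  "cancer": "199.1", "thyroid": "244.9"}
COMEDICATION_ATC = {"statin": "C10AA01", "antiplatelet": "B01AC06",
                    "anticoagulant": "B01AA03"}

MEAN_STAY_DAYS = {"kidney": 17, "liver": 25, "heart": 44, "lung": 36,
                  "pancreas": 20, "intestine": 20}

CLAIMS_TABLES = (
    "hospital_discharge", "drug_dispensing", "inhabitant_registry",
    "mortality_registry", "emergency_visits", "exemptions",
    "outpatient_tests",
)

OUTCOMES = ("death", "reject", "infection", "diabetes", "cancer")


@dataclass
class ClaimsBundle:
    """One region's seven administrative source tables."""

    region: str
    tables: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        missing = set(CLAIMS_TABLES) - set(self.tables)
        if missing:
            raise ValueError(f"bundle missing tables: {sorted(missing)}")

    def write(self, out_dir: str | Path, fmt: str = "csv") -> None:
        out = Path(out_dir) / self.region
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            if fmt == "csv":
                df.to_csv(out / f"{name}.csv", index=False)
            elif fmt == "parquet":
                df.to_parquet(out / f"{name}.parquet", index=False)
            else:
                raise ValueError(f"unknown format {fmt!r}")

    @classmethod
    def read(cls, in_dir: str | Path, region: str, fmt: str = "csv") -> "ClaimsBundle":
        src = Path(in_dir) / region
        date_cols = {
            "hospital_discharge": ["admission_date", "discharge_date"],
            "drug_dispensing": ["dispensing_date"],
            "inhabitant_registry": ["birth_date", "registration_start",
                                    "registration_end"],
            "mortality_registry": ["death_date"],
            "emergency_visits": ["admission_date", "discharge_date"],
            "exemptions": ["start_date"],
            "outpatient_tests": ["test_date"],
        }
        tables = {}
        for name in CLAIMS_TABLES:
            if fmt == "csv":
                df = pd.read_csv(src / f"{name}.csv",
                                 parse_dates=date_cols.get(name, []))
            else:
                df = pd.read_parquet(src / f"{name}.parquet")
            tables[name] = df
        return cls(region=region, tables=tables)


@dataclass
class TruthManifest:
    """Ground truth, one row per generated transplant recipient."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["pid"].duplicated().any():
            raise ValueError("truth manifest must have one row per recipient")

    @property
    def eligible(self) -> pd.DataFrame:
        return self.table[self.table["planted_rule"] == ""]

    def planted_counts(self) -> dict[str, int]:
        counts = self.table["planted_rule"].value_counts().to_dict()
        counts.pop("", None)
        return {r: int(counts.get(r, 0)) for r in PLANT_RULES}

    def write(self, path: str | Path) -> None:
        records = self.table.copy()
        for col in records.columns:
            if pd.api.types.is_datetime64_any_dtype(records[col]):
                records[col] = records[col].dt.strftime("%Y-%m-%d")
        Path(path).write_text(json.dumps(
            records.where(records.notna(), None).to_dict(orient="records"),
            indent=1))


@dataclass
class SITRegistry:
    """National transplant-registry analogue with a perturbation log.

    `table` is what the linkage sees; `perturbed_field` (registry_id ->
    corrupted quasi-identifier field name) is simulation metadata only.
    """

    table: pd.DataFrame
    perturbed_field: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _regimen_drug_set(label: str, person: dict,
                      rng: np.random.Generator, cfg: SimulationConfig) -> list[str]:
    """Agents dispensed in the index window for a truth regimen label."""
    backbone, companion, steroid = parse_regimen_label(label)
    agents: list[str] = []
    if backbone in ("TAC", "CsA"):
        agents.append(backbone)
    if companion == "antimet":
        agents.append(person["antimet_agent"])
    elif companion == "mTOR":
        agents.append(person["mtor_agent"])
    elif companion == "other":
        if backbone == "NoCNI" and steroid:
            pass  # steroid-only regimen ("mainly steroid-based")
        else:
            agents.extend([person["antimet_agent"], person["mtor_agent"]])
    if steroid:
        agents.append(person["steroid_agent"])
    if not agents:
        raise ValueError(f"regimen label {label} yields no dispensable agent")
    return agents


def _person_core(i: int, rng: np.random.Generator, cfg: SimulationConfig,
                 rule: str) -> dict:
    """Demographics, index admission, and regimen assignment for one person."""
    region = cfg.region_ids[int(rng.integers(len(cfg.region_ids)))]
    organ = _draw_categorical(rng, cfg.organ_mix)
    sex = "M" if rng.random() < 0.68 else "F"

    if rule == "out_of_window_index":
        admission = pd.Timestamp("2007-01-15") + pd.Timedelta(
            days=int(rng.integers(0, 650)))
    elif rule == "prior_transplant":
        admission = pd.Timestamp("2009-01-10") + pd.Timedelta(
            days=int(rng.integers(0, 120)))
    else:
        span = (ENROL_END - ENROL_START).days - 60
        admission = ENROL_START + pd.Timedelta(days=int(rng.integers(0, span)))
    stay = max(1, int(rng.normal(MEAN_STAY_DAYS[organ], 6)))
    discharge = admission + pd.Timedelta(days=stay)
    if discharge > ENROL_END and rule != "out_of_window_index":
        discharge = ENROL_END
        admission = discharge - pd.Timedelta(days=stay)

    age = float(np.clip(rng.normal(50, 15), 1, 80))
    birth = admission - pd.Timedelta(days=int(age * 365.25))

    label = _draw_categorical(rng, cfg.regimen_mixture[organ])
    mmf = rng.random() < cfg.mmf_share[organ]
    hospital = f"{region[:2].upper()}H{int(rng.integers(1, cfg.hospitals_per_region + 1)):02d}"
    adherence = 1.0 if cfg.adherence_mean >= 1.0 else float(rng.beta(
        cfg.adherence_mean * cfg.adherence_concentration,
        (1 - cfg.adherence_mean) * cfg.adherence_concentration))
    return {
        "person_id": f"P{i:06d}", "region": region, "sex": sex,
        "organ": organ, "birth_date": birth, "admission_date": admission,
        "discharge_date": discharge, "hospital": hospital,
        "regimen_label": label,
        "antimet_agent": "MMF" if mmf else "AZA",
        "mtor_agent": "EVE" if rng.random() < 0.7 else "SIR",
        "steroid_agent": ["prednisone", "methylprednisolone", "prednisolone"][
            int(rng.choice(3, p=[0.8, 0.1, 0.1]))],
        "tac_formulation": "IR" if rng.random() < cfg.tac_ir_share[organ] else "ER",
        "adherence": adherence, "planted_rule": rule,
    }


def _event_dates(person: dict, rng: np.random.Generator,
                 cfg: SimulationConfig) -> dict[str, pd.Timestamp]:
    """Exponential waiting times from the day-30 landmark, unbounded."""
    fup_start = person["discharge_date"] + pd.Timedelta(days=LANDMARK_DAYS)
    out: dict[str, pd.Timestamp] = {}
    for outcome in OUTCOMES:
        lam = cfg.outcome_hazards[person["organ"]].get(outcome, 0.0)
        if lam <= 0:
            out[outcome] = pd.NaT
            continue
        years = rng.exponential(1.0 / lam)
        days = min(int(round(years * 365.25)) + 1, 36500)  # beyond any horizon
        out[outcome] = fup_start + pd.Timedelta(days=days)
    if person["planted_rule"] == "early_death":
        out["death"] = person["discharge_date"] + pd.Timedelta(
            days=int(rng.integers(2, LANDMARK_DAYS)))
    return out


def _dispensing_rows(person: dict, events: dict, rng: np.random.Generator,
                     cfg: SimulationConfig, dictionary: DrugDictionary) -> list[dict]:
    """Index-window dispensings plus 30-day refills thinned by adherence."""
    discharge = person["discharge_date"]
    rule = person["planted_rule"]
    supply_end = discharge + pd.Timedelta(days=LANDMARK_DAYS + FOLLOWUP_CAP_DAYS)
    if pd.notna(events["death"]):
        supply_end = min(supply_end, events["death"])
    supply_end = min(supply_end, STUDY_END)

    agents = _regimen_drug_set(person["regimen_label"], person, rng, cfg)
    # Per-person generic preference, applied once the generic is marketed.
    prefers_generic = {a: rng.random() < cfg.generic_uptake.get(a, 0.0)
                       for a in ("TAC", "CsA", "MMF", "AZA")}
    backbone = parse_regimen_label(person["regimen_label"])[0]
    switch_date = pd.NaT
    switch_to = ""
    if backbone in ("TAC", "CsA") and rng.random() < cfg.switch_rate:
        switch_date = discharge + pd.Timedelta(days=int(rng.integers(60, 400)))
        switch_to = "CsA" if backbone == "TAC" else "TAC"
    person["switch_date"] = switch_date
    person["switch_to"] = switch_to

    rows: list[dict] = []

    def emit(agent: str, date: pd.Timestamp) -> None:
        eff_agent = agent
        if agent in ("TAC", "CsA") and pd.notna(switch_date) and date >= switch_date:
            eff_agent = switch_to
        generic = (prefers_generic.get(eff_agent, False)
                   and date >= dictionary.first_generic_date(eff_agent))
        form = person["tac_formulation"] if eff_agent == "TAC" else None
        aic = dictionary.aic_for(eff_agent, "generic" if generic else "brand", form)
        product = dictionary.lookup(aic)
        rows.append({"person_id": person["person_id"],
                     "dispensing_date": date, "atc_code": product["atc"],
                     "aic_code": aic, "n_packages": 1,
                     "cost_euro": round(float(rng.uniform(20, 400)), 2)})

    first_offset = (int(rng.integers(35, 61)) if rule == "no_index_dispensing"
                    else int(rng.integers(0, 2)) if rule == "early_death"
                    else int(rng.integers(0, 26)))
    for agent in agents:
        first = discharge + pd.Timedelta(days=first_offset + int(rng.integers(0, 3)))
        date = first
        k = 0
        while date <= supply_end:
            if k == 0 or rng.random() < person["adherence"]:
                emit(agent, date)
            k += 1
            date = first + pd.Timedelta(days=30 * k)

    if rule == "prior_l04":
        aic = dictionary.aic_for("TAC", "brand", person["tac_formulation"])
        rows.append({"person_id": person["person_id"],
                     "dispensing_date": discharge - pd.Timedelta(
                         days=int(rng.integers(30, 171))),
                     "atc_code": "L04AD02", "aic_code": aic,
                     "n_packages": 1, "cost_euro": 150.0})

    # Pre-transplant comedications feed the baseline table; they are not
    # maintenance-dictionary drugs and never disturb classification.
    for name, atc in COMEDICATION_ATC.items():
        if rng.random() < 0.15:
            rows.append({"person_id": person["person_id"],
                         "dispensing_date": person["admission_date"]
                         - pd.Timedelta(days=int(rng.integers(30, 700))),
                         "atc_code": atc,
                         "aic_code": f"X{zlib.crc32(atc.encode()) % 10**8:08d}",
                         "n_packages": 1, "cost_euro": 10.0})
    return rows


def _hospitalization_rows(person: dict, events: dict,
                          rng: np.random.Generator) -> list[dict]:
    organ_code = ORGAN_PROC_CODE[person["organ"]]
    procs = [""] * 6
    procs[int(rng.integers(0, 6))] = organ_code
    if person["planted_rule"] == "multi_organ":
        other = rng.choice([c for o, c in sorted(ORGAN_PROC_CODE.items())
                            if o != person["organ"]])
        free = [j for j, p in enumerate(procs) if not p]
        procs[int(rng.choice(free))] = str(other)
    dxs = [""] * 6
    dxs[0] = "V42.0"
    base = {"hospital_code": person["hospital"],
            "drg_code": f"DRG{int(rng.integers(100, 600))}"}
    rows = [{"person_id": person["person_id"],
             "admission_date": person["admission_date"],
             "discharge_date": person["discharge_date"],
             **base,
             **{f"dx_{j+1}": dxs[j] for j in range(6)},
             **{f"proc_{j+1}": procs[j] for j in range(6)}}]

    if person["planted_rule"] == "prior_transplant":
        prior_disc = person["discharge_date"] - pd.Timedelta(
            days=int(rng.integers(120, 700)))
        # keep the prior transplant pre-enrolment but inside the washout
        prior_disc = min(prior_disc, pd.Timestamp("2008-12-15"))
        prior_disc = max(prior_disc, pd.Timestamp("2007-02-01"),
                         person["discharge_date"] - pd.Timedelta(days=725))
        prior_adm = prior_disc - pd.Timedelta(days=10)
        pprocs = [""] * 6
        pprocs[0] = organ_code
        rows.append({"person_id": person["person_id"],
                     "admission_date": prior_adm, "discharge_date": prior_disc,
                     **base,
                     **{f"dx_{j+1}": "" for j in range(6)},
                     **{f"proc_{j+1}": pprocs[j] for j in range(6)}})

    # Prevalent comorbidity admissions (pre-transplant), for the baseline table.
    for name, dx in COMORBIDITY_DX.items():
        if rng.random() < 0.12:
            adm = person["admission_date"] - pd.Timedelta(
                days=int(rng.integers(60, 730)))
            rows.append({"person_id": person["person_id"],
                         "admission_date": adm,
                         "discharge_date": adm + pd.Timedelta(days=3),
                         **base,
                         **{f"dx_{j+1}": dx if j == 0 else "" for j in range(6)},
                         **{f"proc_{j+1}": "" for j in range(6)}})

    # Post-landmark outcome events appear as hospitalizations.
    for outcome, dx in OUTCOME_DX_CODE.items():
        date = events.get(outcome)
        if pd.notna(date) and date <= STUDY_END and (
                pd.isna(events["death"]) or date <= events["death"]):
            rows.append({"person_id": person["person_id"],
                         "admission_date": date,
                         "discharge_date": min(date + pd.Timedelta(days=3),
                                               STUDY_END),
                         **base,
                         **{f"dx_{j+1}": dx if j == 0 else "" for j in range(6)},
                         **{f"proc_{j+1}": "" for j in range(6)}})
    return rows


def generate_regional_claims(
    config: SimulationConfig,
    dictionary: DrugDictionary | None = None,
) -> tuple[dict[str, ClaimsBundle], TruthManifest]:
    """Generate per-region claims bundles and the ground-truth manifest.

    Returns a dict region -> ClaimsBundle plus a TruthManifest with one
    row per recipient (person ids are unique across regions; the `pid`
    column carries the region-namespaced id used after pooling).
    """
    rng = np.random.default_rng(config.seed)
    dictionary = dictionary or default_dictionary()

    rules = [r for r in PLANT_RULES if config.planted_negative_rates.get(r, 0) > 0]
    rates = np.array([config.planted_negative_rates[r] for r in rules])

    truth_rows: list[dict] = []
    hosp_rows: list[dict] = []
    disp_rows: list[dict] = []
    inhab_rows: list[dict] = []
    mort_rows: list[dict] = []

    for i in range(config.n_persons):
        u = rng.random()
        rule = ""
        acc = 0.0
        for r, p in zip(rules, rates):
            acc += p
            if u < acc:
                rule = r
                break
        person = _person_core(i, rng, config, rule)
        events = _event_dates(person, rng, config)
        disp_rows.extend(_dispensing_rows(person, events, rng, config, dictionary))
        hosp_rows.extend(_hospitalization_rows(person, events, rng))

        reg_start = min(person["birth_date"], pd.Timestamp("2005-01-01"))
        if rule == "deregistered":
            reg_end = person["discharge_date"] + pd.Timedelta(
                days=int(rng.integers(5, 26)))
        elif pd.notna(events["death"]):
            reg_end = events["death"]
        else:
            reg_end = pd.NaT
        inhab_rows.append({"person_id": person["person_id"],
                           "sex": person["sex"],
                           "birth_date": person["birth_date"],
                           "registration_start": reg_start,
                           "registration_end": reg_end,
                           "region": person["region"]})
        if pd.notna(events["death"]) and events["death"] <= STUDY_END:
            mort_rows.append({"person_id": person["person_id"],
                              "death_date": events["death"],
                              "cause_code": "428.0",
                              "region": person["region"]})

        truth_rows.append({
            **{k: person[k] for k in (
                "person_id", "region", "sex", "birth_date", "organ",
                "admission_date", "discharge_date", "hospital",
                "regimen_label", "antimet_agent", "mtor_agent",
                "steroid_agent", "tac_formulation", "adherence",
                "planted_rule", "switch_to")},
            "pid": f"{person['region']}::{person['person_id']}",
            "switch_date": person["switch_date"],
            **{f"{o}_date": events[o] for o in OUTCOMES},
        })

    truth = pd.DataFrame(truth_rows)
    truth["registry_id"] = [f"SIT{i:06d}" for i in range(len(truth))]

    hosp = pd.DataFrame(hosp_rows)
    disp = pd.DataFrame(disp_rows)
    inhab = pd.DataFrame(inhab_rows)
    mort = pd.DataFrame(mort_rows, columns=["person_id", "death_date",
                                            "cause_code", "region"])
    hosp = hosp.merge(inhab[["person_id", "region"]], on="person_id")
    disp = disp.merge(inhab[["person_id", "region"]], on="person_id")

    bundles: dict[str, ClaimsBundle] = {}
    for region in config.region_ids:
        persons = inhab[inhab["region"] == region]
        person_ids = persons["person_id"]
        seeded = np.random.default_rng(
            [config.seed, zlib.crc32(region.encode()) % 2**31])
        n_aux = max(1, len(persons) // 20)
        aux_ids = (persons["person_id"].sample(
            n=n_aux, random_state=int(seeded.integers(2**31))).tolist()
            if len(persons) else [])
        emergency = pd.DataFrame([
            {"person_id": pid,
             "admission_date": pd.Timestamp("2015-06-01"),
             "discharge_date": pd.Timestamp("2015-06-02"),
             "reason_code": "780.2"} for pid in aux_ids])
        exemptions = pd.DataFrame([
            {"person_id": pid, "exemption_code": "052",
             "start_date": pd.Timestamp("2012-01-01")} for pid in aux_ids])
        outpatient = pd.DataFrame([
            {"person_id": pid, "test_date": pd.Timestamp("2014-03-01"),
             "test_code": "90.27.1", "lab_code": "LAB01"} for pid in aux_ids])
        for df in (emergency, exemptions, outpatient):
            if df.empty:
                df["person_id"] = pd.Series(dtype=object)

        def cut(df: pd.DataFrame) -> pd.DataFrame:
            out = df[df["person_id"].isin(person_ids)].drop(
                columns=["region"], errors="ignore")
            return out.sort_values(list(out.columns[:2])).reset_index(drop=True)

        bundles[region] = ClaimsBundle(region=region, tables={
            "hospital_discharge": cut(hosp),
            "drug_dispensing": cut(disp),
            "inhabitant_registry": cut(inhab),
            "mortality_registry": cut(mort),
            "emergency_visits": emergency if not emergency.empty else
            pd.DataFrame(columns=["person_id", "admission_date",
                                  "discharge_date", "reason_code"]),
            "exemptions": exemptions if not exemptions.empty else
            pd.DataFrame(columns=["person_id", "exemption_code", "start_date"]),
            "outpatient_tests": outpatient if not outpatient.empty else
            pd.DataFrame(columns=["person_id", "test_date", "test_code",
                                  "lab_code"]),
        })

    return bundles, TruthManifest(table=truth)


KEY_FIELDS = ("sex", "organ", "birth_ym", "transplant_ym", "hospital")


def generate_sit_registry(truth: TruthManifest,
                          config: SimulationConfig) -> SITRegistry:
    """Build the national registry: quasi-identifiers, donor attributes,
    physician-reported therapy, and key perturbation.

    With probability `key_perturbation_rate` exactly one quasi-identifier
    field of a row is corrupted; with probability `sit_disagreement_rate`
    the reported therapy differs from the dispensing truth.
    """
    if truth.table.empty:
        raise ValueError("truth manifest is empty")
    rng = np.random.default_rng([config.seed, 7919])

    t = truth.table
    rows = []
    perturbed: dict[str, str] = {}
    hospitals = sorted(t["hospital"].unique())
    organs = sorted(t["organ"].unique())
    for _, p in t.iterrows():
        row = {
            "registry_id": p["registry_id"],
            "sex": p["sex"],
            "organ": p["organ"],
            "birth_ym": p["birth_date"].strftime("%Y-%m"),
            "transplant_ym": p["admission_date"].strftime("%Y-%m"),
            "hospital": p["hospital"],
            "donor_age": int(rng.integers(10, 75)),
            "donor_sex": "M" if rng.random() < 0.55 else "F",
            "donor_type": "living" if (p["organ"] == "kidney"
                                       and rng.random() < 0.108) else "deceased",
            "reported_therapy": p["regimen_label"],
        }
        if rng.random() < config.sit_disagreement_rate:
            mix = dict(config.regimen_mixture[p["organ"]])
            mix.pop(p["regimen_label"], None)
            if mix:
                row["reported_therapy"] = _draw_categorical(rng, mix)
        if rng.random() < config.key_perturbation_rate:
            fld = KEY_FIELDS[int(rng.integers(len(KEY_FIELDS)))]
            perturbed[p["registry_id"]] = fld
            if fld == "sex":
                row["sex"] = "F" if row["sex"] == "M" else "M"
            elif fld == "organ":
                others = [o for o in organs if o != row["organ"]] or ["pancreas"]
                row["organ"] = others[int(rng.integers(len(others)))]
            elif fld in ("birth_ym", "transplant_ym"):
                ts = pd.Timestamp(row[fld] + "-01")
                shift = 1 if rng.random() < 0.5 else -1
                row[fld] = (ts + pd.DateOffset(months=shift)).strftime("%Y-%m")
            else:
                others = [h for h in hospitals if h != row["hospital"]]
                row[fld] = (others[int(rng.integers(len(others)))]
                            if others else row["hospital"] + "X")
        rows.append(row)

    table = pd.DataFrame(rows).sample(frac=1.0, random_state=int(
        rng.integers(2**31))).reset_index(drop=True)
    return SITRegistry(table=table,
                       perturbed_field=pd.Series(perturbed, dtype=object))
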