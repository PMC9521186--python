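"""Descriptive study outputs: regimen share tables, agent splits,
claims-vs-registry concordance, the median odds ratio, and a baseline
characteristics table.

All printed percentages are half-up rounded to one decimal; the table
builders are pure functions of their inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import cohen_kappa_score

from .cdm import AnalyticalDataset
from .utils import round_half_up, share_percent

COMPANION_ORDER = ("mono", "+antimet", "+mTOR", "other")
BACKBONE_ORDER = ("TAC-based", "CsA-based", "No-CNI")

COMORBIDITY_DX_PREFIXES = {
    "cancer": ("140", "199", "196"),
    "diabetes": ("250",),
    "thyroid_disease": ("244",),
    "hypertension": ("401", "402", "403", "404", "405"),
    "infections": ("038",),
}
COMEDICATION_ATC_PREFIXES = {
    "anticoagulants": ("B01AA",),
    "antiplatelet": ("B01AC",),
    "statins": ("C10AA",),
}
LOOKBACK_DAYS = 730


def regimen_share_table(classifications: pd.DataFrame) -> pd.DataFrame:
    """Organ x regimen cell counts with column percentages and steroid co-use.

    One row per (organ, backbone, companion) cell plus backbone subtotal
    rows (companion='all') and an organ total row; percentages are of the
    organ cohort size.
    """
    rows = []
    for organ, grp in classifications.groupby("organ"):
        total = len(grp)
        for backbone in BACKBONE_ORDER:
            bgrp = grp[grp["backbone"] == backbone]
            if bgrp.empty:
                continue
            rows.append({"organ": organ, "backbone": backbone,
                         "companion": "all", "n": len(bgrp),
                         "percent": share_percent(len(bgrp), total),
                         "with_steroids": int(bgrp["steroid"].sum())})
            for companion in COMPANION_ORDER:
                cgrp = bgrp[bgrp["companion"] == companion]
                if cgrp.empty:
                    continue
                rows.append({"organ": organ, "backbone": backbone,
                             "companion": companion, "n": len(cgrp),
                             "percent": share_percent(len(cgrp), total),
                             "with_steroids": int(cgrp["steroid"].sum())})
        rows.append({"organ": organ, "backbone": "Total", "companion": "",
                     "n": total, "percent": 100.0,
                     "with_steroids": int(grp["steroid"].sum())})
    return pd.DataFrame(rows)


def agent_split_shares(classifications: pd.DataFrame) -> pd.DataFrame:
    """Per-organ shares with figure-specific denominators: MMF vs AZA among
    antimetabolite users, IR vs ER among tacrolimus users, brand vs
    generic per agent among generic-era enrollees who received the agent."""
    rows = []
    for organ, grp in classifications.groupby("organ"):
        antimet = grp[grp["antimet_agent"] != "none"]
        if len(antimet):
            for agent in ("MMF", "AZA"):
                n = int((antimet["antimet_agent"] == agent).sum())
                rows.append({"organ": organ, "measure": "antimet_agent",
                             "category": agent, "n": n,
                             "denominator": len(antimet),
                             "percent": share_percent(n, len(antimet))})
        tac = grp[grp["backbone"] == "TAC-based"]
        if len(tac):
            for form in ("IR", "ER", "mixed"):
                n = int((tac["tac_formulation"] == form).sum())
                rows.append({"organ": organ, "measure": "tac_formulation",
                             "category": form, "n": n,
                             "denominator": len(tac),
                             "percent": share_percent(n, len(tac))})
        for agent in ("TAC", "CsA", "MMF"):
            col = f"brand_{agent}"
            if col not in grp.columns:
                continue
            evaluable = grp[~grp[col].isin(("not-evaluable", "n/a"))]
            if evaluable.empty:
                continue
            for status in ("brand", "generic", "mixed"):
                n = int((evaluable[col] == status).sum())
                rows.append({"organ": organ, "measure": f"brand_status_{agent}",
                             "category": status, "n": n,
                             "denominator": len(evaluable),
                             "percent": share_percent(n, len(evaluable))})
    return pd.DataFrame(rows)


@dataclass
class ConcordanceReport:
    n: int
    agreement: float
    kappa: float
    degenerate: bool               # fewer than 2 categories on a margin
    per_cell: pd.DataFrame         # label, n, agreement

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "n": self.n, "agreement": self.agreement, "kappa": self.kappa,
            "degenerate": self.degenerate,
            "per_cell": self.per_cell.to_dict(orient="records")}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def concordance(pairs: pd.DataFrame, level: str = "full") -> ConcordanceReport:
    """Agreement between claims-derived and registry-reported regimens.

    `pairs` holds one row per linked person with columns `claims_label`
    and `registry_label` (canonical 'backbone|companion|steroid' labels).
    level='backbone-companion' drops the steroid flag before comparing.
    Cohen's kappa is the chance-corrected coefficient; when either margin
    has a single category kappa is undefined and reported as 1.0 with the
    degenerate flag set.
    """
    if pairs.empty:
        raise ValueError("concordance needs at least one linked pair")
    a = pairs["claims_label"].astype(str)
    b = pairs["registry_label"].astype(str)
    if level == "backbone-companion":
        a = a.str.rsplit("|", n=1).str[0]
        b = b.str.rsplit("|", n=1).str[0]
    elif level != "full":
        raise ValueError(f"unknown concordance level: {level}")

    agree = a == b
    agreement = float(agree.mean())
    degenerate = a.nunique() < 2 or b.nunique() < 2
    if degenerate:
        kappa = 1.0 if agreement == 1.0 else 0.0
    else:
        kappa = float(cohen_kappa_score(a, b))

    per_cell = pd.DataFrame({"label": a, "agree": agree}) \
        .groupby("label").agg(n=("agree", "size"), agreement=("agree", "mean")) \
        .reset_index()
    return ConcordanceReport(n=len(pairs), agreement=agreement, kappa=kappa,
                             degenerate=degenerate, per_cell=per_cell)


def median_odds_ratio(cluster_variance: float) -> float:
    """Median odds ratio for a cluster-level (e.g. between-hospital) random
    effect: MOR = exp(sqrt(2*sigma^2) * z_0.75). The variance comes from a
    mixed-effects model fitted elsewhere; sigma^2=0 means no heterogeneity
    (MOR=1)."""
    if cluster_variance < 0:
        raise ValueError("cluster variance must be non-negative")
    return float(np.exp(np.sqrt(2.0 * cluster_variance) * norm.ppf(0.75)))


def load_charlson_codes() -> pd.DataFrame:
    text = (resources.files("txclaims") / "data" / "charlson_codes.csv")
    with resources.as_file(text) as p:
        return pd.read_csv(p, dtype={"icd9_prefix": str})


def _dx_lookback(cohort: pd.DataFrame, dataset: AnalyticalDataset
                 ) -> pd.DataFrame:
    """Diagnosis rows in the 2-year pre-admission window, one row per
    (pid, dx code)."""
    hosp = dataset.hospitalizations.merge(
        cohort[["pid", "admission_date"]].rename(
            columns={"admission_date": "index_admission"}), on="pid")
    hosp = hosp[(hosp["admission_date"] < hosp["index_admission"])
                & (hosp["admission_date"] >= hosp["index_admission"]
                   - pd.Timedelta(days=LOOKBACK_DAYS))]
    dx_cols = [f"dx_{i}" for i in range(1, 7)]
    melted = hosp.melt(id_vars=["pid"], value_vars=dx_cols, value_name="dx")
    melted["dx"] = melted["dx"].fillna("").astype(str)
    return melted[melted["dx"] != ""][["pid", "dx"]]


def baseline_table(cohort: pd.DataFrame, dataset: AnalyticalDataset,
                   registry_pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Demographic/clinical summary by organ (a compact analogue of a
    study baseline table): cohort share, sex, age bands, stay length,
    code-list comorbidity/comedication flags, Charlson bands, and donor
    attributes for linked persons when registry pairs are supplied."""
    total = len(cohort)
    persons = dataset.persons.set_index("pid")
    merged = cohort.merge(persons, left_on="pid", right_index=True)
    merged["age"] = ((merged["admission_date"] - merged["birth_date"])
                     .dt.days / 365.25)
    merged["stay"] = (merged["discharge_date"]
                      - merged["admission_date"]).dt.days

    dx = _dx_lookback(cohort, dataset)
    disp = dataset.dispensings.merge(
        cohort[["pid", "admission_date"]], on="pid")
    disp = disp[(disp["dispensing_date"] < disp["admission_date"])
                & (disp["dispensing_date"] >= disp["admission_date"]
                   - pd.Timedelta(days=LOOKBACK_DAYS))]
    charlson = load_charlson_codes()

    rows = []
    for organ, grp in merged.groupby("organ"):
        n = len(grp)
        pids = set(grp["pid"])

        def add(stat: str, value, count=None):
            rows.append({"organ": organ, "statistic": stat, "value": value,
                         "n": count})

        add("n", n)
        add("share_of_cohort_percent", share_percent(n, total))
        add("male_percent", share_percent(int((grp["sex"] == "M").sum()), n))
        for label, lo, hi in (("age_lt18", 0, 18), ("age_18_64", 18, 65),
                              ("age_65plus", 65, 200)):
            k = int(((grp["age"] >= lo) & (grp["age"] < hi)).sum())
            add(f"{label}_percent", share_percent(k, n), k)
        add("mean_age_years", round_half_up(float(grp["age"].mean()), 1))
        add("mean_stay_days", round_half_up(float(grp["stay"].mean()), 1))

        odx = dx[dx["pid"].isin(pids)]
        for name, prefixes in COMORBIDITY_DX_PREFIXES.items():
            k = odx[odx["dx"].str.startswith(prefixes)]["pid"].nunique()
            add(f"{name}_percent", share_percent(k, n), k)
        odisp = disp[disp["pid"].isin(pids)]
        for name, prefixes in COMEDICATION_ATC_PREFIXES.items():
            k = odisp[odisp["atc_code"].astype(str).str.startswith(prefixes)][
                "pid"].nunique()
            add(f"{name}_percent", share_percent(k, n), k)

        scores = {}
        for _, cond in charlson.iterrows():
            hit = odx[odx["dx"].str.startswith(cond["icd9_prefix"])]
            for pid in hit["pid"].unique():
                scores[pid] = scores.get(pid, 0) + int(cond["weight"])
        score_s = pd.Series({pid: scores.get(pid, 0) for pid in pids})
        add("charlson_0_1_percent",
            share_percent(int((score_s <= 1).sum()), n))
        add("charlson_2_percent", share_percent(int((score_s == 2).sum()), n))
        add("charlson_3plus_percent",
            share_percent(int((score_s >= 3).sum()), n))

        if registry_pairs is not None and not registry_pairs.empty:
            linked = registry_pairs[registry_pairs["cohort_id"].isin(pids)]
            if len(linked) and "donor_age" in linked.columns:
                add("donor_mean_age_years",
                    round_half_up(float(linked["donor_age"].mean()), 1),
                    len(linked))
    return pd.DataFrame(rows)
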