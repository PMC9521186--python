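"""Index regimen classification, adherence, and switching.

The index immunosuppressive regimen is read off the dispensings in the
30-day landmark window after transplant discharge: the backbone is the
calcineurin inhibitor present (tacrolimus TAC or cyclosporine CsA; if
both, the earlier first dispensing wins, same-day ties go to TAC — a
deterministic, configurable rule, since dual-CNI induction is not a
maintenance category); the companion is mono / +antimetabolite / +mTOR,
with antimetabolite and mTOR together falling into "other"; steroid
co-use is any H02AB dispensing in the window. A person with no CNI and
only steroids is No-CNI/other ("mainly steroid-based").

Adherence uses the two standard dispensing-based measures over a period
anchored at follow-up start: PDC (proportion of days covered, with
overlapping supplies shifted forward, i.e. stockpiling) and MPR (total
days supplied / period length, reported raw and capped at 1). Claims
carry package counts, not days supplied; days per package come from the
drug dictionary (default 30).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import regimen_label
from .dictionary import DrugDictionary


class ClassificationError(Exception):
    pass


@dataclass(frozen=True)
class RegimenClassification:
    backbone: str          # "TAC-based" | "CsA-based" | "No-CNI"
    companion: str         # "mono" | "+antimet" | "+mTOR" | "other"
    steroid: bool
    antimet_agent: str     # "MMF" | "AZA" | "none"
    tac_formulation: str   # "IR" | "ER" | "mixed" | "n/a"

    def __post_init__(self) -> None:
        if self.backbone == "No-CNI" and self.tac_formulation != "n/a":
            raise ValueError("No-CNI regimen cannot carry a TAC formulation")
        if self.companion == "mono" and self.antimet_agent != "none":
            raise ValueError("mono regimen cannot carry an antimet agent")

    def to_label(self) -> str:
        """Canonical 'backbone|companion|steroid' label (truth taxonomy)."""
        bb = {"TAC-based": "TAC", "CsA-based": "CsA", "No-CNI": "NoCNI"}[self.backbone]
        comp = self.companion.lstrip("+")
        return regimen_label(bb, comp, self.steroid)


def _annotated_window(dispensings: pd.DataFrame, dictionary: DrugDictionary,
                      ) -> pd.DataFrame:
    ann = dictionary.annotate(dispensings)
    return ann[ann["role"].notna()].sort_values("dispensing_date")


def classify_index_regimen(dispensings: pd.DataFrame,
                           dictionary: DrugDictionary,
                           tie_break: str = "TAC") -> RegimenClassification:
    """Classify from the dispensings inside [discharge, discharge+30).

    `dispensings` must already be restricted to the index window (columns
    dispensing_date, atc_code, aic_code). Raises ClassificationError when
    the window holds no maintenance-dictionary drug (impossible for a
    person who passed eligibility).
    """
    ann = _annotated_window(dispensings, dictionary)
    if ann.empty:
        raise ClassificationError("no maintenance drug in the index window")

    cni = ann[ann["role"] == "CNI"]
    if cni.empty:
        backbone_agent = None
    else:
        firsts = cni.groupby("agent")["dispensing_date"].min()
        if len(firsts) == 1:
            backbone_agent = firsts.index[0]
        elif firsts["TAC"] < firsts["CsA"]:
            backbone_agent = "TAC"
        elif firsts["CsA"] < firsts["TAC"]:
            backbone_agent = "CsA"
        else:
            backbone_agent = tie_break

    antimet = ann["role"].eq("antimet").any()
    mtor = ann["role"].eq("mTOR").any()
    steroid = bool(ann["role"].eq("steroid").any())

    if antimet and mtor:
        companion = "other"
    elif antimet:
        companion = "+antimet"
    elif mtor:
        companion = "+mTOR"
    elif backbone_agent is None:
        companion = "other"  # steroid-only: "mainly steroid-based"
    else:
        companion = "mono"

    if companion in ("+antimet", "other") and antimet:
        agents = set(ann.loc[ann["role"] == "antimet", "agent"])
        antimet_agent = "MMF" if "MMF" in agents else "AZA"
    else:
        antimet_agent = "none"

    backbone = {"TAC": "TAC-based", "CsA": "CsA-based",
                None: "No-CNI"}[backbone_agent]
    formulation = classify_tac_formulation(dispensings, dictionary) \
        if backbone == "TAC-based" else "n/a"
    return RegimenClassification(backbone=backbone, companion=companion,
                                 steroid=steroid, antimet_agent=antimet_agent,
                                 tac_formulation=formulation)


def classify_tac_formulation(dispensings: pd.DataFrame,
                             dictionary: DrugDictionary) -> str:
    """IR / ER / mixed from the AIC-level flags of TAC dispensings."""
    ann = _annotated_window(dispensings, dictionary)
    tac = ann[ann["agent"] == "TAC"]
    if tac.empty:
        return "n/a"
    forms = set(tac["formulation"])
    if forms - {"IR", "ER"}:
        raise KeyError("TAC product lacks a formulation flag")
    if forms == {"IR"}:
        return "IR"
    if forms == {"ER"}:
        return "ER"
    return "mixed"


def classify_brand_status(dispensings: pd.DataFrame,
                          dictionary: DrugDictionary,
                          index_date: pd.Timestamp,
                          agents: tuple[str, ...] = ("TAC", "CsA", "MMF"),
                          ) -> dict[str, str]:
    """Per-agent brand/generic status in the index window.

    Persons enrolled before an agent's generic entered the market are
    'not-evaluable' for that agent (brand was the only choice); agents
    not dispensed are 'n/a'.
    """
    ann = _annotated_window(dispensings, dictionary)
    out: dict[str, str] = {}
    for agent in agents:
        if index_date < dictionary.first_generic_date(agent):
            out[agent] = "not-evaluable"
            continue
        rows = ann[ann["agent"] == agent]
        if rows.empty:
            out[agent] = "n/a"
        else:
            statuses = set(rows["brand_status"])
            out[agent] = statuses.pop() if len(statuses) == 1 else "mixed"
    return out


@dataclass(frozen=True)
class AdherenceResult:
    pdc: float
    mpr_raw: float
    mpr_capped: float
    period_days: int
    agent_scope: str


def compute_adherence(dispensings: pd.DataFrame, period_days: int,
                      dictionary: DrugDictionary,
                      anchor: pd.Timestamp,
                      agents: tuple[str, ...] | None = None,
                      ) -> AdherenceResult:
    """PDC and MPR over [anchor, anchor+period_days).

    Only dispensings dated inside the period count (no carry-in from the
    landmark window). Overlapping supplies shift forward: a refill picked
    up early starts covering when the previous supply runs out.
    """
    if period_days <= 0:
        raise ValueError("period must be positive")
    ann = _annotated_window(dispensings, dictionary)
    if agents is not None:
        ann = ann[ann["agent"].isin(agents)]
    end = anchor + pd.Timedelta(days=period_days)
    ann = ann[(ann["dispensing_date"] >= anchor)
              & (ann["dispensing_date"] < end)]

    covered = 0
    total_supply = 0
    coverage_end = 0  # day offset from anchor
    for _, row in ann.sort_values("dispensing_date").iterrows():
        offset = int((row["dispensing_date"] - anchor).days)
        supply = int(row["n_packages"]) * int(row["days_per_package"])
        total_supply += supply
        start = max(offset, coverage_end)
        stop = start + supply
        covered += max(0, min(stop, period_days) - min(start, period_days))
        coverage_end = stop
    pdc = covered / period_days
    mpr = total_supply / period_days
    scope = ",".join(agents) if agents else "all-maintenance"
    return AdherenceResult(pdc=pdc, mpr_raw=mpr, mpr_capped=min(mpr, 1.0),
                           period_days=period_days, agent_scope=scope)


def detect_switches(dispensings: pd.DataFrame, dictionary: DrugDictionary,
                    anchor: pd.Timestamp, horizon_days: int,
                    grace_days: int = 60) -> pd.DataFrame:
    """Treatment-change events over [anchor, anchor+horizon_days).

    Events: within-class switch (a new agent replaces another of the same
    class, e.g. TAC->CsA), add-on (a class absent from the 30-day index
    window appears later), and discontinuation (coverage gap longer than
    the grace period across all maintenance drugs). Returns a frame
    (date, kind, detail) sorted by date.
    """
    ann = _annotated_window(dispensings, dictionary)
    end = anchor + pd.Timedelta(days=horizon_days)
    ann = ann[ann["dispensing_date"] < end]
    events: list[dict] = []

    index_end = anchor  # anchor is follow-up start = discharge + 30 days
    index_classes = set(ann.loc[ann["dispensing_date"] < index_end, "role"]) \
        - {"steroid"}

    for role in ("CNI", "antimet", "mTOR"):
        stream = ann[ann["role"] == role].sort_values("dispensing_date")
        if stream.empty:
            continue
        prev_agent = stream.iloc[0]["agent"]
        for _, row in stream.iloc[1:].iterrows():
            if row["agent"] != prev_agent:
                events.append({"date": row["dispensing_date"],
                               "kind": "within-class switch",
                               "detail": f"{prev_agent}->{row['agent']}"})
                prev_agent = row["agent"]
        first = stream.iloc[0]
        if role not in index_classes and first["dispensing_date"] >= index_end:
            events.append({"date": first["dispensing_date"],
                           "kind": "add-on", "detail": role})

    maint = ann[ann["role"] != "steroid"].sort_values("dispensing_date")
    coverage_end: pd.Timestamp | None = None
    for _, row in maint.iterrows():
        supply = pd.Timedelta(days=int(row["n_packages"])
                              * int(row["days_per_package"]))
        if coverage_end is not None \
                and row["dispensing_date"] > coverage_end + pd.Timedelta(days=grace_days):
            events.append({"date": coverage_end + pd.Timedelta(days=grace_days),
                           "kind": "discontinuation", "detail": "gap"})
        start = row["dispensing_date"] if coverage_end is None \
            else max(row["dispensing_date"], coverage_end)
        coverage_end = start + supply
    if coverage_end is not None \
            and coverage_end + pd.Timedelta(days=grace_days) < end:
        events.append({"date": coverage_end + pd.Timedelta(days=grace_days),
                       "kind": "discontinuation", "detail": "end of supply"})

    out = pd.DataFrame(events, columns=["date", "kind", "detail"])
    return out.sort_values("date").reset_index(drop=True)


def classify_cohort(cohort: pd.DataFrame, dispensings: pd.DataFrame,
                    dictionary: DrugDictionary) -> pd.DataFrame:
    """Classify every cohort member; one row per person.

    Columns: pid, organ, backbone, companion, steroid, antimet_agent,
    tac_formulation, label, plus per-agent brand status.
    """
    disp = dispensings.sort_values("dispensing_date")
    by_pid = dict(tuple(disp.groupby("pid")))
    rows = []
    for _, person in cohort.iterrows():
        d = by_pid.get(person["pid"])
        if d is None:
            raise ClassificationError(
                f"cohort member without dispensings: {person['pid']}")
        lo = person["discharge_date"]
        hi = lo + pd.Timedelta(days=30)
        window = d[(d["dispensing_date"] >= lo) & (d["dispensing_date"] < hi)]
        c = classify_index_regimen(window, dictionary)
        brands = classify_brand_status(window, dictionary, lo)
        rows.append({"pid": person["pid"], "organ": person["organ"],
                     "backbone": c.backbone, "companion": c.companion,
                     "steroid": c.steroid, "antimet_agent": c.antimet_agent,
                     "tac_formulation": c.tac_formulation,
                     "label": c.to_label(),
                     **{f"brand_{a}": s for a, s in brands.items()}})
    return pd.DataFrame(rows)
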