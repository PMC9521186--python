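"""Stepwise deterministic record linkage on pseudonymous keys.

Cohort and registry records are matched by exact equality of a
concatenated key built from quasi-identifiers (sex, organ, year+month of
birth, year+month of transplant, transplant hospital). The ladder of key
definitions is configuration, not code: by default step 1 uses all five
fields and subsequent steps each leave one field out (so a record with a
single corrupted field can still be recovered). Within a step, records
whose key is not unique on their own side are set aside — deterministic
linkage must not guess — and remain eligible at later steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .utils import share_percent

SEPARATOR = "|"
KEY_FIELDS = ("sex", "organ", "birth_ym", "transplant_ym", "hospital")

DEFAULT_STEPS: tuple[tuple[str, ...], ...] = (
    KEY_FIELDS,
    ("sex", "organ", "birth_ym", "transplant_ym"),        # drop hospital
    ("sex", "organ", "birth_ym", "hospital"),             # drop transplant_ym
    ("sex", "organ", "transplant_ym", "hospital"),        # drop birth_ym
    ("sex", "birth_ym", "transplant_ym", "hospital"),     # drop organ
    ("organ", "birth_ym", "transplant_ym", "hospital"),   # drop sex
)


class KeyConstructionError(Exception):
    pass


def _encode(fieldname: str, value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise KeyConstructionError(f"missing key field: {fieldname}")
    s = str(value).strip()
    if not s:
        raise KeyConstructionError(f"missing key field: {fieldname}")
    if SEPARATOR in s:
        raise KeyConstructionError(
            f"field {fieldname} contains the key separator: {s!r}")
    if fieldname == "organ":
        return s[:3].upper()
    if fieldname in ("birth_ym", "transplant_ym"):
        ts = pd.Period(s, freq="M")
        return f"{ts.year:04d}-{ts.month:02d}"
    return s.upper()


def build_key(record, fields: tuple[str, ...] = KEY_FIELDS) -> str:
    """Canonicalized concatenation of the requested quasi-identifiers."""
    return SEPARATOR.join(_encode(f, record[f]) for f in fields)


def _key_series(df: pd.DataFrame, fields: tuple[str, ...]) -> pd.Series:
    parts = []
    for f in fields:
        if f not in df.columns:
            raise KeyConstructionError(f"missing key field: {f}")
        parts.append(df[f].map(lambda v, f=f: _encode(f, v)))
    out = parts[0]
    for p in parts[1:]:
        out = out + SEPARATOR + p
    return out


@dataclass
class LinkageResult:
    matches: pd.DataFrame            # cohort_id, registry_id, step
    unmatched: pd.DataFrame          # cohort_id, reason
    step_counts: list[int]
    cohort_size: int

    def __post_init__(self) -> None:
        if self.matches["cohort_id"].duplicated().any() \
                or self.matches["registry_id"].duplicated().any():
            raise ValueError("linkage must be one-to-one")

    @property
    def linkage_rate(self) -> float:
        return len(self.matches) / self.cohort_size if self.cohort_size else 0.0


def stepwise_link(cohort: pd.DataFrame, registry: pd.DataFrame,
                  steps: tuple[tuple[str, ...], ...] = DEFAULT_STEPS
                  ) -> LinkageResult:
    """Exact one-to-one matching over an ordered ladder of key definitions.

    `cohort` needs a `cohort_id` column plus the key fields; `registry`
    needs `registry_id` plus the key fields. Each cohort id and registry
    id is consumed at most once.
    """
    if not steps:
        raise ValueError("empty linkage step list")

    cohort = cohort.reset_index(drop=True)
    registry = registry.reset_index(drop=True)
    un_c = cohort.copy()
    un_r = registry.copy()
    match_rows: list[dict] = []
    step_counts: list[int] = []
    ever_duplicate: set = set()

    for step_idx, fields in enumerate(steps, start=1):
        if un_c.empty or un_r.empty:
            step_counts.append(0)
            continue
        ck = _key_series(un_c, fields)
        rk = _key_series(un_r, fields)
        c_dup = ck.duplicated(keep=False)
        r_dup = rk.duplicated(keep=False)
        ever_duplicate.update(un_c.loc[c_dup.values, "cohort_id"])

        c_uni = un_c.loc[~c_dup.values].assign(_key=ck[~c_dup.values])
        r_uni = un_r.loc[~r_dup.values].assign(_key=rk[~r_dup.values])
        hit = c_uni[["cohort_id", "_key"]].merge(
            r_uni[["registry_id", "_key"]], on="_key", validate="one_to_one")
        for _, row in hit.iterrows():
            match_rows.append({"cohort_id": row["cohort_id"],
                               "registry_id": row["registry_id"],
                               "step": step_idx})
        step_counts.append(len(hit))
        un_c = un_c[~un_c["cohort_id"].isin(hit["cohort_id"])]
        un_r = un_r[~un_r["registry_id"].isin(hit["registry_id"])]

    matches = pd.DataFrame(match_rows,
                           columns=["cohort_id", "registry_id", "step"])
    unmatched = pd.DataFrame({
        "cohort_id": un_c["cohort_id"].values,
        "reason": ["duplicate-key" if cid in ever_duplicate else "no-candidate"
                   for cid in un_c["cohort_id"]]})
    return LinkageResult(matches=matches, unmatched=unmatched,
                         step_counts=step_counts, cohort_size=len(cohort))


def cohort_key_frame(cohort: pd.DataFrame,
                     persons: pd.DataFrame) -> pd.DataFrame:
    """Derive the quasi-identifier frame for linkage from the claims side.

    Day of birth is reduced to year+month (data minimization); the
    transplant date is the index admission month.
    """
    merged = cohort.merge(persons[["pid", "sex", "birth_date"]], on="pid",
                          validate="one_to_one")
    return pd.DataFrame({
        "cohort_id": merged["pid"],
        "sex": merged["sex"],
        "organ": merged["organ"],
        "birth_ym": merged["birth_date"].dt.strftime("%Y-%m"),
        "transplant_ym": merged["admission_date"].dt.strftime("%Y-%m"),
        "hospital": merged["hospital_code"],
    })


def linkage_report(result: LinkageResult,
                   truth: pd.DataFrame | None = None,
                   path: str | Path | None = None) -> dict:
    """Per-step counts, overall rate, and (when ground truth is supplied
    as a frame with pid/registry_id) the false-match rate."""
    report = {
        "cohort_size": result.cohort_size,
        "matched": len(result.matches),
        "linkage_rate": result.linkage_rate,
        "linkage_rate_percent": share_percent(len(result.matches),
                                              result.cohort_size)
        if result.cohort_size else 0.0,
        "per_step_matches": result.step_counts,
        "unmatched_reasons":
            result.unmatched["reason"].value_counts().to_dict(),
    }
    if truth is not None and len(result.matches):
        expected = truth.set_index("pid")["registry_id"]
        got = result.matches.set_index("cohort_id")["registry_id"]
        wrong = (got != got.index.map(expected)).sum()
        report["false_matches"] = int(wrong)
        report["false_match_rate"] = float(wrong / len(result.matches))
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=1))
    return report
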