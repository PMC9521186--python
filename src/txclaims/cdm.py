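"""Common data model: schema, bundle validation, analytical datasets.

The distributed design is modelled as independent per-region invocations
of one executable: each region validates its own claims bundle against
the shared schema, builds the minimal event-level analytical dataset
(data minimization: only fields the study reads survive), and the
datasets pool losslessly because person identifiers are namespaced by
region ("region::id") at build time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .simulate import ClaimsBundle


class SchemaError(Exception):
    """Structural failure (missing mandatory table/field list), not a
    row-level violation."""


class ValidationFailure(Exception):
    def __init__(self, report: "ValidationReport"):
        super().__init__(f"bundle failed validation with "
                         f"{len(report.violations)} violation(s)")
        self.report = report


@dataclass
class CDMSchema:
    version: int
    claims_window: tuple[pd.Timestamp, pd.Timestamp]
    code_systems: dict[str, re.Pattern]
    tables: dict[str, dict]
    analytical: dict

    @classmethod
    def load(cls, path: str | Path | None = None) -> "CDMSchema":
        if path is None:
            text = (resources.files("txclaims") / "schema" /
                    "cdm_schema.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        for tname, tdef in raw["tables"].items():
            if "person_id" not in tdef["fields"]:
                raise SchemaError(f"table {tname} lacks the anonymous "
                                  "person identifier")
            for fname in tdef["fields"]:
                if fname in ("name", "surname", "fiscal_code"):
                    raise SchemaError(f"direct identifier {fname} in schema")
        return cls(
            version=int(raw["version"]),
            claims_window=(pd.Timestamp(raw["claims_window"]["start"]),
                           pd.Timestamp(raw["claims_window"]["end"])),
            code_systems={k: re.compile(v)
                          for k, v in raw["code_systems"].items()},
            tables=raw["tables"],
            analytical=raw["analytical"],
        )


@dataclass
class ValidationReport:
    region: str
    row_counts: dict[str, int]
    violations: list[dict] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"region": self.region, "passed": self.passed,
                              "row_counts": self.row_counts,
                              "violations": self.violations}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def validate_bundle(bundle: ClaimsBundle, schema: CDMSchema) -> ValidationReport:
    """Structural and semantic check of one region's source tables.

    Missing mandatory tables raise SchemaError; everything else is
    collected as row-level violations (table, row ordinal, field, reason).
    Non-mutating.
    """
    report = ValidationReport(region=bundle.region, row_counts={})
    known = bundle.tables.get("inhabitant_registry")
    known_ids = set(known["person_id"]) if known is not None else set()
    lo, hi = schema.claims_window

    for tname, tdef in schema.tables.items():
        df = bundle.tables.get(tname)
        if df is None:
            if tdef.get("required", False):
                raise SchemaError(f"missing mandatory table: {tname}")
            continue
        report.row_counts[tname] = len(df)
        for fname, ftype in tdef["fields"].items():
            if fname not in df.columns:
                report.violations.append(
                    {"table": tname, "row": -1, "field": fname,
                     "reason": "missing field"})
                continue
            col = df[fname]
            if ftype == "date":
                dates = pd.to_datetime(col, errors="coerce")
                bad = col.notna() & ((dates < lo) | (dates > hi))
                for row in df.index[bad]:
                    report.violations.append(
                        {"table": tname, "row": int(row), "field": fname,
                         "reason": "date outside study window"})
            elif ftype.startswith("code:"):
                pattern = schema.code_systems[ftype.split(":", 1)[1]]
                values = col.fillna("").astype(str)
                bad = (values != "") & ~values.str.fullmatch(pattern)
                for row in df.index[bad]:
                    report.violations.append(
                        {"table": tname, "row": int(row), "field": fname,
                         "reason": "bad code format"})
            elif ftype == "identifier" and tname != "inhabitant_registry":
                orphan = ~col.isin(known_ids)
                for row in df.index[orphan]:
                    report.violations.append(
                        {"table": tname, "row": int(row), "field": fname,
                         "reason": "orphan person id"})
    return report


@dataclass
class AnalyticalDataset:
    """Minimal pooled event-level dataset; person ids are region-namespaced."""

    schema_version: int
    regions: list[str]
    persons: pd.DataFrame
    hospitalizations: pd.DataFrame
    dispensings: pd.DataFrame
    deaths: pd.DataFrame
    registration: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"persons": self.persons,
                "hospitalizations": self.hospitalizations,
                "dispensings": self.dispensings,
                "deaths": self.deaths,
                "registration": self.registration}

    def write(self, out_dir: str | Path, fmt: str = "csv") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            if fmt == "csv":
                df.to_csv(out / f"{name}.csv", index=False)
            else:
                df.to_parquet(out / f"{name}.parquet", index=False)


def build_analytical_dataset(bundle: ClaimsBundle,
                             schema: CDMSchema) -> AnalyticalDataset:
    """Validate, then reduce a claims bundle to the study's event tables.

    Refuses (ValidationFailure carrying the report) if validation finds
    any violation. Fields outside the declared minimal field list are
    stripped; dispensings are restricted to the ATC families the study
    reads (immunosuppressants, steroids, baseline comedications).
    """
    report = validate_bundle(bundle, schema)
    if not report.passed:
        raise ValidationFailure(report)

    region = bundle.region

    def ns(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["pid"] = region + "::" + df["person_id"].astype(str)
        df["region"] = region
        return df

    spec = schema.analytical["tables"]
    inhab = ns(bundle.tables["inhabitant_registry"])
    persons = inhab[spec["persons"]]
    registration = inhab[spec["registration"]]

    hosp = ns(bundle.tables["hospital_discharge"])
    hospitalizations = hosp[spec["hospitalizations"]]

    disp = ns(bundle.tables["drug_dispensing"])
    prefixes = tuple(schema.analytical["relevant_atc_prefixes"])
    disp = disp[disp["atc_code"].astype(str).str.startswith(prefixes)]
    dispensings = disp[spec["dispensings"]].reset_index(drop=True)

    deaths = ns(bundle.tables["mortality_registry"])[spec["deaths"]]

    return AnalyticalDataset(
        schema_version=schema.version, regions=[region], persons=persons,
        hospitalizations=hospitalizations, dispensings=dispensings,
        deaths=deaths, registration=registration)


def pool_regions(datasets: list[AnalyticalDataset]) -> AnalyticalDataset:
    """Union of per-region datasets; namespaced ids make collisions impossible."""
    if not datasets:
        raise SchemaError("nothing to pool")
    versions = {d.schema_version for d in datasets}
    if len(versions) > 1:
        raise SchemaError(f"schema version mismatch: {sorted(versions)}")
    if len(datasets) == 1:
        return datasets[0]

    def cat(name: str) -> pd.DataFrame:
        return pd.concat([getattr(d, name) for d in datasets],
                         ignore_index=True)

    regions = sorted({r for d in datasets for r in d.regions})
    return AnalyticalDataset(
        schema_version=datasets[0].schema_version, regions=regions,
        persons=cat("persons"), hospitalizations=cat("hospitalizations"),
        dispensings=cat("dispensings"), deaths=cat("deaths"),
        registration=cat("registration"))


def check_minimal_fields(dataset: AnalyticalDataset,
                         schema: CDMSchema) -> list[str]:
    """Data-minimization audit: columns outside the declared minimal lists."""
    extra: list[str] = []
    for name, allowed in schema.analytical["tables"].items():
        df = getattr(dataset, name)
        extra.extend(f"{name}.{c}" for c in df.columns if c not in allowed)
    return extra
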