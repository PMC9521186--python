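"""Drug dictionary for the maintenance immunosuppressive phase.

Maps ATC codes to agent roles (CNI backbone, antimetabolite, mTOR
inhibitor, corticosteroid) and synthetic AIC-style product codes to
package-level attributes the claims themselves do not carry: brand vs
generic status, tacrolimus release formulation (immediate IR vs
extended ER), and the days-of-therapy one package supplies.

Italian dispensing claims record package counts, not days supplied; the
days-per-package convention (default 30) lives here, in one auditable
table, rather than being scattered through the adherence code.

The generic-availability calendar is synthetic: it reproduces the shape
of the Italian market (cyclosporine and azathioprine generic throughout,
mycophenolate from mid-study, tacrolimus later, no mTOR generics) without
claiming the true authorization dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# ATC -> (agent, role)
ATC_ROLES: dict[str, tuple[str, str]] = {
    "L04AD01": ("CsA", "CNI"),
    "L04AD02": ("TAC", "CNI"),
    "L04AA06": ("MMF", "antimet"),
    "L04AX01": ("AZA", "antimet"),
    "L04AA18": ("EVE", "mTOR"),
    "L04AA10": ("SIR", "mTOR"),
    "H02AB07": ("prednisone", "steroid"),
    "H02AB04": ("methylprednisolone", "steroid"),
    "H02AB06": ("prednisolone", "steroid"),
}

CNI_AGENTS = ("TAC", "CsA")
ANTIMET_AGENTS = ("MMF", "AZA")
MTOR_AGENTS = ("EVE", "SIR")
STEROID_ATCS = tuple(a for a, (_, r) in ATC_ROLES.items() if r == "steroid")
L04_ATCS = tuple(a for a in ATC_ROLES if a.startswith("L04"))

# First date a generic version is on the market (far future = brand only).
GENERIC_AVAILABILITY: dict[str, str] = {
    "CsA": "2009-01-01",
    "AZA": "2009-01-01",
    "MMF": "2010-07-01",
    "TAC": "2013-07-01",
    "EVE": "2100-01-01",
    "SIR": "2100-01-01",
    "prednisone": "2009-01-01",
    "methylprednisolone": "2009-01-01",
    "prednisolone": "2009-01-01",
}


@dataclass(frozen=True)
class DrugProduct:
    aic: str
    atc: str
    agent: str
    role: str
    brand_status: str       # "brand" | "generic"
    formulation: str        # "IR" | "ER" for TAC, "n/a" otherwise
    days_per_package: int = 30


def _products() -> list[DrugProduct]:
    rows: list[DrugProduct] = []
    serial = 0
    for atc, (agent, role) in ATC_ROLES.items():
        formulations = ("IR", "ER") if agent == "TAC" else ("n/a",)
        for form in formulations:
            for status in ("brand", "generic"):
                serial += 1
                rows.append(DrugProduct(
                    aic=f"A{serial:08d}", atc=atc, agent=agent, role=role,
                    brand_status=status, formulation=form,
                ))
    return rows


@dataclass
class DrugDictionary:
    """Product-level lookup plus the generic-availability calendar."""

    products: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        [vars(p) for p in _products()]
    ))
    availability: dict[str, pd.Timestamp] = field(default_factory=lambda: {
        agent: pd.Timestamp(d) for agent, d in GENERIC_AVAILABILITY.items()
    })

    def __post_init__(self) -> None:
        roles = self.products.groupby("atc")["role"].nunique()
        if (roles > 1).any():
            raise ValueError("an ATC code maps to more than one role")
        if self.products["aic"].duplicated().any():
            raise ValueError("duplicate AIC product codes")
        self._by_aic = {row["aic"]: row
                        for _, row in self.products.iterrows()}
        self._aic_index: dict[tuple, str] = {}
        for _, row in self.products.iterrows():
            key = (row["agent"], row["brand_status"], row["formulation"])
            self._aic_index.setdefault(key, row["aic"])
            self._aic_index.setdefault((row["agent"], row["brand_status"], None),
                                       row["aic"])

    def lookup(self, aic: str) -> pd.Series:
        try:
            return self._by_aic[aic]
        except KeyError:
            raise KeyError(f"unknown AIC product code: {aic}")

    def aic_for(self, agent: str, brand_status: str = "brand",
                formulation: str | None = None) -> str:
        try:
            return self._aic_index[(agent, brand_status, formulation)]
        except KeyError:
            raise KeyError(f"no product for {agent}/{brand_status}/{formulation}")

    def first_generic_date(self, agent: str) -> pd.Timestamp:
        try:
            return self.availability[agent]
        except KeyError:
            raise KeyError(f"agent missing from availability calendar: {agent}")

    def annotate(self, dispensings: pd.DataFrame) -> pd.DataFrame:
        """Join agent/role/brand/formulation/days columns onto dispensing rows.

        Accepts either the claims column names (atc_code/aic_code) or the
        bare ones (atc/aic)."""
        df = dispensings.rename(columns={"atc_code": "atc", "aic_code": "aic"})
        return df.merge(self.products, on=["aic", "atc"], how="left",
                        validate="many_to_one")


def default_dictionary() -> DrugDictionary:
    return DrugDictionary()
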