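"""Simulation configuration for the synthetic multi-region claims generator.

Defaults encode the study conditions of the source setting: the organ mix
of an Italian four-region transplant population (kidney-dominated), the
per-organ index-regimen mixtures with their steroid co-use fractions, and
per-organ constant outcome hazards on the incidence-rate scale actually
observed in such cohorts. Pancreas and intestine transplants occur at
trace frequency; they exist mainly as multi-organ-exclusion material.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

ORGANS = ("kidney", "liver", "heart", "lung", "pancreas", "intestine")
BACKBONES = ("TAC", "CsA", "NoCNI")
COMPANIONS = ("mono", "antimet", "mTOR", "other")

DEFAULT_ORGAN_MIX = {
    "kidney": 0.583, "liver": 0.321, "heart": 0.063, "lung": 0.031,
    "pancreas": 0.001, "intestine": 0.001,
}

# (backbone, companion) -> (cell count, steroid co-use count), per organ.
_REGIMEN_CELLS: dict[str, dict[tuple[str, str], tuple[int, int]]] = {
    "kidney": {
        ("TAC", "mono"): (261, 210), ("TAC", "antimet"): (1980, 1682),
        ("TAC", "mTOR"): (559, 398), ("TAC", "other"): (35, 25),
        ("CsA", "mono"): (85, 74), ("CsA", "antimet"): (617, 416),
        ("CsA", "mTOR"): (79, 69), ("CsA", "other"): (6, 5),
        ("NoCNI", "antimet"): (78, 60), ("NoCNI", "mTOR"): (30, 27),
        ("NoCNI", "other"): (299, 294),
    },
    "liver": {
        ("TAC", "mono"): (927, 786), ("TAC", "antimet"): (690, 579),
        ("TAC", "mTOR"): (211, 129), ("TAC", "other"): (39, 27),
        ("CsA", "mono"): (225, 162), ("CsA", "antimet"): (39, 34),
        ("CsA", "mTOR"): (7, 2),
        ("NoCNI", "antimet"): (16, 12), ("NoCNI", "mTOR"): (16, 11),
        ("NoCNI", "other"): (49, 46),
    },
    "heart": {
        ("TAC", "mono"): (21, 19), ("TAC", "antimet"): (45, 40),
        ("CsA", "mono"): (84, 64), ("CsA", "antimet"): (231, 181),
        ("CsA", "mTOR"): (14, 10), ("CsA", "other"): (4, 3),
        ("NoCNI", "antimet"): (17, 9), ("NoCNI", "mTOR"): (2, 1),
        ("NoCNI", "other"): (16, 16),
    },
    "lung": {
        ("TAC", "mono"): (42, 36), ("TAC", "antimet"): (81, 78),
        ("CsA", "mono"): (13, 12), ("CsA", "antimet"): (63, 59),
        ("NoCNI", "antimet"): (10, 6), ("NoCNI", "other"): (6, 6),
    },
}
_REGIMEN_CELLS["pancreas"] = _REGIMEN_CELLS["kidney"]
_REGIMEN_CELLS["intestine"] = _REGIMEN_CELLS["kidney"]


def regimen_label(backbone: str, companion: str, steroid: bool) -> str:
    """Canonical regimen label, e.g. 'TAC|antimet|steroid'."""
    if backbone not in BACKBONES or companion not in COMPANIONS:
        raise ValueError(f"unknown regimen cell {backbone}/{companion}")
    return f"{backbone}|{companion}|{'steroid' if steroid else 'nosteroid'}"


def parse_regimen_label(label: str) -> tuple[str, str, bool]:
    backbone, companion, ster = label.split("|")
    return backbone, companion, ster == "steroid"


def default_regimen_mixture() -> dict[str, dict[str, float]]:
    """Per-organ label -> probability, splitting each cell by steroid co-use."""
    out: dict[str, dict[str, float]] = {}
    for organ, cells in _REGIMEN_CELLS.items():
        total = sum(n for n, _ in cells.values())
        mix: dict[str, float] = {}
        for (bb, comp), (n, ster) in cells.items():
            if ster:
                mix[regimen_label(bb, comp, True)] = ster / total
            if n - ster:
                mix[regimen_label(bb, comp, False)] = (n - ster) / total
        out[organ] = mix
    return out


# MMF share among antimetabolite users, by organ.
DEFAULT_MMF_SHARE = {
    "kidney": 0.920, "liver": 0.999, "heart": 0.785, "lung": 0.274,
    "pancreas": 0.920, "intestine": 0.920,
}
# Immediate-release share among tacrolimus users, by organ.
DEFAULT_TAC_IR_SHARE = {
    "kidney": 0.507, "liver": 0.688, "heart": 0.60, "lung": 0.60,
    "pancreas": 0.507, "intestine": 0.507,
}
# Probability a dispensing is the generic product (given generics available).
DEFAULT_GENERIC_UPTAKE = {"TAC": 0.25, "MMF": 0.45, "CsA": 0.30, "AZA": 0.50,
                          "EVE": 0.0, "SIR": 0.0}

# Constant hazards (events per person-year) by organ and outcome.
DEFAULT_OUTCOME_HAZARDS: dict[str, dict[str, float]] = {
    "kidney": {"death": 0.0196, "reject": 0.0212, "infection": 0.0938,
               "diabetes": 0.0362, "cancer": 0.0236},
    "liver": {"death": 0.0367, "reject": 0.0175, "infection": 0.0424,
              "diabetes": 0.0420, "cancer": 0.0595},
    "heart": {"death": 0.0289, "reject": 0.0135, "infection": 0.0795,
              "diabetes": 0.0216, "cancer": 0.0158},
    "lung": {"death": 0.1079, "reject": 0.0666, "infection": 0.3738,
             "diabetes": 0.1732, "cancer": 0.0310},
}
DEFAULT_OUTCOME_HAZARDS["pancreas"] = DEFAULT_OUTCOME_HAZARDS["kidney"]
DEFAULT_OUTCOME_HAZARDS["intestine"] = DEFAULT_OUTCOME_HAZARDS["kidney"]

# Eligibility rules that can receive planted violators.
PLANT_RULES = (
    "out_of_window_index",   # index discharge before the enrolment window
    "multi_organ",           # second organ procedure in the index admission
    "prior_transplant",      # transplant in the 2 years before index discharge
    "early_death",           # death within 30 days of discharge
    "deregistered",          # not covered by the inhabitant registry at index
    "prior_l04",             # L04 dispensing in the 180 days pre-discharge
    "no_index_dispensing",   # no maintenance drug in the 30 days post-discharge
)


class SimulationConfig(BaseModel):
    """Everything the generator needs; all randomness flows from `seed`."""

    n_persons: int = Field(ge=1)
    seed: int = 0
    region_ids: list[str] = ["lombardy", "veneto", "lazio", "sardinia"]
    organ_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ORGAN_MIX))
    regimen_mixture: dict[str, dict[str, float]] = Field(
        default_factory=default_regimen_mixture)
    mmf_share: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MMF_SHARE))
    tac_ir_share: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_TAC_IR_SHARE))
    generic_uptake: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_GENERIC_UPTAKE))
    adherence_mean: float = Field(default=0.8, gt=0.0, le=1.0)
    adherence_concentration: float = Field(default=10.0, gt=0.0)
    outcome_hazards: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {o: dict(h) for o, h in DEFAULT_OUTCOME_HAZARDS.items()})
    planted_negative_rates: dict[str, float] = Field(
        default_factory=lambda: {r: 0.05 for r in PLANT_RULES})
    switch_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    key_perturbation_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    sit_disagreement_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    hospitals_per_region: int = Field(default=5, ge=1)

    @field_validator("organ_mix")
    @classmethod
    def _organ_mix_valid(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(ORGANS)
        if unknown:
            raise ValueError(f"unknown organs in organ_mix: {sorted(unknown)}")
        _check_simplex(v, "organ_mix")
        return v

    @field_validator("regimen_mixture")
    @classmethod
    def _mixture_valid(cls, v: dict[str, dict[str, float]]):
        for organ, mix in v.items():
            for label in mix:
                parse_regimen_label(label)
            _check_simplex(mix, f"regimen_mixture[{organ}]")
        return v

    @field_validator("outcome_hazards")
    @classmethod
    def _hazards_nonneg(cls, v):
        for organ, hz in v.items():
            for name, lam in hz.items():
                if lam < 0:
                    raise ValueError(f"negative hazard {organ}/{name}")
        return v

    @field_validator("planted_negative_rates")
    @classmethod
    def _rates_valid(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(PLANT_RULES)
        if unknown:
            raise ValueError(f"unknown planted-negative rules: {sorted(unknown)}")
        for rule, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"planted rate outside [0,1]: {rule}={p}")
        return v

    @model_validator(mode="after")
    def _plant_total(self) -> "SimulationConfig":
        if sum(self.planted_negative_rates.values()) > 1.0 + 1e-9:
            raise ValueError("planted-negative rates sum above 1")
        return self


def _check_simplex(probs: dict[str, float], name: str) -> None:
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} has negative proportions")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions sum to {total!r}, not 1")
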