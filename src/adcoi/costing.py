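"""Scenario costing engine.

Assembles the annual national cost of atopic dermatitis in EUR for one
population segment under one of four scenarios:

    {prevalence, incidence} x {survey-reported treatment cost,
                               national average prescription cost}

Components follow the mixed costing design: per-patient survey averages
scaled to national case counts (bottom-up) for treatment, medical services
and associated out-of-pocket costs; national hospital discharge data
apportioned to strata (top-down) for inpatient care; and worker counts x
mean absence days x gross daily wage (human-capital approach, absenteeism
only) for productivity losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import pandas as pd
from pydantic import BaseModel, model_validator

from .extrapolate import SEVERITIES, Basis, Segment, SeverityStratification
from .processing import SeverityAverages

EmploymentClass = Literal["full_time", "part_time"]
TreatmentSource = Literal["survey", "prescription"]

#: Component keys in reporting order; pediatric runs force medical_services to 0.
COMPONENTS: tuple[str, ...] = (
    "treatment",
    "medical_services",
    "associated",
    "hospitalization",
    "productivity_ft",
    "productivity_pt",
)


class UnitCosts(BaseModel):
    """National unit costs and conversion constants (2022 reference year).

    Wages and hospital tariffs are in RON; ``fx`` converts RON to EUR.
    ``hospital_cost_basis`` selects whether the hospital tariff is read as a
    per-day or a per-stay figure; only the per-day reading is consistent
    with the packaged national hospitalization totals.
    """

    gross_monthly_wage: float = 6126.0
    part_time_monthly_wage: float = 3063.0
    working_days_per_year: float = 251.0
    alos_adult: float = 7.95
    alos_pediatric: float = 4.44
    hospital_cost_per_day_adult: float = 1094.0
    hospital_cost_per_day_pediatric: float = 1012.0
    avg_prescription: float = 40.4
    fx: float = 4.9315
    hospital_cost_basis: Literal["per_day", "per_stay"] = "per_day"

    @model_validator(mode="after")
    def _positive(self) -> "UnitCosts":
        for name in (
            "gross_monthly_wage",
            "part_time_monthly_wage",
            "working_days_per_year",
            "alos_adult",
            "alos_pediatric",
            "hospital_cost_per_day_adult",
            "hospital_cost_per_day_pediatric",
            "avg_prescription",
            "fx",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.part_time_monthly_wage > self.gross_monthly_wage:
            raise ValueError("part-time wage cannot exceed the gross monthly wage")
        return self

    def monthly_wage(self, employment_class: EmploymentClass) -> float:
        if employment_class == "full_time":
            return self.gross_monthly_wage
        if employment_class == "part_time":
            return self.part_time_monthly_wage
        raise ValueError(f"unknown employment class {employment_class!r}")

    def daily_wage_eur(self, employment_class: EmploymentClass) -> float:
        """Gross daily wage in EUR: monthly wage x 12 / working days / fx."""
        return (
            self.monthly_wage(employment_class) * 12.0 / self.working_days_per_year / self.fx
        )


class ScenarioSpec(BaseModel):
    """One of the four valid scenario combinations."""

    basis: Basis
    treatment_source: TreatmentSource = "survey"

    @property
    def label(self) -> str:
        suffix = "" if self.treatment_source == "survey" else "_prescription"
        return f"{self.basis}{suffix}"


def ron_to_eur(amount: float, fx: float) -> float:
    """Convert RON to EUR at the configured annual-average exchange rate."""
    if fx <= 0:
        raise ValueError("fx must be strictly positive")
    return amount / fx


def component_total(mean_cost: float, cases: float) -> float:
    """Bottom-up national total: per-patient annual average x case count."""
    if mean_cost < 0 or cases < 0:
        raise ValueError("mean cost and case count must be nonnegative")
    return mean_cost * cases


def prescription_treatment_total(cases: float, unit: UnitCosts) -> float:
    """Treatment total when the survey mean is replaced by the annual
    average prescription value (RON), converted to EUR."""
    if cases < 0:
        raise ValueError("case count must be nonnegative")
    return cases * ron_to_eur(unit.avg_prescription, unit.fx)


def hospitalization_total(hosp_unrounded: float, segment: Segment, unit: UnitCosts) -> float:
    """Top-down inpatient total for one stratum.

    Per-day basis: hospitalizations x average length of stay x per-day
    tariff; per-stay basis multiplies the tariff once per admission.
    The unrounded hospitalization count is used — rounding only happens in
    the reported counts, not inside cost chains.
    """
    if hosp_unrounded < 0:
        raise ValueError("hospitalization count must be nonnegative")
    tariff = (
        unit.hospital_cost_per_day_adult
        if segment == "adult"
        else unit.hospital_cost_per_day_pediatric
    )
    alos = unit.alos_adult if segment == "adult" else unit.alos_pediatric
    ron = hosp_unrounded * tariff * (alos if unit.hospital_cost_basis == "per_day" else 1.0)
    return ron_to_eur(ron, unit.fx)


def productivity_total(
    workers: float,
    mean_days: float,
    employment_class: EmploymentClass,
    unit: UnitCosts,
) -> float:
    """Human-capital absenteeism cost: workers x missed days x daily wage."""
    if workers < 0 or mean_days < 0:
        raise ValueError("workers and mean days must be nonnegative")
    return workers * mean_days * unit.daily_wage_eur(employment_class)


@dataclass
class ScenarioResult:
    """Component x severity cost cells for one segment under one scenario."""

    segment: Segment
    spec: ScenarioSpec
    cells: dict[str, tuple[float, float, float]]
    cases: tuple[int, int, int]
    component_totals: dict[str, float] = field(init=False)
    severity_totals: tuple[float, float, float] = field(init=False)
    grand_total: float = field(init=False)
    average_overall: float = field(init=False)
    average_per_severity: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.component_totals = {k: sum(v) for k, v in self.cells.items()}
        self.severity_totals = tuple(
            sum(self.cells[k][i] for k in self.cells) for i in range(3)
        )
        self.grand_total = sum(self.component_totals.values())
        total_cases = sum(self.cases)
        self.average_overall = self.grand_total / total_cases if total_cases else 0.0
        self.average_per_severity = tuple(
            (t / c if c else 0.0) for t, c in zip(self.severity_totals, self.cases)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for component, values in self.cells.items():
            for sev, value in zip(SEVERITIES, values):
                rows.append(
                    {
                        "segment": self.segment,
                        "scenario": self.spec.label,
                        "component": component,
                        "severity": sev,
                        "total_eur": value,
                    }
                )
        return pd.DataFrame(rows)


def run_scenario(
    spec: ScenarioSpec,
    segment: Segment,
    averages: SeverityAverages,
    strat: SeverityStratification,
    unit: UnitCosts,
) -> ScenarioResult:
    """Assemble every component total for one segment under one scenario.

    The stratification must be on the scenario's epidemiological basis and
    the averages on the scenario's segment; pediatric runs force the
    medical-services component to zero because that category is not
    collected for caregiver-reported patients.
    """
    if strat.basis != spec.basis:
        raise ValueError(
            f"stratification basis {strat.basis!r} does not match scenario {spec.basis!r}"
        )
    if strat.segment != segment or averages.segment != segment:
        raise ValueError("segment mismatch between averages, stratification and scenario")

    cells: dict[str, tuple[float, float, float]] = {}
    if spec.treatment_source == "survey":
        cells["treatment"] = tuple(
            component_total(m, c) for m, c in zip(averages.cost_treatment, strat.cases)
        )
    else:
        cells["treatment"] = tuple(
            prescription_treatment_total(c, unit) for c in strat.cases
        )
    if segment == "pediatric" or averages.cost_medical_services is None:
        cells["medical_services"] = (0.0, 0.0, 0.0)
    else:
        cells["medical_services"] = tuple(
            component_total(m, c)
            for m, c in zip(averages.cost_medical_services, strat.cases)
        )
    cells["associated"] = tuple(
        component_total(m, c) for m, c in zip(averages.cost_associated, strat.cases)
    )
    cells["hospitalization"] = tuple(
        hospitalization_total(h, segment, unit) for h in strat.hospitalizations_unrounded
    )
    cells["productivity_ft"] = tuple(
        productivity_total(w, d, "full_time", unit)
        for w, d in zip(strat.workers_full_time, averages.days_missed_full_time)
    )
    cells["productivity_pt"] = tuple(
        productivity_total(w, d, "part_time", unit)
        for w, d in zip(strat.workers_part_time, averages.days_missed_part_time)
    )
    return ScenarioResult(segment=segment, spec=spec, cells=cells, cases=strat.cases)
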