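"""National-inputs configuration.

One YAML file carries everything the extrapolation and costing stages need:
GBD crude counts, hospital discharges, unit costs, the survey severity
margins, the per-severity per-patient input cost averages, and the
worker-share / mean-absence-day reproduction fixtures.  The packaged
default (``data/romania_2022.yaml``) holds the 2022 Romanian inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .costing import UnitCosts
from .extrapolate import (
    Basis,
    EpiInputs,
    Segment,
    SeverityStratification,
    SurveyMargins,
    build_stratification,
)
from .processing import SeverityAverages


@dataclass
class NationalInputs:
    """Parsed national-inputs bundle."""

    epi: EpiInputs
    unit_costs: UnitCosts
    margins: dict[Segment, SurveyMargins]
    cost_averages: dict[Segment, dict[str, tuple[float, float, float] | None]]
    worker_shares: dict[Segment, dict[str, tuple[float, float, float]]]
    #: segment -> basis -> class -> per-severity mean absence days
    mean_days: dict[Segment, dict[Basis, dict[str, tuple[float, float, float]]]]

    def fixture_averages(self, segment: Segment, basis: Basis) -> SeverityAverages:
        """SeverityAverages assembled from the calibrated fixture inputs."""
        cost = self.cost_averages[segment]
        days = self.mean_days[segment][basis]
        shares = self.worker_shares[segment]
        margins = self.margins[segment]
        return SeverityAverages(
            segment=segment,
            n=margins.counts,
            cost_treatment=cost["cost_treatment"],
            cost_medical_services=cost.get("cost_medical_services"),
            cost_associated=cost["cost_associated"],
            employment_share_full_time=shares["full_time"],
            employment_share_part_time=shares["part_time"],
            days_missed_full_time=days["full_time"],
            days_missed_part_time=days["part_time"],
        )

    def stratification(self, segment: Segment, basis: Basis) -> SeverityStratification:
        return build_stratification(
            self.epi,
            segment,
            basis,
            self.margins["adult"],
            self.margins["pediatric"],
            ft_shares=self.worker_shares[segment]["full_time"],
            pt_shares=self.worker_shares[segment]["part_time"],
        )


def _triple(x) -> tuple[float, float, float] | None:
    return None if x is None else tuple(float(v) for v in x)


def load_national_inputs(path: str | Path | None = None) -> NationalInputs:
    """Parse a national-inputs YAML; packaged Romanian 2022 file by default."""
    if path is None:
        with resources.as_file(resources.files("adcoi.data") / "romania_2022.yaml") as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())

    margins = {
        seg: SurveyMargins(**raw["survey_margins"][seg]) for seg in ("adult", "pediatric")
    }
    cost_averages = {
        seg: {col: _triple(vals) for col, vals in raw["cost_averages_eur"][seg].items()}
        for seg in ("adult", "pediatric")
    }
    worker_shares = {
        seg: {cls: _triple(vals) for cls, vals in raw["worker_shares"][seg].items()}
        for seg in ("adult", "pediatric")
    }
    days_raw = raw["mean_days_missed"]
    mean_days: dict[Segment, dict[Basis, dict[str, tuple[float, float, float]]]] = {}
    for seg in ("adult", "pediatric"):
        entry = days_raw[seg]
        if "prevalence" in entry:  # per-basis fixture
            mean_days[seg] = {
                basis: {cls: _triple(v) for cls, v in entry[basis].items()}
                for basis in ("prevalence", "incidence")
            }
        else:  # one set shared by both bases
            shared = {cls: _triple(v) for cls, v in entry.items()}
            mean_days[seg] = {"prevalence": shared, "incidence": shared}
    return NationalInputs(
        epi=EpiInputs(**raw["epi"]),
        unit_costs=UnitCosts(**raw["unit_costs"]),
        margins=margins,
        cost_averages=cost_averages,
        worker_shares=worker_shares,
        mean_days=mean_days,
    )
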