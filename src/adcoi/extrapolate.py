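"""National extrapolation of survey severity shares.

Turns Global Burden of Disease (GBD) crude case counts, national hospital
discharges and survey severity margins into severity-stratified counts of
cases, hospitalizations and full-/part-time workers for each population
segment (adult = 20+ years, pediatric = <20 years) and epidemiological
basis (prevalence or incidence).

Conventions that matter for exact reproduction of published national
figures:

* severity shares enter as the *integer* survey counts, never as rounded
  percentages;
* all chained computations use unrounded intermediates; round-half-up is
  applied once, at the final reporting step of each quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd
from pydantic import BaseModel, NonNegativeInt, model_validator

Severity = Literal["mild", "moderate", "severe"]
SEVERITIES: tuple[str, ...] = ("mild", "moderate", "severe")
Basis = Literal["prevalence", "incidence"]
Segment = Literal["adult", "pediatric"]


def round_half_up(x: float) -> int:
    """Round a nonnegative quantity half away from zero (.5 rounds up).

    Used only at the final reporting step of extrapolated counts; chained
    computations keep unrounded intermediates.
    """
    if x < 0:
        raise ValueError(f"counts are nonnegative, got {x}")
    return int(math.floor(x + 0.5))


class EpiInputs(BaseModel):
    """National GBD crude counts and hospital discharges for one year."""

    prevalence_under20: NonNegativeInt
    prevalence_20plus: NonNegativeInt
    incidence_under20: NonNegativeInt
    incidence_20plus: NonNegativeInt
    hospital_discharges_total: NonNegativeInt

    def segment_count(self, segment: Segment, basis: Basis) -> int:
        return getattr(
            self,
            f"{basis}_{'under20' if segment == 'pediatric' else '20plus'}",
        )

    def basis_total(self, basis: Basis) -> int:
        return self.segment_count("adult", basis) + self.segment_count("pediatric", basis)


class SurveyMargins(BaseModel):
    """Integer severity counts observed in one survey cohort."""

    mild: NonNegativeInt
    moderate: NonNegativeInt
    severe: NonNegativeInt

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.mild, self.moderate, self.severe)

    @property
    def n(self) -> int:
        return sum(self.counts)

    @model_validator(mode="after")
    def _nonempty(self) -> "SurveyMargins":
        if self.n == 0:
            raise ValueError("survey margins must contain at least one respondent")
        return self


@dataclass
class SeverityStratification:
    """Per-severity national counts for one segment on one basis."""

    segment: Segment
    basis: Basis
    cases_unrounded: tuple[float, float, float]
    cases: tuple[int, int, int]
    hospitalizations_unrounded: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hospitalizations: tuple[int, int, int] = (0, 0, 0)
    workers_full_time: tuple[int, int, int] = (0, 0, 0)
    workers_part_time: tuple[int, int, int] = (0, 0, 0)
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per (severity, quantity)."""
        rows = []
        for quantity in (
            "cases_unrounded",
            "cases",
            "hospitalizations_unrounded",
            "hospitalizations",
            "workers_full_time",
            "workers_part_time",
        ):
            for sev, value in zip(SEVERITIES, getattr(self, quantity)):
                rows.append(
                    {
                        "segment": self.segment,
                        "basis": self.basis,
                        "severity": sev,
                        "quantity": quantity,
                        "value": value,
                    }
                )
        return pd.DataFrame(rows)


def stratify_cases(
    total: float, severity_counts: Sequence[int], n_survey: int
) -> tuple[tuple[float, ...], tuple[int, ...]]:
    """Apportion a national case total to severity strata by survey counts.

    ``cases_unrounded[s] = total * count_s / n_survey``; the integer counts
    are round-half-up of each stratum independently, so stratum sums may
    drift from ``total`` by at most n_strata/2.

    Returns ``(unrounded, rounded)`` triples.
    """
    if n_survey <= 0:
        raise ValueError("n_survey must be positive")
    if total < 0:
        raise ValueError("total must be nonnegative")
    if sum(severity_counts) != n_survey:
        raise ValueError(
            f"severity counts {tuple(severity_counts)} do not sum to n_survey={n_survey}"
        )
    unrounded = tuple(total * c / n_survey for c in severity_counts)
    return unrounded, tuple(round_half_up(u) for u in unrounded)


def split_hospitalizations(
    discharges: int,
    epi: EpiInputs,
    basis: Basis,
    adult_margins: SurveyMargins,
    pediatric_margins: SurveyMargins,
) -> dict[Segment, tuple[tuple[float, ...], tuple[int, ...]]]:
    """Split national hospital discharges by age segment, then severity.

    The segment share is ``discharges * segment_count / basis_total`` on the
    chosen epidemiological basis, kept unrounded; severity then splits the
    share by the segment's own survey fractions.  Integers are
    round-half-up of the *chained unrounded* value.
    """
    if discharges < 0:
        raise ValueError("discharges must be nonnegative")
    total = epi.basis_total(basis)
    if discharges and total == 0:
        raise ZeroDivisionError("basis total is zero but discharges are not")
    out: dict[Segment, tuple[tuple[float, ...], tuple[int, ...]]] = {}
    for segment, margins in (("adult", adult_margins), ("pediatric", pediatric_margins)):
        share = 0.0 if total == 0 else discharges * epi.segment_count(segment, basis) / total
        out[segment] = stratify_cases(share, margins.counts, margins.n)
    return out


def worker_counts(
    cases: Sequence[int],
    ft_shares: Sequence[float],
    pt_shares: Sequence[float],
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """National full-/part-time worker counts per severity stratum.

    ``workers_ft[s] = round_half_up(cases[s] * ft_share[s])`` and likewise
    part-time; the caregiver variant applies caregiver employment shares to
    pediatric case counts.  Shares are fractions of the stratum's cases; a
    full+part share exceeding 1 is tolerated with a warning because national
    reporting sources are not always internally consistent.
    """
    for shares in (ft_shares, pt_shares):
        for s in shares:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"employment share {s} outside [0, 1]")
    for ft, pt, sev in zip(ft_shares, pt_shares, SEVERITIES):
        if ft + pt > 1.0 + 1e-12:
            warnings.warn(
                f"full+part-time share {ft + pt:.3f} exceeds 1 for {sev} stratum",
                stacklevel=2,
            )
    ft = tuple(round_half_up(c * s) for c, s in zip(cases, ft_shares))
    pt = tuple(round_half_up(c * s) for c, s in zip(cases, pt_shares))
    return ft, pt


def build_stratification(
    epi: EpiInputs,
    segment: Segment,
    basis: Basis,
    adult_margins: SurveyMargins,
    pediatric_margins: SurveyMargins,
    ft_shares: Sequence[float] | None = None,
    pt_shares: Sequence[float] | None = None,
) -> SeverityStratification:
    """Assemble the full severity stratification for one segment/basis."""
    margins = adult_margins if segment == "adult" else pediatric_margins
    unrounded, rounded = stratify_cases(
        epi.segment_count(segment, basis), margins.counts, margins.n
    )
    hosp = split_hospitalizations(
        epi.hospital_discharges_total, epi, basis, adult_margins, pediatric_margins
    )[segment]
    strat = SeverityStratification(
        segment=segment,
        basis=basis,
        cases_unrounded=unrounded,
        cases=rounded,
        hospitalizations_unrounded=hosp[0],
        hospitalizations=hosp[1],
    )
    if ft_shares is not None and pt_shares is not None:
        strat.workers_full_time, strat.workers_part_time = worker_counts(
            rounded, ft_shares, pt_shares
        )
    return strat
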