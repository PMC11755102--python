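"""Seeded synthetic survey cohorts.

Generates adult-patient and caregiver-of-pediatric survey tables with the
statistical structure the downstream analysis assumes: exact severity
margins (stratified generation, never i.i.d. sampling), right-skewed
annual cost categories whose per-severity means can be calibrated exactly,
employment classes, missed work/school days, EQ-5D-5L states and EQ-VAS
scores, plus an MNAR deletion mechanism for the adult treatment-cost
column.

Cost draws are log-normal (nonnegative, right-skewed — the conventional
shape for expenditure data) parameterized by a target mean and coefficient
of variation; calibration multiplies each stratum's draw by
``target_mean / sample_mean`` so the sample mean matches the target
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from . import records as rc
from .extrapolate import SEVERITIES

_SIMPLEX_TOL = 1e-9


def _check_simplex(p: Sequence[float], what: str) -> None:
    if any(x < 0 for x in p) or abs(sum(p) - 1.0) > _SIMPLEX_TOL:
        raise ValueError(f"{what} must be a probability simplex, got {list(p)}")


class CohortSpec(BaseModel):
    """Full parameterization of one synthetic survey cohort.

    ``cost_means`` maps severity -> column -> EUR/year; ``cost_cv`` is the
    common coefficient of variation of the log-normal cost draws.
    ``days_means`` maps severity -> employment class -> expected missed
    days/year (Poisson).  ``eq5d_level_probabilities`` maps dimension
    index (0..4) -> simplex over levels 1..5, shared across age bands
    unless a per-band override is supplied in ``vas_by_age`` style.
    """

    kind: str = rc.ADULT_KIND
    n_total: int = Field(ge=0)
    severity_counts: tuple[int, int, int]
    cost_means: dict[str, dict[str, float]]
    cost_cv: float = 0.8
    days_means: dict[str, dict[str, float]]
    employment_probabilities: dict[str, dict[str, float]]
    age_probabilities: dict[str, float]
    eq5d_level_probabilities: dict[int, tuple[float, float, float, float, float]]
    vas_by_age: dict[str, tuple[float, float]]
    mnar_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    mnar_strength: float = 0.0
    seed: int = 0
    calibrate_means: bool = True

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        if sum(self.severity_counts) != self.n_total:
            raise ValueError(
                f"severity counts {self.severity_counts} do not sum to n_total={self.n_total}"
            )
        for sev, cols in self.cost_means.items():
            for col, mean in cols.items():
                if mean < 0:
                    raise ValueError(f"negative cost mean for {sev}/{col}")
        for sev, probs in self.employment_probabilities.items():
            _check_simplex(list(probs.values()), f"employment probabilities[{sev}]")
        _check_simplex(list(self.age_probabilities.values()), "age probabilities")
        for dim, levels in self.eq5d_level_probabilities.items():
            _check_simplex(levels, f"eq5d level probabilities[{dim}]")
        return self


def calibrate_mean(x: np.ndarray, target_mean: float) -> np.ndarray:
    """Rescale a nonnegative sample so its mean equals ``target_mean`` exactly."""
    m = x.mean()
    if m == 0:
        return np.full_like(x, target_mean)
    return x * (target_mean / m)


def calibrate_mean_sd(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affine-rescale a sample to an exact mean and (n-1) standard deviation."""
    s = x.std(ddof=1)
    if s == 0:
        return np.full_like(x, mean)
    return (x - x.mean()) * (sd / s) + mean


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(n)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def generate_cohort(spec: CohortSpec, kind: str | None = None) -> pd.DataFrame:
    """Generate one cohort with exact severity margins.

    Same spec + seed gives byte-identical output.  Caregiver cohorts never
    carry a medical-services column.  With ``calibrate_means`` on, each
    per-severity cost-category sample mean equals the spec mean to within
    1e-9 (multiplicative rescaling after the draw).
    """
    kind = kind or spec.kind
    rng = np.random.default_rng(spec.seed)
    ages = list(spec.age_probabilities)
    age_p = np.array(list(spec.age_probabilities.values()))
    parts: list[pd.DataFrame] = []
    for sev, count in zip(SEVERITIES, spec.severity_counts):
        if count == 0:
            continue
        emp_classes = list(spec.employment_probabilities[sev])
        emp_p = np.array(list(spec.employment_probabilities[sev].values()))
        df = pd.DataFrame(
            {
                rc.RESPONDENT_KIND: kind,
                rc.AGE_GROUP: rng.choice(ages, size=count, p=age_p),
                rc.SEVERITY: sev,
                rc.EMPLOYMENT: rng.choice(emp_classes, size=count, p=emp_p),
            }
        )
        if kind == rc.ADULT_KIND:
            # youngest band: active respondents are workers or students
            young = (df[rc.AGE_GROUP] == rc.ADULT_AGE_GROUPS[0]) & ~df[
                rc.EMPLOYMENT
            ].isin(["full_time", "part_time", "student"])
            df.loc[young, rc.EMPLOYMENT] = "student"
        for col, mean in spec.cost_means[sev].items():
            x = _lognormal(rng, mean, spec.cost_cv, count)
            df[col] = calibrate_mean(x, mean) if spec.calibrate_means else x
        days = np.zeros(count)
        for cls, lam in spec.days_means[sev].items():
            mask = (df[rc.EMPLOYMENT] == cls).to_numpy()
            if mask.any() and lam > 0:
                days[mask] = rng.poisson(lam, size=int(mask.sum()))
        df[rc.DAYS_MISSED] = days
        levels = np.column_stack(
            [
                rng.choice([1, 2, 3, 4, 5], size=count, p=spec.eq5d_level_probabilities[d])
                for d in range(5)
            ]
        )
        df[rc.EQ5D_STATE] = ["".join(map(str, row)) for row in levels]
        vas = np.empty(count)
        for band in ages:
            mask = (df[rc.AGE_GROUP] == band).to_numpy()
            if mask.any():
                mu, sd = spec.vas_by_age[band]
                vas[mask] = rng.normal(mu, sd, size=int(mask.sum()))
        df[rc.EQ_VAS] = np.clip(np.round(vas), 0, 100).astype(int)
        parts.append(df)
    if not parts:
        cols = [
            rc.RESPONDENT_KIND,
            rc.AGE_GROUP,
            rc.SEVERITY,
            rc.EMPLOYMENT,
            rc.DAYS_MISSED,
            rc.EQ5D_STATE,
            rc.EQ_VAS,
        ]
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)


def inject_mnar(
    records: pd.DataFrame,
    rate: float,
    strength: float,
    seed: int,
    column: str = rc.COST_TREATMENT,
) -> pd.DataFrame:
    """Delete ``column`` entries not-at-random.

    The deletion probability is a logistic function of the record's own
    (pre-deletion, standardized) value scaled by ``strength``; the
    intercept is solved so the expected missing fraction equals ``rate``.
    ``strength = 0`` reduces to MCAR.  Pre-deletion values are retained in
    a shadow column so recovery can be scored.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = records.copy()
    out[rc.COST_TREATMENT_TRUE] = out[column]
    if rate == 0.0 or out.empty:
        return out
    x = out[column].to_numpy(dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    def mean_p(intercept: float) -> float:
        return float(expit(intercept + strength * z).mean())

    a = brentq(lambda t: mean_p(t) - rate, -60.0, 60.0)
    rng = np.random.default_rng(seed)
    drop = rng.random(len(out)) < expit(a + strength * z)
    out.loc[drop, column] = np.nan
    return out


# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------

#: per-worker mean absence days consistent with the packaged national totals
_ADULT_DAYS = {
    "mild": {"full_time": 0.833, "part_time": 3.572, "student": 2.0},
    "moderate": {"full_time": 0.903, "part_time": 6.169, "student": 2.0},
    "severe": {"full_time": 2.635, "part_time": 8.332, "student": 3.0},
}
_ADULT_EMPLOYMENT = {
    "full_time": 0.45,
    "part_time": 0.14,
    "unemployed": 0.09,
    "retired_age": 0.12,
    "retired_sickness": 0.05,
    "student": 0.10,
    "other": 0.05,
}
#: plausible band weights consistent with the published per-band frequencies
_ADULT_AGE_P = {
    "18-25": 29,
    "26-35": 32,
    "36-45": 143,
    "46-55": 200,
    "56-65": 63,
    "66-75": 83,
    "75+": 9,
}
_ADULT_EQ5D = {
    0: (0.865, 0.080, 0.035, 0.015, 0.005),  # mobility
    1: (0.380, 0.300, 0.200, 0.080, 0.040),  # self-care
    2: (0.850, 0.080, 0.040, 0.020, 0.010),  # usual activities
    3: (0.320, 0.300, 0.220, 0.110, 0.050),  # pain/discomfort
    4: (0.280, 0.300, 0.220, 0.130, 0.070),  # anxiety/depression
}
_ADULT_VAS = {
    "18-25": (67.24, 24.98),
    "26-35": (70.56, 22.30),
    "36-45": (66.26, 22.12),
    "46-55": (67.0, 21.13),
    "56-65": (66.80, 20.16),
    "66-75": (59.09, 21.54),
    "75+": (65.33, 14.65),
}

_PED_DAYS = {
    "mild": {"full_time": 8.571, "part_time": 0.0},
    "moderate": {"full_time": 11.786, "part_time": 66.968},
    "severe": {"full_time": 10.715, "part_time": 0.0},
}
#: part-time caregiving appears only in the moderate stratum by default
_PED_EMPLOYMENT = {
    "mild": {"full_time": 0.50, "part_time": 0.0, "unemployed": 0.30, "other": 0.20},
    "moderate": {"full_time": 0.43, "part_time": 0.19, "unemployed": 0.24, "other": 0.14},
    "severe": {"full_time": 0.43, "part_time": 0.0, "unemployed": 0.36, "other": 0.21},
}
_PED_AGE_P = {"1-10": 36, "11-17": 21}
_PED_EQ5D = {
    0: (0.880, 0.070, 0.030, 0.015, 0.005),
    1: (0.450, 0.280, 0.180, 0.060, 0.030),
    2: (0.680, 0.180, 0.090, 0.035, 0.015),
    3: (0.480, 0.270, 0.160, 0.060, 0.030),
    4: (0.340, 0.290, 0.210, 0.110, 0.050),
}
_PED_VAS = {"1-10": (76.81, 19.97), "11-17": (66.9, 23.53)}


def _norm(weights: Mapping[str, float]) -> dict[str, float]:
    t = sum(weights.values())
    return {k: v / t for k, v in weights.items()}


def default_adult_spec(seed: int = 0, mnar_rate: float = 0.15, mnar_strength: float = 1.0) -> CohortSpec:
    """Adult cohort under the study conditions: n=622, severity margin
    (141, 368, 113), per-severity mean costs matching the collected input
    averages, MNAR deletion of treatment cost."""
    means = {
        "mild": {rc.COST_TREATMENT: 116.4, rc.COST_MEDICAL_SERVICES: 61.2, rc.COST_ASSOCIATED: 71.3},
        "moderate": {rc.COST_TREATMENT: 125.3, rc.COST_MEDICAL_SERVICES: 158.3, rc.COST_ASSOCIATED: 97.7},
        "severe": {rc.COST_TREATMENT: 266.5, rc.COST_MEDICAL_SERVICES: 371.9, rc.COST_ASSOCIATED: 219.2},
    }
    return CohortSpec(
        kind=rc.ADULT_KIND,
        n_total=622,
        severity_counts=(141, 368, 113),
        cost_means=means,
        days_means=_ADULT_DAYS,
        employment_probabilities={s: _ADULT_EMPLOYMENT for s in SEVERITIES},
        age_probabilities=_norm(_ADULT_AGE_P),
        eq5d_level_probabilities=_ADULT_EQ5D,
        vas_by_age=_ADULT_VAS,
        mnar_rate=mnar_rate,
        mnar_strength=mnar_strength,
        seed=seed,
    )


def default_pediatric_spec(seed: int = 0) -> CohortSpec:
    """Caregiver cohort under the study conditions: n=57, severity margin
    (22, 21, 14); no medical-services category is collected."""
    means = {
        "mild": {rc.COST_TREATMENT: 89.0, rc.COST_ASSOCIATED: 109.0},
        "moderate": {rc.COST_TREATMENT: 131.0, rc.COST_ASSOCIATED: 177.0},
        "severe": {rc.COST_TREATMENT: 206.4, rc.COST_ASSOCIATED: 427.3},
    }
    return CohortSpec(
        kind=rc.CAREGIVER_KIND,
        n_total=57,
        severity_counts=(22, 21, 14),
        cost_means=means,
        days_means=_PED_DAYS,
        employment_probabilities=_PED_EMPLOYMENT,
        age_probabilities=_norm(_PED_AGE_P),
        eq5d_level_probabilities=_PED_EQ5D,
        vas_by_age=_PED_VAS,
        seed=seed,
    )


def write_cohort(df: pd.DataFrame, path: str | Path, spec: CohortSpec | None = None) -> None:
    """Write the survey CSV (empty field = missing) and, when given, the
    generating spec as JSON next to it."""
    path = Path(path)
    df.to_csv(path, index=False)
    if spec is not None:
        path.with_suffix(".spec.json").write_text(json.dumps(spec.model_dump(), indent=2, default=list))


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={rc.EQ5D_STATE: str})
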