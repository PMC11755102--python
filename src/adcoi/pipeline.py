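"""End-to-end orchestration and table rendering.

Two entry points:

* :func:`run_reproduction` — deterministic: feeds the calibrated fixture
  averages and national inputs straight into extrapolation + costing and
  returns all 8 scenario results (2 segments x 4 scenarios).
* :func:`run_pipeline` — the full survey pipeline: generate (or load)
  cohorts, inject/diagnose/impute missing treatment costs, average,
  extrapolate using the survey's own employment structure, cost, and
  summarize EQ-5D; writes tidy CSVs, rendered tables and a manifest.

Renderers only reformat numbers already present in the tidy results; they
never recompute anything.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from pydantic import BaseModel

from . import __version__, records as rc
from .config import NationalInputs, load_national_inputs
from .costing import ScenarioResult, ScenarioSpec, run_scenario
from .eq5d import dimension_frequencies, load_value_set, utility_ranges, vas_summary
from .extrapolate import SEVERITIES, SeverityStratification
from .processing import impute_treatment, severity_averages, test_mcar
from .synth import default_adult_spec, default_pediatric_spec, generate_cohort, inject_mnar

SCENARIOS = (
    ScenarioSpec(basis="prevalence"),
    ScenarioSpec(basis="incidence"),
    ScenarioSpec(basis="prevalence", treatment_source="prescription"),
    ScenarioSpec(basis="incidence", treatment_source="prescription"),
)
SCENARIO_ORDER = tuple(s.label for s in SCENARIOS)


class RunConfig(BaseModel):
    """Paths, scenario list, seed and options for one pipeline run."""

    out_dir: Path
    adult_csv: Path | None = None
    pediatric_csv: Path | None = None
    national_inputs: Path | None = None
    value_set: Path | None = None
    scenarios: tuple[str, ...] = SCENARIO_ORDER
    seed: int = 0
    fx_override: float | None = None

    def model_post_init(self, _ctx) -> None:
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")


def run_reproduction(
    inputs: NationalInputs | None = None,
) -> dict[tuple[str, str], ScenarioResult]:
    """All 8 scenario results from the calibrated fixture inputs."""
    inputs = inputs or load_national_inputs()
    results: dict[tuple[str, str], ScenarioResult] = {}
    for segment in ("adult", "pediatric"):
        for spec in SCENARIOS:
            strat = inputs.stratification(segment, spec.basis)
            averages = inputs.fixture_averages(segment, spec.basis)
            results[(segment, spec.label)] = run_scenario(
                spec, segment, averages, strat, inputs.unit_costs
            )
    return results


# ---------------------------------------------------------------------------
# table renderers
# ---------------------------------------------------------------------------


def _fmt_eur(x: float) -> float:
    return round(float(x), 1)


def render_average_table(results: dict[tuple[str, str], ScenarioResult], segment: str) -> pd.DataFrame:
    """Per-patient average costs by severity, one column per scenario."""
    rows = {"average_all": {}, **{f"average_{s}": {} for s in SEVERITIES}}
    for label in SCENARIO_ORDER:
        r = results.get((segment, label))
        if r is None:
            continue
        rows["average_all"][label] = _fmt_eur(r.average_overall)
        for sev, avg in zip(SEVERITIES, r.average_per_severity):
            rows[f"average_{sev}"][label] = _fmt_eur(avg)
    return pd.DataFrame(rows).T


def render_direct_cost_table(results: dict[tuple[str, str], ScenarioResult], segment: str) -> pd.DataFrame:
    """Total direct costs by severity for both bases (survey + prescription treatment)."""
    rows = []
    for basis in ("prevalence", "incidence"):
        survey = results[(segment, basis)]
        presc = results[(segment, f"{basis}_prescription")]
        for component in ("treatment", "medical_services", "associated"):
            row = {"basis": basis, "component": component}
            for sev, v in zip(SEVERITIES, survey.cells[component]):
                row[sev] = _fmt_eur(v)
            if component == "treatment":
                for sev, v in zip(SEVERITIES, presc.cells[component]):
                    row[f"{sev}_prescription"] = _fmt_eur(v)
            rows.append(row)
    return pd.DataFrame(rows)


def render_productivity_table(results: dict[tuple[str, str], ScenarioResult]) -> pd.DataFrame:
    rows = []
    for segment in ("adult", "pediatric"):
        for sev_i, sev in enumerate(SEVERITIES):
            row = {"segment": segment, "severity": sev}
            for basis in ("prevalence", "incidence"):
                r = results[(segment, basis)]
                row[f"{basis}_full_time"] = _fmt_eur(r.cells["productivity_ft"][sev_i])
                row[f"{basis}_part_time"] = _fmt_eur(r.cells["productivity_pt"][sev_i])
            rows.append(row)
    return pd.DataFrame(rows)


def render_hospitalization_table(results: dict[tuple[str, str], ScenarioResult]) -> pd.DataFrame:
    rows = []
    for sev_i, sev in enumerate(SEVERITIES):
        row = {"severity": sev}
        for segment in ("adult", "pediatric"):
            for basis in ("prevalence", "incidence"):
                r = results[(segment, basis)]
                row[f"{segment}_{basis}"] = _fmt_eur(r.cells["hospitalization"][sev_i])
        rows.append(row)
    return pd.DataFrame(rows)


def render_input_averages_table(averages_by_segment: dict[str, "object"]) -> pd.DataFrame:
    rows = []
    for label, col in (
        ("treatment", "cost_treatment"),
        ("medical_services", "cost_medical_services"),
        ("associated", "cost_associated"),
    ):
        row = {"cost": label}
        for segment, av in averages_by_segment.items():
            vals = getattr(av, col)
            for sev, v in zip(SEVERITIES, vals or (0.0, 0.0, 0.0)):
                row[f"{segment}_{sev}"] = round(float(v), 1)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineBundle:
    """Everything one pipeline run produced, plus the output manifest."""

    results: dict[tuple[str, str], ScenarioResult]
    averages: dict[str, object]
    stratifications: dict[tuple[str, str], SeverityStratification]
    missingness: object | None
    tables: dict[str, pd.DataFrame]
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> PipelineBundle:
    """Execute synth (optional) -> process -> extrapolate -> cost -> eq5d.

    Any stage failure aborts with a stage-labelled error and removes the
    partially-written output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        bundle = _run_stages(config, out, written)
    except StageError:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return bundle


def _run_stages(config: RunConfig, out: Path, written: list[Path]) -> PipelineBundle:
    stage = "synth"
    try:
        if config.adult_csv is not None:
            adult = pd.read_csv(config.adult_csv, dtype={rc.EQ5D_STATE: str})
        else:
            spec = default_adult_spec(seed=config.seed)
            adult = generate_cohort(spec)
            adult = inject_mnar(adult, spec.mnar_rate, spec.mnar_strength, seed=config.seed + 1)
        if config.pediatric_csv is not None:
            pediatric = pd.read_csv(config.pediatric_csv, dtype={rc.EQ5D_STATE: str})
        else:
            pediatric = generate_cohort(default_pediatric_spec(seed=config.seed + 2))
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, e) from e

    stage = "process"
    try:
        report = None
        if adult[rc.COST_TREATMENT].isna().any():
            report = test_mcar(
                adult, covariates=[rc.SEVERITY, rc.COST_ASSOCIATED, rc.DAYS_MISSED]
            )
            adult = impute_treatment(adult, seed=config.seed + 3).completed
        averages = {
            "adult": severity_averages(adult, "adult"),
            "pediatric": severity_averages(pediatric, "pediatric"),
        }
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "extrapolate+cost"
    try:
        inputs = load_national_inputs(config.national_inputs)
        if config.fx_override is not None:
            inputs.unit_costs = inputs.unit_costs.model_copy(update={"fx": config.fx_override})
        results: dict[tuple[str, str], ScenarioResult] = {}
        strats: dict[tuple[str, str], SeverityStratification] = {}
        from .extrapolate import build_stratification  # local to avoid cycle in docs

        for segment, av in averages.items():
            for spec in SCENARIOS:
                if spec.label not in config.scenarios:
                    continue
                strat = build_stratification(
                    inputs.epi,
                    segment,
                    spec.basis,
                    inputs.margins["adult"],
                    inputs.margins["pediatric"],
                    ft_shares=av.employment_share_full_time,
                    pt_shares=av.employment_share_part_time,
                )
                strats[(segment, spec.basis)] = strat
                results[(segment, spec.label)] = run_scenario(
                    spec, segment, av, strat, inputs.unit_costs
                )
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "eq5d"
    try:
        vs = load_value_set(config.value_set)
        eq_tables = {}
        for segment, df in (("adult", adult), ("pediatric", pediatric)):
            eq_tables[f"eq5d_frequencies_{segment}"] = dimension_frequencies(df, rc.AGE_GROUP)
            eq_tables[f"eq_vas_{segment}"] = vas_summary(df, rc.AGE_GROUP)
            eq_tables[f"eq5d_utilities_{segment}"] = utility_ranges(df, vs, rc.SEVERITY)
    except Exception as e:
        raise StageError(stage, e) from e

    stage = "report"
    try:
        tables: dict[str, pd.DataFrame] = {
            "averages_adult": render_average_table(results, "adult"),
            "averages_pediatric": render_average_table(results, "pediatric"),
            "direct_costs_adult": render_direct_cost_table(results, "adult"),
            "direct_costs_pediatric": render_direct_cost_table(results, "pediatric"),
            "productivity": render_productivity_table(results),
            "hospitalization": render_hospitalization_table(results),
            "input_averages": render_input_averages_table(averages),
            **eq_tables,
        }
        tidy = pd.concat([r.to_frame() for r in results.values()], ignore_index=True)
        tidy_path = out / "scenario_cells.csv"
        tidy.to_csv(tidy_path, index=False)
        written.append(tidy_path)
        strat_frames = pd.concat([s.to_frame() for s in strats.values()], ignore_index=True)
        strat_path = out / "stratification.csv"
        strat_frames.to_csv(strat_path, index=False)
        written.append(strat_path)
        for name, df in tables.items():
            p = out / f"table_{name}.csv"
            df.to_csv(p, index=name.startswith("averages"))
            written.append(p)
        if report is not None:
            p = out / "missingness.json"
            p.write_text(json.dumps(report.to_dict(), indent=2))
            written.append(p)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "scenarios": list(config.scenarios),
            "inputs": {
                "national_inputs": str(config.national_inputs or "packaged:romania_2022.yaml"),
                "value_set": str(config.value_set or "packaged:valueset_synthetic.csv"),
                "adult_rows": len(adult),
                "pediatric_rows": len(pediatric),
            },
            "checksums": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as e:
        raise StageError(stage, e) from e

    return PipelineBundle(
        results=results,
        averages=averages,
        stratifications=strats,
        missingness=report,
        tables=tables,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# reproduction diff
# ---------------------------------------------------------------------------


def load_expected() -> dict:
    with resources.as_file(
        resources.files("adcoi.data") / "expected_romania_2022.json"
    ) as p:
        return json.loads(p.read_text())


def reproduce(
    inputs: NationalInputs | None = None,
    count_tol: int = 0,
    rel_tol: float = 0.002,
) -> pd.DataFrame:
    """Recompute everything from the packaged inputs and diff against the
    packaged national reference values.

    Counts must match exactly; monetary quantities within ``rel_tol``
    (reference values are printed at coarser precision than the chain that
    produced them).  Returns a tidy diff with a boolean ``ok`` column.
    """
    inputs = inputs or load_national_inputs()
    expected = load_expected()
    results = run_reproduction(inputs)
    rows = []

    def add(name: str, computed: float, reference: float, kind: str) -> None:
        if kind == "count":
            ok = abs(computed - reference) <= count_tol
        else:
            denom = max(abs(reference), 1e-9)
            ok = abs(computed - reference) / denom <= rel_tol
        rows.append(
            {"quantity": name, "computed": computed, "reference": reference, "ok": ok}
        )

    for segment in ("adult", "pediatric"):
        for basis in ("prevalence", "incidence"):
            strat = inputs.stratification(segment, basis)
            for sev_i, sev in enumerate(SEVERITIES):
                add(f"cases_{segment}_{basis}_{sev}", strat.cases[sev_i],
                    expected["cases"][segment][basis][sev_i], "count")
                add(f"hospitalizations_{segment}_{basis}_{sev}", strat.hospitalizations[sev_i],
                    expected["hospitalizations"][segment][basis][sev_i], "count")
                add(f"workers_ft_{segment}_{basis}_{sev}", strat.workers_full_time[sev_i],
                    expected["workers_full_time"][segment][basis][sev_i], "count")
                add(f"workers_pt_{segment}_{basis}_{sev}", strat.workers_part_time[sev_i],
                    expected["workers_part_time"][segment][basis][sev_i], "count")
        for label in SCENARIO_ORDER:
            r = results[(segment, label)]
            add(f"grand_total_{segment}_{label}", r.grand_total,
                expected["grand_totals"][segment][label], "eur")
            add(f"average_overall_{segment}_{label}", r.average_overall,
                expected["average_overall"][segment][label], "eur")
            for sev_i, sev in enumerate(SEVERITIES):
                add(f"average_{segment}_{label}_{sev}", r.average_per_severity[sev_i],
                    expected["average_per_severity"][segment][label][sev_i], "eur")
    return pd.DataFrame(rows)
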