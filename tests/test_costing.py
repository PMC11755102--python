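"""Costing engine: unit operations and scenario assembly."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcoi.costing import (
    COMPONENTS,
    ScenarioSpec,
    UnitCosts,
    component_total,
    hospitalization_total,
    prescription_treatment_total,
    productivity_total,
    ron_to_eur,
    run_scenario,
)
from adcoi.extrapolate import SeverityStratification
from adcoi.processing import SeverityAverages

UNIT = UnitCosts()


class TestUnitOps:
    def test_ron_to_eur(self):
        assert ron_to_eur(0.0, 4.9315) == 0.0
        # national prescription average and gross wage convert to the
        # published EUR figures at the 2022 annual-average rate
        assert ron_to_eur(40.4, 4.9315) == pytest.approx(8.19, abs=0.005)
        assert ron_to_eur(6126.0, 4.9315) == pytest.approx(1242.27, abs=0.1)
        with pytest.raises(ValueError):
            ron_to_eur(1.0, 0.0)

    @pytest.mark.parametrize(
        "mean,cases,expected,rtol",
        [
            (266.5, 9593, 2_556_162.1, 1e-3),  # severe treatment, prevalent adults
            (427.3, 25245, 10_787_181.0, 1e-4),  # severe associated, prevalent pediatric
            (123.4, 0, 0.0, 0),
        ],
    )
    def test_component_total(self, mean, cases, expected, rtol):
        assert component_total(mean, cases) == pytest.approx(expected, rel=rtol or None, abs=1e-12)

    @pytest.mark.parametrize(
        "cases,expected",
        [(11969, 98_057.0), (102783, 842_056.5), (0, 0.0)],
    )
    def test_prescription_treatment_total(self, cases, expected):
        assert prescription_treatment_total(cases, UNIT) == pytest.approx(expected, rel=2e-3)

    @pytest.mark.parametrize(
        "hosp,segment,expected",
        [
            (92.99, "adult", 164_041.3),
            (196.15, "pediatric", 178_746.64),
            (0.0, "adult", 0.0),
        ],
    )
    def test_hospitalization_total(self, hosp, segment, expected):
        assert hospitalization_total(hosp, segment, UNIT) == pytest.approx(expected, rel=2e-3)

    def test_hospitalization_per_stay_reading(self):
        unit = UNIT.model_copy(update={"hospital_cost_basis": "per_stay"})
        assert hospitalization_total(100, "adult", unit) == pytest.approx(
            100 * 1094 / 4.9315
        )

    def test_productivity_round_trip(self):
        """Workers x back-solved mean days recovers the published moderate
        full-time productivity total."""
        assert productivity_total(17125, 0.90271, "full_time", UNIT) == pytest.approx(
            918_088.9, rel=1e-3
        )

    def test_productivity_zero_days(self):
        assert productivity_total(1000, 0.0, "full_time", UNIT) == 0.0

    def test_part_time_is_half_full_time(self):
        ft = productivity_total(500, 3.0, "full_time", UNIT)
        pt = productivity_total(500, 3.0, "part_time", UNIT)
        assert pt == pytest.approx(ft / 2.0, rel=1e-12)

    def test_unknown_employment_class(self):
        with pytest.raises(ValueError):
            productivity_total(1, 1.0, "gig_economy", UNIT)

    def test_unit_costs_validation(self):
        with pytest.raises(ValueError):
            UnitCosts(fx=-1)
        with pytest.raises(ValueError):
            UnitCosts(part_time_monthly_wage=7000.0)


def _averages(segment="adult", zero=False):
    v = (0.0, 0.0, 0.0) if zero else (10.0, 20.0, 30.0)
    return SeverityAverages(
        segment=segment,
        n=(141, 368, 113),
        cost_treatment=v,
        cost_medical_services=None if segment == "pediatric" else v,
        cost_associated=v,
        employment_share_full_time=(0.4, 0.4, 0.4),
        employment_share_part_time=(0.1, 0.1, 0.1),
        days_missed_full_time=v,
        days_missed_part_time=v,
    )


def _strat(segment="adult", basis="prevalence", scale=1):
    cases = (100 * scale, 200 * scale, 50 * scale)
    return SeverityStratification(
        segment=segment,
        basis=basis,
        cases_unrounded=tuple(float(c) for c in cases),
        cases=cases,
        hospitalizations_unrounded=(2.0 * scale, 4.0 * scale, 1.0 * scale),
        hospitalizations=(2 * scale, 4 * scale, 1 * scale),
        workers_full_time=(40 * scale, 80 * scale, 20 * scale),
        workers_part_time=(10 * scale, 20 * scale, 5 * scale),
    )


class TestRunScenario:
    def test_additivity(self):
        r = run_scenario(ScenarioSpec(basis="prevalence"), "adult", _averages(), _strat(), UNIT)
        assert r.grand_total == pytest.approx(sum(r.component_totals.values()), abs=0.01)
        assert set(r.cells) == set(COMPONENTS)

    def test_basis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="basis"):
            run_scenario(
                ScenarioSpec(basis="incidence"), "adult", _averages(), _strat(), UNIT
            )

    def test_pediatric_medical_services_forced_zero(self):
        r = run_scenario(
            ScenarioSpec(basis="prevalence"),
            "pediatric",
            _averages("pediatric"),
            _strat("pediatric"),
            UNIT,
        )
        assert r.cells["medical_services"] == (0.0, 0.0, 0.0)

    def test_zero_averages_leave_only_hospitalization(self):
        r = run_scenario(
            ScenarioSpec(basis="prevalence"), "adult", _averages(zero=True), _strat(), UNIT
        )
        for comp in COMPONENTS:
            if comp != "hospitalization":
                assert r.component_totals[comp] == 0.0
        assert r.component_totals["hospitalization"] > 0

    def test_scenario_coupling_only_treatment_differs(self):
        survey = run_scenario(ScenarioSpec(basis="prevalence"), "adult", _averages(), _strat(), UNIT)
        presc = run_scenario(
            ScenarioSpec(basis="prevalence", treatment_source="prescription"),
            "adult",
            _averages(),
            _strat(),
            UNIT,
        )
        for comp in COMPONENTS:
            if comp == "treatment":
                assert survey.cells[comp] != presc.cells[comp]
            else:
                assert survey.cells[comp] == presc.cells[comp]

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.integers(min_value=2, max_value=50))
    def test_homogeneity_degree_one_in_counts(self, scale):
        """Scaling every count scales every total; averages are invariant."""
        base = run_scenario(ScenarioSpec(basis="prevalence"), "adult", _averages(), _strat(), UNIT)
        big = run_scenario(
            ScenarioSpec(basis="prevalence"), "adult", _averages(), _strat(scale=scale), UNIT
        )
        assert big.grand_total == pytest.approx(scale * base.grand_total, rel=1e-12)
        assert big.average_overall == pytest.approx(base.average_overall, rel=1e-12)

    def test_currency_order_invariance(self):
        """Computing fx-dependent components in RON then converting equals
        computing with the configured rate directly."""
        ron_unit = UNIT.model_copy(update={"fx": 1.0})
        fx = UNIT.fx
        for segment in ("adult", "pediatric"):
            assert hospitalization_total(7.3, segment, UNIT) == pytest.approx(
                hospitalization_total(7.3, segment, ron_unit) / fx, rel=1e-12
            )
        assert prescription_treatment_total(123, UNIT) == pytest.approx(
            prescription_treatment_total(123, ron_unit) / fx, rel=1e-12
        )
        assert productivity_total(10, 2.5, "part_time", UNIT) == pytest.approx(
            productivity_total(10, 2.5, "part_time", ron_unit) / fx, rel=1e-12
        )
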