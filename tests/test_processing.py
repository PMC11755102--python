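"""Missingness diagnosis, chained-equations imputation, input averages."""

import numpy as np
import pandas as pd
import pytest

from adcoi import records as rc
from adcoi.processing import (
    impute_treatment,
    little_mcar_test,
    severity_averages,
    test_mcar,
)
from adcoi.synth import default_adult_spec, generate_cohort, inject_mnar

COVARS = [rc.SEVERITY, rc.COST_ASSOCIATED, rc.DAYS_MISSED]


def _mvn_frame(n, rng, corr=0.5):
    cov = np.full((4, 4), corr) + (1 - corr) * np.eye(4)
    x = rng.multivariate_normal(np.zeros(4), cov, size=n)
    return pd.DataFrame(x, columns=["y", "a", "b", "c"])


class TestLittleMcar:
    def test_no_missing_is_degenerate(self, rng):
        df = _mvn_frame(100, rng)
        stat, df_, p = little_mcar_test(df)
        assert (stat, df_, p) == (0.0, 1, 1.0)

    def test_all_missing_rejected(self):
        df = pd.DataFrame({"y": [np.nan, np.nan], "a": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            little_mcar_test(df)

    def test_affine_invariance_of_statistic(self, rng):
        """The chi-square is invariant to affine rescaling of covariates."""
        df = _mvn_frame(400, rng)
        df.loc[rng.random(400) < 0.2, "y"] = np.nan
        s1, d1, _ = little_mcar_test(df)
        scaled = df.copy()
        scaled["a"] = scaled["a"] * 1000.0 + 5.0
        scaled["b"] = scaled["b"] * -0.01 + 2.0
        s2, d2, _ = little_mcar_test(scaled)
        assert d1 == d2
        assert s1 == pytest.approx(s2, rel=1e-8)

    def test_detects_pattern_mean_shift(self, rng):
        """Deleting the largest values shifts pattern means -> rejection."""
        df = _mvn_frame(2000, rng)
        df.loc[df["y"] > df["y"].quantile(0.75), "y"] = np.nan
        _, _, p = little_mcar_test(df)
        assert p < 1e-6


class TestTestMcar:
    def test_no_missing_concludes_mcar(self, adult_cohort):
        report = test_mcar(adult_cohort, covariates=COVARS)
        assert report.conclusion == "MCAR"
        assert report.mcar_statistic == 0.0 and report.mcar_p == 1.0

    def test_requires_two_covariates(self, adult_cohort):
        with pytest.raises(ValueError):
            test_mcar(adult_cohort, covariates=[rc.SEVERITY])

    def test_power_against_value_dependent_deletion(self):
        """Strong MNAR deletion at n=5,000 is flagged (conclusion != MCAR)
        in at least 95% of replicates."""
        spec = default_adult_spec(seed=0)
        base = generate_cohort(spec)
        big = pd.concat([base] * 9, ignore_index=True)  # n = 5,598
        flagged = 0
        n_rep = 20
        for i in range(n_rep):
            out = inject_mnar(big, 0.25, 3.0, seed=100 + i)
            report = test_mcar(out, covariates=COVARS)
            flagged += report.conclusion != "MCAR"
        assert flagged >= int(np.ceil(0.95 * n_rep))


class TestImputeTreatment:
    def test_no_missing_is_identity(self, adult_cohort):
        res = impute_treatment(adult_cohort, seed=1)
        pd.testing.assert_frame_equal(res.completed, adult_cohort)
        assert res.imputations.empty

    def test_observed_cells_never_altered(self, adult_cohort):
        out = inject_mnar(adult_cohort, 0.2, 1.0, seed=2)
        res = impute_treatment(out, m=3, iterations=3, seed=3)
        observed = out[rc.COST_TREATMENT].notna()
        pd.testing.assert_series_equal(
            res.completed.loc[observed, rc.COST_TREATMENT],
            out.loc[observed, rc.COST_TREATMENT],
        )

    def test_pmm_draws_are_observed_donor_values(self, adult_cohort):
        """Every per-imputation value is one of the observed donor values."""
        out = inject_mnar(adult_cohort, 0.2, 1.0, seed=2)
        res = impute_treatment(out, m=3, iterations=3, seed=3)
        donors = set(out[rc.COST_TREATMENT].dropna())
        for col in res.imputations.columns:
            assert set(res.imputations[col]).issubset(donors)

    def test_deterministic_under_seed(self, adult_cohort):
        out = inject_mnar(adult_cohort, 0.2, 1.0, seed=2)
        a = impute_treatment(out, m=2, iterations=2, seed=7).completed
        b = impute_treatment(out, m=2, iterations=2, seed=7).completed
        pd.testing.assert_frame_equal(a, b)

    def test_zero_variance_predictor_dropped_with_warning(self, adult_cohort):
        out = inject_mnar(adult_cohort, 0.2, 0.0, seed=2).copy()
        out["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = impute_treatment(
                out,
                m=2,
                iterations=2,
                seed=4,
                predictors=[rc.SEVERITY, rc.COST_ASSOCIATED, "flat"],
            )
        assert res.dropped_predictors == ["flat"]

    def test_all_missing_rejected(self, adult_cohort):
        broken = adult_cohort.copy()
        broken[rc.COST_TREATMENT] = np.nan
        with pytest.raises(ValueError):
            impute_treatment(broken)


class TestSeverityAverages:
    def test_single_record_mean_of_one(self):
        df = pd.DataFrame(
            {
                rc.SEVERITY: ["mild"],
                rc.EMPLOYMENT: ["full_time"],
                rc.COST_TREATMENT: [10.0],
                rc.COST_MEDICAL_SERVICES: [20.0],
                rc.COST_ASSOCIATED: [30.0],
                rc.DAYS_MISSED: [4.0],
            }
        )
        with pytest.warns(UserWarning, match="empty"):
            av = severity_averages(df, "adult")
        assert av.cost_treatment[0] == 10.0
        assert av.cost_medical_services[0] == 20.0
        assert av.cost_associated[0] == 30.0
        assert av.employment_share_full_time[0] == 1.0
        assert av.days_missed_full_time[0] == 4.0
        assert av.n == (1, 0, 0)
        assert "empty stratum: moderate" in av.flags

    def test_calibrated_adult_cohort_recovers_input_averages(self, adult_cohort):
        av = severity_averages(adult_cohort, "adult")
        assert av.cost_treatment == pytest.approx((116.4, 125.3, 266.5), abs=1e-9)
        assert av.cost_medical_services == pytest.approx((61.2, 158.3, 371.9), abs=1e-9)

    def test_calibrated_pediatric_cohort(self, pediatric_cohort):
        av = severity_averages(pediatric_cohort, "pediatric")
        assert av.cost_associated == pytest.approx((109.0, 177.0, 427.3), abs=1e-9)
        assert av.cost_medical_services is None

    def test_permutation_invariance(self, adult_cohort):
        shuffled = adult_cohort.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = severity_averages(adult_cohort, "adult")
        b = severity_averages(shuffled, "adult")
        assert a.cost_treatment == pytest.approx(b.cost_treatment, rel=1e-12)
        assert a.employment_share_full_time == pytest.approx(
            b.employment_share_full_time, rel=1e-12
        )

    def test_employment_shares_bounded(self, adult_cohort):
        av = severity_averages(adult_cohort, "adult")
        for ft, pt in zip(av.employment_share_full_time, av.employment_share_part_time):
            assert 0.0 <= ft <= 1.0 and 0.0 <= pt <= 1.0 and ft + pt <= 1.0

    def test_round_trip_via_dict(self, adult_cohort):
        av = severity_averages(adult_cohort, "adult")
        from adcoi.processing import SeverityAverages

        again = SeverityAverages.from_dict(av.to_dict())
        assert again == av
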