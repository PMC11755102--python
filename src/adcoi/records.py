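"""Shared survey-record schema.

Survey data travels through the pipeline as a pandas DataFrame with the
columns below; the CSV dialect is one header row, one record per line and
an empty field for a missing value.  Medical-services cost is collected
only for adult respondents, so pediatric (caregiver-reported) tables omit
that column entirely.
"""

from __future__ import annotations

RESPONDENT_KIND = "respondent_kind"
AGE_GROUP = "age_group"
SEVERITY = "severity"
EMPLOYMENT = "employment"
COST_TREATMENT = "cost_treatment"
COST_MEDICAL_SERVICES = "cost_medical_services"
COST_ASSOCIATED = "cost_associated"
DAYS_MISSED = "days_missed"
EQ5D_STATE = "eq5d_state"
EQ_VAS = "eq_vas"
#: shadow column kept by the MNAR injector so recovery can be scored
COST_TREATMENT_TRUE = "cost_treatment_true"

ADULT_KIND = "adult_patient"
CAREGIVER_KIND = "caregiver_of_pediatric"

ADULT_AGE_GROUPS = ("18-25", "26-35", "36-45", "46-55", "56-65", "66-75", "75+")
PEDIATRIC_AGE_GROUPS = ("1-10", "11-17")

EMPLOYMENT_CLASSES = (
    "full_time",
    "part_time",
    "unemployed",
    "retired_age",
    "retired_sickness",
    "student",
    "other",
)

COST_COLUMNS = (COST_TREATMENT, COST_MEDICAL_SERVICES, COST_ASSOCIATED)
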