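"""Shared column names, category orders and default effect sizes.

The person and division tables are plain pandas DataFrames; this module is
the single source of truth for their schemas so that the generator, the
rate calculator and the model builder stay in sync.
"""

from __future__ import annotations

DRUG_CLASSES: tuple[str, ...] = (
    "antidepressant",
    "stimulant",
    "antipsychotic",
    "benzodiazepine",
)

#: pseudo-class aggregating all four (a person counts once)
ALL_CLASSES = "all"

AGE_BANDS: tuple[str, ...] = ("0-4", "5-9", "10-14", "15-19", "20-24")
AGE_BAND_REF = "5-9"
AGE_BAND_EDGES = {"0-4": (0, 4), "5-9": (5, 9), "10-14": (10, 14),
                  "15-19": (15, 19), "20-24": (20, 24)}

SEXES: tuple[str, ...] = ("female", "male")
SEX_REF = "female"

RURALITIES: tuple[str, ...] = ("urban", "rural")
RURALITY_REF = "urban"

INCOME_QUINTILES: tuple[int, ...] = (1, 2, 3, 4, 5)
INCOME_REF = 1

ADG_BANDS: tuple[str, ...] = ("0-5", "6-9", "10+")
ADG_BAND_REF = "0-5"

#: division-level covariate columns on the divisions table
DIVISION_COVARIATES: tuple[str, ...] = (
    "specialist_density",       # per 100,000 population
    "agency_density",           # per 1,000 population
    "mh_admission_ed_rate",     # per 1,000 population
    "pct_postsecondary",
    "pct_visible_minority",
    "mean_household_size",
    "pct_noncitizen",
    "pct_employed",
    "pct_neither_language",
)

PERSON_ID = "person_id"
DIVISION_ID = "division_id"
WEIGHT = "weight"
ANY_PSYCHOTROPIC = "any_psychotropic"


def disp_col(drug_class: str) -> str:
    """Name of the 0/1 dispensing-indicator column for a class."""
    return f"disp_{drug_class}"


def rx_col(drug_class: str) -> str:
    """Name of the prescription-count column for a class."""
    return f"rx_{drug_class}"


def other_col(drug_class: str) -> str:
    """Indicator that the person received any *different* psychotropic class."""
    return f"other_{drug_class}"


def pop_col(age_band: str, sex: str) -> str:
    """Stratum population column on the divisions table."""
    return f"pop_{age_band}_{sex}"


PERSON_COLUMNS: tuple[str, ...] = (
    PERSON_ID, DIVISION_ID, "age_years", "age_band", "sex",
    "income_quintile", "rurality", "adg_count", "adg_band",
    *[disp_col(c) for c in DRUG_CLASSES],
    ANY_PSYCHOTROPIC,
    *[rx_col(c) for c in DRUG_CLASSES],
    *[other_col(c) for c in DRUG_CLASSES],
    WEIGHT,
)

DIVISION_COLUMNS: tuple[str, ...] = (
    DIVISION_ID,
    *[pop_col(b, s) for b in AGE_BANDS for s in SEXES],
    *DIVISION_COVARIATES,
)

#: default covariate rate ratios (per drug class); generator truth and the
#: reference values used by recovery tests.  Levels not listed are reference
#: levels with RR 1.  Values are on the rate-ratio scale.
DEFAULT_COVARIATE_RR: dict[str, dict[str, dict] ] = {
    "antidepressant": {
        "age_band": {"0-4": 0.02, "10-14": 4.56, "15-19": 8.73, "20-24": 9.32},
        "sex": {"male": 0.81},
        "rurality": {"rural": 0.95},
        "income_quintile": {2: 1.01, 3: 0.98, 4: 0.98, 5: 0.97},
        "adg_band": {"6-9": 1.53, "10+": 1.73},
    },
    "antipsychotic": {
        "age_band": {"0-4": 0.14, "10-14": 1.25, "15-19": 1.53, "20-24": 1.80},
        "sex": {"male": 1.40},
        "rurality": {"rural": 0.90},
        "income_quintile": {2: 0.88, 3: 0.81, 4: 0.75, 5: 0.72},
        "adg_band": {"6-9": 1.77, "10+": 2.33},
    },
    "benzodiazepine": {
        "age_band": {"0-4": 0.46, "10-14": 2.89, "15-19": 8.60, "20-24": 12.37},
        "sex": {"male": 0.85},
        "rurality": {"rural": 0.94},
        "income_quintile": {2: 1.01, 3: 0.98, 4: 1.00, 5: 1.01},
        "adg_band": {"6-9": 1.82, "10+": 2.61},
    },
    "stimulant": {
        "age_band": {"0-4": 0.04, "10-14": 1.11, "15-19": 0.81, "20-24": 0.61},
        "sex": {"male": 1.75},
        "rurality": {"rural": 0.91},
        "income_quintile": {2: 0.97, 3: 0.95, 4: 0.95, 5: 1.00},
        "adg_band": {"6-9": 1.50, "10+": 1.71},
    },
}

#: default baseline (reference-pattern) dispensing rates per 1,000
DEFAULT_BASELINE_RATES: dict[str, float] = {
    "antidepressant": 47.8,
    "stimulant": 28.4,
    "antipsychotic": 13.5,
    "benzodiazepine": 9.7,
}
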