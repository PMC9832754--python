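import numpy as np
import pandas as pd
import pytest

from dispvar import schema
from dispvar.synthetic import GeneratorConfig, generate


def zero_effect_log_rr():
    """All covariate effects switched off."""
    return {c: {} for c in schema.DRUG_CLASSES}


@pytest.fixture(scope="session")
def small_cohort():
    """Medium synthetic cohort shared by read-only tests."""
    cfg = GeneratorConfig(
        n_divisions=12,
        division_population_range=(2_000, 20_000),
        total_population=60_000,
        division_effect_sd=0.2,
        seed=3,
    )
    with pytest.warns(RuntimeWarning):
        persons, divisions = generate(cfg)
    return persons, divisions


@pytest.fixture()
def tiny_persons():
    """Hand-built one-division table: 10 recipients + 19 sampled non-recipients.

    True population 10 + 190 = 200; crude any-psychotropic rate 50/1000.
    """
    rows = []
    for i in range(10):
        rows.append(_person(f"P{i:03d}", "D001", disp={"antidepressant": 1}, weight=1.0))
    for i in range(10, 29):
        rows.append(_person(f"P{i:03d}", "D001", disp={}, weight=10.0))
    return pd.DataFrame(rows, columns=list(schema.PERSON_COLUMNS))


def _person(pid, div, disp, weight, age=12, sex="female", inc=1,
            rural="urban", adg=2):
    band = next(b for b, (lo, hi) in schema.AGE_BAND_EDGES.items() if lo <= age <= hi)
    d = {c: int(disp.get(c, 0)) for c in schema.DRUG_CLASSES}
    rec = {
        schema.PERSON_ID: pid,
        schema.DIVISION_ID: div,
        "age_years": age,
        "age_band": band,
        "sex": sex,
        "income_quintile": inc,
        "rurality": rural,
        "adg_count": adg,
        "adg_band": "0-5" if adg <= 5 else ("6-9" if adg <= 9 else "10+"),
        schema.ANY_PSYCHOTROPIC: max(d.values()),
        schema.WEIGHT: weight,
    }
    for c in schema.DRUG_CLASSES:
        rec[schema.disp_col(c)] = d[c]
        rec[schema.rx_col(c)] = d[c]
        rec[schema.other_col(c)] = max(v for k, v in d.items() if k != c)
    return rec


@pytest.fixture()
def make_person():
    return _person


@pytest.fixture()
def tiny_divisions():
    row = {schema.DIVISION_ID: "D001"}
    for b in schema.AGE_BANDS:
        for s in schema.SEXES:
            row[schema.pop_col(b, s)] = 20
    for cov in schema.DIVISION_COVARIATES:
        row[cov] = 1.0
    return pd.DataFrame([row], columns=list(schema.DIVISION_COLUMNS))


def divisions_for(persons: pd.DataFrame) -> pd.DataFrame:
    """Minimal divisions table covering the division ids in *persons*."""
    rows = []
    rng = np.random.default_rng(0)
    for i, div in enumerate(sorted(persons[schema.DIVISION_ID].unique())):
        row = {schema.DIVISION_ID: div}
        for b in schema.AGE_BANDS:
            for s in schema.SEXES:
                row[schema.pop_col(b, s)] = 10
        for cov in schema.DIVISION_COVARIATES:
            row[cov] = float(rng.uniform(0.5, 2.0))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(schema.DIVISION_COLUMNS))
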