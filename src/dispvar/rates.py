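"""Crude and age/sex-standardized dispensing rates per census division.

Rates are computed from the weighted person table: the numerator for a
division/class is the weighted count of persons dispensed that class (or
the weighted prescription count, in ``prescriptions`` mode) and the
denominator is the weighted person count, so the 10%-sampled non-recipient
rows scale back up to population totals.

Direct standardization re-weights a division's stratum-specific rates by
the reference population's age-by-sex shares.  Indirect expected counts
``E_i`` (reference stratum rates applied to the division's own strata) are
computed alongside because the systematic-component-of-variation statistic
and the per-division chi-square tests consume observed/expected pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema
from .schema import AGE_BANDS, ALL_CLASSES, DRUG_CLASSES, SEXES

__all__ = [
    "ReferenceStructure", "SubgroupProportion", "stratum_table",
    "make_reference", "crude_rates", "standardize", "compute_rates",
    "subgroup_proportion", "proportion_from_counts",
]

log = logging.getLogger(__name__)

RATE_CLASSES: tuple[str, ...] = (ALL_CLASSES, *DRUG_CLASSES)

RATES_COLUMNS = ("division_id", "drug_class", "observed", "population",
                 "expected", "crude_per_1000", "standardized_per_1000")


@dataclass(frozen=True)
class ReferenceStructure:
    """Reference age-by-sex structure: population shares and stratum rates.

    ``table`` is indexed by (age_band, sex) with a ``share`` column summing
    to 1 and one events-per-person rate column per drug class (plus "all").
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.empty:
            raise ValueError("reference structure is empty")
        total = float(self.table["share"].sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reference shares must sum to 1 (got {total!r})")
        rate_cols = [c for c in self.table.columns if c != "share"]
        if (self.table[rate_cols] < 0).any().any():
            raise ValueError("reference stratum rates must be >= 0")

    @property
    def classes(self) -> list[str]:
        return [c for c in self.table.columns if c != "share"]


@dataclass(frozen=True)
class SubgroupProportion:
    numerator: float
    denominator: float

    @property
    def percentage(self) -> float:
        """Percentage rounded to one decimal (reporting convention)."""
        return round(100.0 * self.numerator / self.denominator, 1)


def _numerator_column(drug_class: str, numerator_mode: str) -> list[str]:
    if numerator_mode not in ("persons", "prescriptions"):
        raise ValueError(f"numerator_mode must be 'persons' or 'prescriptions', got {numerator_mode!r}")
    if drug_class == ALL_CLASSES:
        if numerator_mode == "persons":
            return [schema.ANY_PSYCHOTROPIC]
        return [schema.rx_col(c) for c in DRUG_CLASSES]
    if numerator_mode == "persons":
        return [schema.disp_col(drug_class)]
    return [schema.rx_col(drug_class)]


def _check_referential_integrity(persons: pd.DataFrame, divisions: pd.DataFrame) -> None:
    known = set(divisions[schema.DIVISION_ID])
    seen = set(persons[schema.DIVISION_ID].unique())
    unknown = sorted(seen - known)
    if unknown:
        raise ValueError(f"person rows reference unknown division ids: {unknown}")
    if (persons[schema.WEIGHT] <= 0).any():
        raise ValueError("person weights must be positive")


def stratum_table(persons: pd.DataFrame, numerator_mode: str = "persons") -> pd.DataFrame:
    """Weighted events and population per division x age band x sex stratum.

    Returns a long frame with columns division_id, age_band, sex,
    population, and one weighted event column per class (``ev_<class>``,
    plus ``ev_all``).
    """
    w = persons[schema.WEIGHT].to_numpy(dtype=float)
    data = {
        schema.DIVISION_ID: persons[schema.DIVISION_ID].to_numpy(),
        "age_band": persons["age_band"].astype(str).to_numpy(),
        "sex": persons["sex"].astype(str).to_numpy(),
        "population": w,
    }
    for cls_name in RATE_CLASSES:
        cols = _numerator_column(cls_name, numerator_mode)
        events = persons[cols].to_numpy(dtype=float).sum(axis=1)
        data[f"ev_{cls_name}"] = w * events
    frame = pd.DataFrame(data)
    out = (frame.groupby([schema.DIVISION_ID, "age_band", "sex"], observed=True)
           .sum().reset_index())
    return out


def make_reference(persons: pd.DataFrame, numerator_mode: str = "persons") -> ReferenceStructure:
    """Pooled (provincial) reference: stratum shares and stratum rates."""
    strata = stratum_table(persons, numerator_mode)
    pooled = strata.groupby(["age_band", "sex"], observed=True).sum(numeric_only=True)
    total = pooled["population"].sum()
    if total <= 0:
        raise ValueError("reference population is empty")
    table = pd.DataFrame(index=pooled.index)
    table["share"] = pooled["population"] / total
    for cls_name in RATE_CLASSES:
        table[cls_name] = pooled[f"ev_{cls_name}"] / pooled["population"]
    return ReferenceStructure(table)


def crude_rates(persons: pd.DataFrame, divisions: pd.DataFrame,
                numerator_mode: str = "persons") -> pd.DataFrame:
    """One record per division x class with weighted O, population and crude rate."""
    _check_referential_integrity(persons, divisions)
    strata = stratum_table(persons, numerator_mode)
    agg = strata.groupby(schema.DIVISION_ID, observed=True).sum(numeric_only=True)
    zero_pop = agg.index[agg["population"] <= 0].tolist()
    if zero_pop:
        raise ValueError(f"divisions with zero population: {zero_pop}")
    records = []
    for cls_name in RATE_CLASSES:
        records.append(pd.DataFrame({
            "division_id": agg.index,
            "drug_class": cls_name,
            "observed": agg[f"ev_{cls_name}"].to_numpy(),
            "population": agg["population"].to_numpy(),
        }))
    out = pd.concat(records, ignore_index=True)
    out["crude_per_1000"] = 1000.0 * out["observed"] / out["population"]
    return out


def standardize(persons: pd.DataFrame, divisions: pd.DataFrame,
                reference: ReferenceStructure,
                numerator_mode: str = "persons") -> pd.DataFrame:
    """Directly standardized rates plus indirect expected counts per division x class.

    The direct rate is ``1000 * sum_s share_s * (O_is / w_is)``; strata with
    no population in a division contribute nothing and their reference share
    is renormalized away (logged).  ``E_i = sum_s reference_rate_s * w_is``.
    """
    rates = crude_rates(persons, divisions, numerator_mode)
    strata = stratum_table(persons, numerator_mode)
    strata = strata.set_index([schema.DIVISION_ID, "age_band", "sex"])

    ref = reference.table
    std_rows: dict[str, dict[str, float]] = {}
    exp_rows: dict[str, dict[str, float]] = {}
    for div_id, div_strata in strata.groupby(level=0, observed=True):
        div_strata = div_strata.droplevel(0)
        present = div_strata.index
        ref_present = ref.index.intersection(present)
        share_total = float(ref.loc[ref_present, "share"].sum())
        if share_total <= 0:
            raise ValueError(f"division {div_id!r} shares no strata with the reference")
        if share_total < 1.0 - 1e-12:
            log.warning("division %s: empty strata; renormalizing reference "
                        "shares from %.6f", div_id, share_total)
        shares = ref.loc[ref_present, "share"] / share_total
        pop = div_strata.loc[ref_present, "population"]
        std_rows[div_id] = {}
        exp_rows[div_id] = {}
        for cls_name in RATE_CLASSES:
            if cls_name not in reference.classes:
                continue
            obs = div_strata.loc[ref_present, f"ev_{cls_name}"]
            std_rows[div_id][cls_name] = float(
                1000.0 * (shares * (obs / pop)).sum())
            # expected counts use *all* of the division's strata present in
            # the reference (share renormalization does not apply)
            exp_rows[div_id][cls_name] = float(
                (ref.loc[ref_present, cls_name] * pop).sum())

    rates["standardized_per_1000"] = [
        std_rows[d].get(c, np.nan)
        for d, c in zip(rates["division_id"], rates["drug_class"])]
    rates["expected"] = [
        exp_rows[d].get(c, np.nan)
        for d, c in zip(rates["division_id"], rates["drug_class"])]
    return rates[list(RATES_COLUMNS)]


def compute_rates(persons: pd.DataFrame, divisions: pd.DataFrame,
                  numerator_mode: str = "persons",
                  reference: ReferenceStructure | None = None) -> pd.DataFrame:
    """Full rate table; the reference defaults to the pooled province."""
    if reference is None:
        reference = make_reference(persons, numerator_mode)
    return standardize(persons, divisions, reference, numerator_mode)


def proportion_from_counts(numerator: float, denominator: float) -> SubgroupProportion:
    """Subgroup proportion from explicit counts."""
    if denominator <= 0:
        raise ValueError("empty subgroup: denominator must be > 0")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return SubgroupProportion(float(numerator), float(denominator))


def subgroup_proportion(persons: pd.DataFrame, denominator_mask,
                        flag_column: str) -> SubgroupProportion:
    """Weighted proportion of *flag_column* among persons selected by the mask."""
    sub = persons.loc[np.asarray(denominator_mask, dtype=bool)]
    w = sub[schema.WEIGHT].to_numpy(dtype=float)
    den = float(w.sum())
    if den <= 0:
        raise ValueError("empty subgroup: no persons match the denominator filter")
    num = float((w * sub[flag_column].to_numpy(dtype=float)).sum())
    return SubgroupProportion(num, den)
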