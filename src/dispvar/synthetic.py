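"""Synthetic cohort generator.

Produces a person-level table (one row per retained study subject) and a
division-level table (stratified population counts plus area covariates)
with the statistical structure the downstream analysis assumes:

* division youth populations drawn log-uniform between a configured min/max;
* a multiplicative log-normal division effect ``u_d = exp(N(-sigma^2/2, sigma))``
  (mean-corrected so ``E[u_d] = 1``) applied to every class's rate;
* per-person dispensing probability for class ``c`` of
  ``(baseline_c / 1000) * u_d * exp(sum of covariate log rate ratios)``;
* non-recipients of every class downsampled to a 10% sample carrying
  weight 10, recipients retained in full with weight 1.

All randomness flows from one ``numpy.random.Generator`` seeded from the
config, in a fixed documented order (division sizes, division covariates,
division effects, then per-division person draws, then the non-recipient
subsample, then prescription counts), so identical configs give
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema
from .schema import (
    ADG_BANDS, AGE_BANDS, AGE_BAND_EDGES, DIVISION_COVARIATES, DRUG_CLASSES,
    INCOME_QUINTILES, RURALITIES, SEXES,
)

__all__ = ["GeneratorConfig", "generate", "write_tables", "ProbabilityOverflowError"]


class ProbabilityOverflowError(ValueError):
    """A configured covariate pattern implies a dispensing probability > 1."""


def _default_age_shares() -> dict[str, float]:
    return {b: 0.2 for b in AGE_BANDS}


def _default_income_shares() -> dict[int, float]:
    return {q: 0.2 for q in INCOME_QUINTILES}


def _default_log_rr() -> dict:
    out: dict[str, dict[str, dict]] = {}
    for cls, covs in schema.DEFAULT_COVARIATE_RR.items():
        out[cls] = {cov: {lvl: math.log(rr) for lvl, rr in levels.items()}
                    for cov, levels in covs.items()}
    return out


def _default_division_covariate_params() -> dict:
    # shapes chosen so defaults look like plausible area-level covariates;
    # all independent across covariates and divisions unless reconfigured
    return {
        "specialist_density": {"dist": "gamma", "shape": 2.0, "scale": 1.0},
        "agency_density": {"dist": "gamma", "shape": 2.0, "scale": 0.05},
        "mh_admission_ed_rate": {"dist": "gamma", "shape": 4.0, "scale": 2.5},
        "pct_postsecondary": {"dist": "normal", "mean": 55.0, "sd": 8.0,
                              "clip": [0.0, 100.0]},
        "pct_visible_minority": {"dist": "gamma", "shape": 1.5, "scale": 8.0,
                                 "clip": [0.0, 100.0]},
        "mean_household_size": {"dist": "normal", "mean": 2.9, "sd": 0.25,
                                "clip": [1.0, None]},
        "pct_noncitizen": {"dist": "gamma", "shape": 1.5, "scale": 3.0,
                           "clip": [0.0, 100.0]},
        "pct_employed": {"dist": "normal", "mean": 60.0, "sd": 5.0,
                         "clip": [0.0, 100.0]},
        "pct_neither_language": {"dist": "gamma", "shape": 1.2, "scale": 1.0,
                                 "clip": [0.0, 100.0]},
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``log_rate_ratios`` maps drug class -> covariate -> level -> log rate
    ratio; omitted levels are reference levels (log RR 0).  ``baseline_rates``
    are reference-pattern one-year dispensing probabilities per 1,000 (the
    study window is one calendar year, so rates are treated as one-year
    cumulative probabilities).
    """

    n_divisions: int = 49
    division_population_range: tuple[int, int] = (3_500, 738_000)
    #: optional total youth population; division sizes are rescaled to sum
    #: to this while keeping their log-uniform shape
    total_population: int | None = None
    age_group_shares: dict[str, float] = field(default_factory=_default_age_shares)
    sex_share_female: float = 0.49
    income_quintile_shares: dict[int, float] = field(default_factory=_default_income_shares)
    rural_share: float = 0.14
    #: non-negative integer comorbidity-count distribution on 0..32
    adg_distribution: dict = field(default_factory=lambda: {"dist": "nbinom", "n": 3.0, "p": 3.0 / 7.0})
    baseline_rates_per_1000: dict[str, float] = field(
        default_factory=lambda: dict(schema.DEFAULT_BASELINE_RATES))
    log_rate_ratios: dict = field(default_factory=_default_log_rr)
    division_effect_sd: float = 0.0
    division_covariate_params: dict = field(default_factory=_default_division_covariate_params)
    #: prescription count for a dispensed person is 1 + NB(mean rx_mean - 1)
    rx_mean: float = 3.0
    rx_size: float = 1.5
    nonrecipient_sample_fraction: float = 0.1
    seed: int = 0

    # -- construction -------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # JSON/YAML mappings arrive with string keys; normalize integers
        cfg.income_quintile_shares = {int(k): v for k, v in cfg.income_quintile_shares.items()}
        for cls_name, covs in cfg.log_rate_ratios.items():
            if "income_quintile" in covs:
                covs["income_quintile"] = {int(k): v for k, v in covs["income_quintile"].items()}
        if not isinstance(cfg.division_population_range, tuple):
            cfg.division_population_range = tuple(cfg.division_population_range)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if self.n_divisions < 1:
            raise ValueError("n_divisions must be >= 1")
        lo, hi = self.division_population_range
        if not (0 < lo <= hi):
            raise ValueError("division_population_range must be 0 < min <= max")
        for name, shares in (("age_group_shares", self.age_group_shares),
                             ("income_quintile_shares", self.income_quintile_shares)):
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total!r})")
            if any(v < 0 for v in shares.values()):
                raise ValueError(f"{name} must be non-negative")
        if set(self.age_group_shares) != set(AGE_BANDS):
            raise ValueError(f"age_group_shares must cover bands {AGE_BANDS}")
        if set(self.income_quintile_shares) != set(INCOME_QUINTILES):
            raise ValueError("income_quintile_shares must cover quintiles 1..5")
        for p, name in ((self.sex_share_female, "sex_share_female"),
                        (self.rural_share, "rural_share"),
                        (self.nonrecipient_sample_fraction, "nonrecipient_sample_fraction")):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nonrecipient_sample_fraction <= 0:
            raise ValueError("nonrecipient_sample_fraction must be > 0")
        if self.division_effect_sd < 0:
            raise ValueError("division_effect_sd must be >= 0")
        for cls_name, rate in self.baseline_rates_per_1000.items():
            if rate <= 0:
                raise ValueError(f"baseline rate for {cls_name!r} must be > 0")
        unknown = set(self.baseline_rates_per_1000) - set(DRUG_CLASSES)
        if unknown:
            raise ValueError(f"unknown drug classes in baseline rates: {sorted(unknown)}")
        self._check_max_probability()

    def _max_pattern(self, drug_class: str) -> tuple[float, dict]:
        """Largest deterministic probability multiplier and its pattern."""
        mult = self.baseline_rates_per_1000[drug_class] / 1000.0
        pattern: dict = {}
        for cov, levels in self.log_rate_ratios.get(drug_class, {}).items():
            best_lvl, best = None, 0.0  # reference level
            for lvl, lrr in levels.items():
                if lrr > best:
                    best_lvl, best = lvl, lrr
            if best_lvl is not None:
                pattern[cov] = best_lvl
            mult *= math.exp(best)
        return mult, pattern

    def _check_max_probability(self) -> None:
        # the division effect is random and handled by clipping at draw time;
        # the deterministic covariate part must stay a probability on its own
        for cls_name in self.baseline_rates_per_1000:
            p_max, pattern = self._max_pattern(cls_name)
            if p_max > 1.0:
                raise ProbabilityOverflowError(
                    f"class {cls_name!r}: most-exposed pattern {pattern} implies "
                    f"probability {p_max:.3f} > 1; lower the baseline rate or "
                    "the covariate rate ratios")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------
# drawing helpers

def _draw_distribution(rng: np.random.Generator, params: dict, size: int) -> np.ndarray:
    kind = params.get("dist", "normal")
    if kind == "normal":
        x = rng.normal(params["mean"], params["sd"], size)
    elif kind == "gamma":
        x = rng.gamma(params["shape"], params["scale"], size)
    elif kind == "uniform":
        x = rng.uniform(params["low"], params["high"], size)
    elif kind == "constant":
        x = np.full(size, float(params["value"]))
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    clip = params.get("clip")
    if clip is not None:
        lo = -np.inf if clip[0] is None else clip[0]
        hi = np.inf if clip[1] is None else clip[1]
        x = np.clip(x, lo, hi)
    return x


def _draw_adg(rng: np.random.Generator, params: dict, size: int) -> np.ndarray:
    kind = params.get("dist", "nbinom")
    if kind == "nbinom":
        x = rng.negative_binomial(params["n"], params["p"], size)
    elif kind == "poisson":
        x = rng.poisson(params["lam"], size)
    elif kind == "constant":
        x = np.full(size, int(params["value"]))
    else:
        raise ValueError(f"unknown adg distribution kind {kind!r}")
    return np.minimum(x, 32).astype(np.int16)


def _division_populations(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    lo, hi = config.division_population_range
    raw = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_divisions))
    if config.total_population is not None:
        raw = raw * (config.total_population / raw.sum())
    pops = np.maximum(np.rint(raw).astype(np.int64), 1)
    return pops


def _adg_band_codes(adg: np.ndarray) -> np.ndarray:
    """0 -> '0-5', 1 -> '6-9', 2 -> '10+'."""
    return np.where(adg >= 10, 2, np.where(adg >= 6, 1, 0)).astype(np.int8)


def _class_multiplier(config: GeneratorConfig, drug_class: str,
                      age_idx: np.ndarray, male: np.ndarray, rural: np.ndarray,
                      income: np.ndarray, adg_band: np.ndarray) -> np.ndarray:
    """exp(sum of covariate log rate ratios) per person, by lookup tables."""
    covs = config.log_rate_ratios.get(drug_class, {})

    def table(cov: str, levels: tuple, codes: np.ndarray) -> np.ndarray:
        lut = np.array([math.exp(covs.get(cov, {}).get(lvl, 0.0)) for lvl in levels])
        return lut[codes]

    out = table("age_band", AGE_BANDS, age_idx)
    out *= table("sex", SEXES, male.astype(np.int8))        # SEXES=(female, male)
    out *= table("rurality", RURALITIES, rural.astype(np.int8))
    out *= table("income_quintile", INCOME_QUINTILES, income - 1)
    out *= table("adg_band", ADG_BANDS, adg_band)
    return out


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cohort; returns ``(persons, divisions)`` DataFrames.

    Columns follow :data:`dispvar.schema.PERSON_COLUMNS` and
    :data:`dispvar.schema.DIVISION_COLUMNS`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pops = _division_populations(rng, config)
    n_div = config.n_divisions
    div_ids = np.array([f"D{i + 1:03d}" for i in range(n_div)])

    # sorted so the rng stream does not depend on dict insertion order
    div_cov = {name: _draw_distribution(rng, config.division_covariate_params[name], n_div)
               for name in sorted(config.division_covariate_params)}
    missing = set(DIVISION_COVARIATES) - set(div_cov)
    if missing:
        raise ValueError(f"division_covariate_params missing {sorted(missing)}")

    sigma = config.division_effect_sd
    if sigma > 0:
        u = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, n_div))
    else:
        u = np.ones(n_div)

    age_shares = np.array([config.age_group_shares[b] for b in AGE_BANDS])
    inc_shares = np.array([config.income_quintile_shares[q] for q in INCOME_QUINTILES])
    band_lo = np.array([AGE_BAND_EDGES[b][0] for b in AGE_BANDS])
    band_hi = np.array([AGE_BAND_EDGES[b][1] for b in AGE_BANDS])
    classes = [c for c in DRUG_CLASSES if c in config.baseline_rates_per_1000]

    frames = []
    strata_counts = np.zeros((n_div, len(AGE_BANDS), 2), dtype=np.int64)
    n_clipped = 0
    for d in range(n_div):
        n = int(pops[d])
        age_idx = rng.choice(len(AGE_BANDS), size=n, p=age_shares).astype(np.int8)
        age = band_lo[age_idx] + rng.integers(
            0, band_hi[age_idx] - band_lo[age_idx] + 1, size=n)
        female = rng.random(n) < config.sex_share_female
        male = ~female
        income = (rng.choice(5, size=n, p=inc_shares) + 1).astype(np.int8)
        rural = rng.random(n) < config.rural_share
        adg = _draw_adg(rng, config.adg_distribution, n)
        adg_band = _adg_band_codes(adg)

        disp = np.zeros((n, len(classes)), dtype=np.int8)
        for j, cls_name in enumerate(classes):
            base = config.baseline_rates_per_1000[cls_name] / 1000.0
            p = base * u[d] * _class_multiplier(
                config, cls_name, age_idx, male, rural, income, adg_band)
            over = p > 1.0
            if over.any():
                n_clipped += int(over.sum())
                p = np.minimum(p, 1.0)
            disp[:, j] = rng.random(n) < p

        np.add.at(strata_counts[d], (age_idx, male.astype(np.int8)), 1)

        frames.append(pd.DataFrame({
            schema.DIVISION_ID: div_ids[d],
            "age_years": age.astype(np.int16),
            "age_band": pd.Categorical.from_codes(age_idx, AGE_BANDS),
            "sex": pd.Categorical.from_codes(male.astype(np.int8), SEXES),
            "income_quintile": income,
            "rurality": pd.Categorical.from_codes(rural.astype(np.int8), RURALITIES),
            "adg_count": adg,
            "adg_band": pd.Categorical.from_codes(adg_band, ADG_BANDS),
            **{schema.disp_col(c): disp[:, j] for j, c in enumerate(classes)},
        }))

    if n_clipped:
        warnings.warn(
            f"{n_clipped} person-class probabilities exceeded 1 and were "
            "clipped; consider lowering division_effect_sd or rate ratios",
            RuntimeWarning, stacklevel=2)

    persons = pd.concat(frames, ignore_index=True)
    disp_cols = [schema.disp_col(c) for c in classes]
    for c in DRUG_CLASSES:
        if schema.disp_col(c) not in persons.columns:
            persons[schema.disp_col(c)] = np.int8(0)
            disp_cols.append(schema.disp_col(c))
    any_disp = persons[[schema.disp_col(c) for c in DRUG_CLASSES]].to_numpy().max(axis=1)
    persons[schema.ANY_PSYCHOTROPIC] = any_disp.astype(np.int8)

    # 10% non-recipient sample: every k-th element of a random permutation,
    # so sum of weights = n_recipients + k * ceil(n_nonrecipients / k)
    # (exact population total when n_nonrecipients is divisible by k)
    k = int(round(1.0 / config.nonrecipient_sample_fraction))
    nonrec_idx = np.flatnonzero(any_disp == 0)
    kept_nonrec = np.sort(rng.permutation(nonrec_idx)[::k])
    keep = np.zeros(len(persons), dtype=bool)
    keep[any_disp == 1] = True
    keep[kept_nonrec] = True
    weight = np.where(any_disp == 1, 1.0, float(k))
    persons[schema.WEIGHT] = weight
    persons = persons.loc[keep].reset_index(drop=True)

    # prescription counts: 1 + NB(mean rx_mean - 1) for dispensed persons
    extra_mean = max(config.rx_mean - 1.0, 0.0)
    for c in DRUG_CLASSES:
        d = persons[schema.disp_col(c)].to_numpy()
        counts = np.zeros(len(persons), dtype=np.int32)
        idx = np.flatnonzero(d == 1)
        if len(idx) and extra_mean > 0:
            p_nb = config.rx_size / (config.rx_size + extra_mean)
            counts[idx] = 1 + rng.negative_binomial(config.rx_size, p_nb, len(idx))
        elif len(idx):
            counts[idx] = 1
        persons[schema.rx_col(c)] = counts

    for c in DRUG_CLASSES:
        others = [schema.disp_col(o) for o in DRUG_CLASSES if o != c]
        persons[schema.other_col(c)] = (
            persons[others].to_numpy().max(axis=1).astype(np.int8))

    persons[schema.PERSON_ID] = [f"P{i + 1:08d}" for i in range(len(persons))]
    persons = persons[list(schema.PERSON_COLUMNS)]

    divisions = pd.DataFrame({schema.DIVISION_ID: div_ids})
    for bi, b in enumerate(AGE_BANDS):
        for si, s in enumerate(SEXES):
            divisions[schema.pop_col(b, s)] = strata_counts[:, bi, si]
    for name in DIVISION_COVARIATES:
        divisions[name] = div_cov[name]
    divisions = divisions[list(schema.DIVISION_COLUMNS)]
    return persons, divisions


def write_tables(persons: pd.DataFrame, divisions: pd.DataFrame,
                 out_dir: str | Path, config: GeneratorConfig | None = None) -> dict[str, Path]:
    """Write persons.csv / divisions.csv (+ metadata sidecar) to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"persons": out / "persons.csv", "divisions": out / "divisions.csv"}
    persons.to_csv(paths["persons"], index=False, lineterminator="\r\n")
    divisions.to_csv(paths["divisions"], index=False, lineterminator="\r\n")
    if config is not None:
        meta = {"seed": config.seed, "n_persons": int(len(persons)),
                "n_divisions": int(len(divisions)), "config": config.to_dict()}
        paths["metadata"] = out / "generator_metadata.json"
        paths["metadata"].write_text(json.dumps(meta, indent=2, default=str))
    return paths
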