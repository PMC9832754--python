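"""Small-area variation statistics and per-division significance tests.

Implements the three classical statistics — extremal quotient, population-
weighted coefficient of variation, and the systematic component of
variation (SCV) — plus the one-sample chi-square comparing each division's
count with the expectation under the pooled provincial rate.

The SCV estimator subtracts the Poisson (random) variance component from
the total relative variance of observed-to-expected counts:

    SCV = (100 / k) * sum_i [ ((O_i - E_i) / E_i)^2 - 1 / E_i ]

Interpretation bands: < 3.0 low, [3.0, 5.5) moderate, [5.5, 10] high,
> 10 very high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "VariationSummary", "DivisionTestResult", "extremal_quotient",
    "weighted_cv", "scv", "classify_scv", "variation_summary",
    "division_vs_province_test", "per_comparison_alpha",
]


@dataclass(frozen=True)
class VariationSummary:
    k: int
    eq: float
    cv: float
    scv: float
    band: str

    def to_dict(self) -> dict:
        return {"k": self.k, "EQ": self.eq, "CV": self.cv,
                "SCV": self.scv, "band": self.band}


@dataclass(frozen=True)
class DivisionTestResult:
    division_id: str
    statistic: float
    p_value: float
    alpha: float
    direction: str  # above | below | none
    significant: bool


def extremal_quotient(rates) -> float:
    """Ratio of the highest to the lowest area rate."""
    r = np.asarray(rates, dtype=float)
    if r.size < 2:
        raise ValueError("extremal quotient needs at least 2 areas")
    lo = r.min()
    if lo <= 0:
        raise ValueError(
            "minimum rate is not positive; check for areas with no events "
            "(try the other persons/prescriptions numerator mode or drop "
            "empty classes)")
    return float(r.max() / lo)


def weighted_cv(rates, weights) -> float:
    """Population-weighted coefficient of variation, in percent."""
    r = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.size < 2:
        raise ValueError("weighted CV needs at least 2 areas")
    if r.shape != w.shape:
        raise ValueError("rates and weights must have equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    mean = float(np.average(r, weights=w))
    if mean <= 0:
        raise ValueError("weighted mean rate is not positive")
    var = float(np.average((r - mean) ** 2, weights=w))
    return 100.0 * math.sqrt(var) / mean


def scv(observed, expected) -> float:
    """Systematic component of variation (x100 scale)."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    k = o.size
    if k < 2:
        raise ValueError("SCV needs at least 2 areas")
    bad = np.flatnonzero(e <= 0)
    if bad.size:
        raise ValueError(f"expected counts must be > 0 (violated at areas {bad.tolist()})")
    return float(100.0 / k * np.sum(((o - e) / e) ** 2 - 1.0 / e))


def classify_scv(value: float) -> str:
    """Interpretation band for an SCV value."""
    if not math.isfinite(value):
        raise ValueError("SCV value must be finite")
    if value < 3.0:
        return "low"
    if value < 5.5:
        return "moderate"
    if value <= 10.0:
        return "high"
    return "very high"


def variation_summary(rates, weights, observed, expected) -> VariationSummary:
    """All three statistics for one drug class."""
    s = scv(observed, expected)
    return VariationSummary(
        k=int(np.asarray(rates).size),
        eq=extremal_quotient(rates),
        cv=weighted_cv(rates, weights),
        scv=s,
        band=classify_scv(s),
    )


def division_vs_province_test(division_id: str, observed: float, expected: float,
                              population: float, alpha: float) -> DivisionTestResult:
    """One-sample proportion chi-square (1 df) against the provincial rate.

    X^2 = (O-E)^2/E + ((N-O)-(N-E))^2/(N-E); the province is treated as a
    fixed reference.
    """
    if not (0 <= observed <= population):
        raise ValueError("observed must lie in [0, population]")
    if not (0 < expected < population):
        raise ValueError("expected must lie strictly inside (0, population)")
    diff = observed - expected
    statistic = diff ** 2 / expected + diff ** 2 / (population - expected)
    p_value = float(stats.chi2.sf(statistic, df=1))
    significant = bool(p_value < alpha)
    if significant:
        direction = "above" if diff > 0 else "below"
    else:
        direction = "none"
    return DivisionTestResult(division_id, float(statistic), p_value,
                              float(alpha), direction, significant)


def per_comparison_alpha(familywise_alpha: float, k: int) -> float:
    """Familywise alpha split over k comparisons, one significant figure.

    0.05 over 49 areas gives 0.00102..., reported as 0.001.
    """
    if not (0 < familywise_alpha < 1):
        raise ValueError("familywise alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    raw = familywise_alpha / k
    exponent = math.floor(math.log10(raw))
    return round(raw, -exponent)
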