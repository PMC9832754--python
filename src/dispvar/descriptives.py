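"""Baseline characteristics and division-level correlations.

Standardized differences use the usual pooled-variance conventions:
``|p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)`` for proportions and
``|m1 - m2| / sqrt((s1^2 + s2^2) / 2)`` for continuous variables.
Spearman correlations get a Fisher-z confidence interval with standard
error ``1 / sqrt(n - 3)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .schema import ADG_BANDS, AGE_BANDS, INCOME_QUINTILES, RURALITIES

__all__ = [
    "CorrelationResult", "std_diff_proportions", "std_diff_continuous",
    "spearman_with_ci", "baseline_table",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {"rho": self.rho, "n": self.n, "ci95": [self.ci_low, self.ci_high]}


def std_diff_proportions(p1: float, p2: float) -> float:
    """Standardized difference between two proportions."""
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled <= 0:
        raise ValueError("pooled variance is zero; standardized difference undefined")
    return abs(p1 - p2) / math.sqrt(pooled)


def std_diff_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """Standardized difference between two means (pooled-SD convention)."""
    pooled = (s1 ** 2 + s2 ** 2) / 2.0
    if pooled <= 0:
        raise ValueError("pooled variance is zero; standardized difference undefined")
    return abs(m1 - m2) / math.sqrt(pooled)


def spearman_with_ci(x, y) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties) with Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant input")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, n, rho, rho)
    z = math.atanh(rho)
    half = 1.959964 / math.sqrt(n - 3)
    return CorrelationResult(rho, n, math.tanh(z - half), math.tanh(z + half))


# ---------------------------------------------------------------------
# baseline table

def _weighted_quantiles(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(qs, cum, v)


def _group_stats(sub: pd.DataFrame) -> dict:
    w = sub[schema.WEIGHT].to_numpy(dtype=float)
    age = sub["age_years"].to_numpy(dtype=float)
    mean = float(np.average(age, weights=w))
    sd = float(math.sqrt(np.average((age - mean) ** 2, weights=w)))
    q25, q50, q75 = _weighted_quantiles(age, w, [0.25, 0.5, 0.75])
    return {"n": float(w.sum()), "age_mean": mean, "age_sd": sd,
            "age_median": float(q50), "age_iqr": (float(q25), float(q75))}


def _prop(sub: pd.DataFrame, mask: np.ndarray) -> float:
    w = sub[schema.WEIGHT].to_numpy(dtype=float)
    return float((w * mask).sum() / w.sum())


def baseline_table(persons: pd.DataFrame) -> pd.DataFrame:
    """Recipients vs. sampled non-recipients with standardized differences.

    Returns one row per characteristic with weighted group summaries.  The
    age row carries median (IQR) for display but its standardized
    difference uses the weighted mean/SD (pooled-SD convention).
    """
    recip = persons[persons[schema.ANY_PSYCHOTROPIC] == 1]
    nonrec = persons[persons[schema.ANY_PSYCHOTROPIC] == 0]
    if recip.empty or nonrec.empty:
        raise ValueError("both recipient and non-recipient groups must be non-empty")
    g1, g2 = _group_stats(recip), _group_stats(nonrec)

    rows = [{
        "variable": "age_years (median, IQR)",
        "recipients": f"{g1['age_median']:.0f} ({g1['age_iqr'][0]:.0f}-{g1['age_iqr'][1]:.0f})",
        "non_recipients": f"{g2['age_median']:.0f} ({g2['age_iqr'][0]:.0f}-{g2['age_iqr'][1]:.0f})",
        "standardized_difference": std_diff_continuous(
            g1["age_mean"], g1["age_sd"], g2["age_mean"], g2["age_sd"]),
    }]

    def add_categorical(label: str, column: str, level) -> None:
        m1 = (recip[column] == level).to_numpy()
        m2 = (nonrec[column] == level).to_numpy()
        p1, p2 = _prop(recip, m1), _prop(nonrec, m2)
        rows.append({
            "variable": label,
            "recipients": f"{100 * p1:.1f}%",
            "non_recipients": f"{100 * p2:.1f}%",
            "standardized_difference": std_diff_proportions(p1, p2),
        })

    for band in AGE_BANDS:
        add_categorical(f"age_band {band}", "age_band", band)
    add_categorical("female", "sex", "female")
    for q in INCOME_QUINTILES:
        add_categorical(f"income_quintile {q}", "income_quintile", q)
    for r in RURALITIES:
        add_categorical(f"residence {r}", "rurality", r)
    for band in ADG_BANDS:
        add_categorical(f"adg_band {band}", "adg_band", band)

    out = pd.DataFrame(rows)
    out["standardized_difference"] = out["standardized_difference"].round(2)
    return out
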