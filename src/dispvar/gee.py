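"""Log-link marginal models (GEE) for dispensing counts.

The regression mirrors the cohort sampling design: persons are aggregated into
covariate-pattern cells within census divisions; the cell outcome is the
number of recipients and the offset is the log of the weighted cell size
(so the 10% non-recipient sample is inflated back to population scale).
A log-link GEE is then solved by Fisher scoring with either an
exchangeable or an independent working correlation, quasi-Poisson or
negative-binomial variance, and a cluster-robust (sandwich) covariance.

With an independent working correlation the point estimates coincide with
a quasi-Poisson GLM fit — a property the test-suite checks against an
external IRLS implementation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .schema import (
    ADG_BANDS, ADG_BAND_REF, AGE_BANDS, AGE_BAND_REF, ALL_CLASSES,
    DIVISION_COVARIATES, DRUG_CLASSES, INCOME_QUINTILES, INCOME_REF,
    RURALITIES, RURALITY_REF, SEXES, SEX_REF,
)

__all__ = ["ModelSpec", "GEEResult", "build_design", "fit_gee", "rr_table"]

log = logging.getLogger(__name__)

Z95 = 1.959964  # fixed normal multiplier for 95% CIs

_CATEGORICAL_TERMS: dict[str, tuple[tuple, object]] = {
    # term -> (level order, reference level)
    "age_band": (AGE_BANDS, AGE_BAND_REF),
    "sex": (SEXES, SEX_REF),
    "rurality": (RURALITIES, RURALITY_REF),
    "income_quintile": (INCOME_QUINTILES, INCOME_REF),
    "adg_band": (ADG_BANDS, ADG_BAND_REF),
}

DEFAULT_INDIVIDUAL_TERMS = ("age_band", "sex", "rurality", "income_quintile",
                            "adg_band", "other_class")


@dataclass(frozen=True)
class ModelSpec:
    """What to regress: outcome class, covariates and working assumptions."""

    outcome_class: str = ALL_CLASSES
    individual_terms: tuple[str, ...] = DEFAULT_INDIVIDUAL_TERMS
    division_terms: tuple[str, ...] = DIVISION_COVARIATES
    working_correlation: str = "independent"  # or "exchangeable"
    variance_family: str = "poisson_quasi"     # or "negative_binomial"

    def __post_init__(self):
        if self.outcome_class not in (ALL_CLASSES, *DRUG_CLASSES):
            raise ValueError(f"unknown outcome class {self.outcome_class!r}")
        if self.working_correlation not in ("independent", "exchangeable"):
            raise ValueError(f"unknown working correlation {self.working_correlation!r}")
        if self.variance_family not in ("poisson_quasi", "negative_binomial"):
            raise ValueError(f"unknown variance family {self.variance_family!r}")
        if "other_class" in self.individual_terms and self.outcome_class == ALL_CLASSES:
            raise ValueError("'other_class' is undefined for the pooled (all-class) outcome")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["intercept"]
        for term in self.individual_terms:
            if term == "other_class":
                names.append("other_class")
                continue
            levels, ref = _CATEGORICAL_TERMS[term]
            names.extend(f"{term}[{lvl}]" for lvl in levels if lvl != ref)
        names.extend(self.division_terms)
        return tuple(names)


@dataclass
class GEEResult:
    """Fitted coefficients with cluster-robust inference."""

    spec: ModelSpec
    params: pd.Series                 # coefficient vector (log scale)
    robust_cov: pd.DataFrame
    alpha_work: float                 # exchangeable correlation estimate
    phi: float                        # Pearson dispersion
    theta: float | None               # NB size parameter, if used
    n_clusters: int
    n_obs: int
    iterations: int
    converged: bool
    max_abs_update: float
    naive_cov: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_cov.to_numpy())),
                         index=self.params.index)

    @property
    def rate_ratios(self) -> pd.DataFrame:
        """RR with 95% CI from the robust covariance (full precision)."""
        se = self.robust_se
        return pd.DataFrame({
            "rr": np.exp(self.params),
            "ci_low": np.exp(self.params - Z95 * se),
            "ci_high": np.exp(self.params + Z95 * se),
        })

    def to_dict(self) -> dict:
        rr = self.rate_ratios
        return {
            "outcome_class": self.spec.outcome_class,
            "working_correlation": self.spec.working_correlation,
            "variance_family": self.spec.variance_family,
            "params": self.params.to_dict(),
            "robust_se": self.robust_se.to_dict(),
            "rate_ratios": {k: {"rr": rr.at[k, "rr"], "ci95": [rr.at[k, "ci_low"], rr.at[k, "ci_high"]]}
                            for k in rr.index},
            "alpha_work": self.alpha_work,
            "phi": self.phi,
            "theta": self.theta,
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
            "iterations": self.iterations,
            "converged": self.converged,
            "max_abs_update": self.max_abs_update,
        }


class GEEConvergenceError(RuntimeError):
    def __init__(self, message: str, last_params: pd.Series, iterations: int,
                 max_abs_update: float):
        super().__init__(message)
        self.last_params = last_params
        self.iterations = iterations
        self.max_abs_update = max_abs_update


# ---------------------------------------------------------------------
# design construction

def build_design(persons: pd.DataFrame, divisions: pd.DataFrame,
                 spec: ModelSpec) -> pd.DataFrame:
    """Aggregate persons to covariate-pattern cells within divisions.

    Returns a frame with columns ``cluster``, ``y`` (recipient count),
    ``offset`` (log weighted cell size) and one column per design term
    (intercept excluded; it is added by :func:`fit_gee`).

    Aggregation is lossless for a log-link count model: cells with the same
    covariate pattern contribute the same estimating-equation terms whether
    or not they are collapsed.
    """
    known = set(divisions[schema.DIVISION_ID])
    unknown = sorted(set(persons[schema.DIVISION_ID].unique()) - known)
    if unknown:
        raise ValueError(f"person rows reference unknown division ids: {unknown}")
    bad_w = persons[schema.WEIGHT] <= 0
    if bad_w.any():
        raise ValueError("person weights must be positive")

    if spec.outcome_class == ALL_CLASSES:
        outcome = persons[schema.ANY_PSYCHOTROPIC]
    else:
        outcome = persons[schema.disp_col(spec.outcome_class)]

    group_cols = []
    frame = pd.DataFrame({schema.DIVISION_ID: persons[schema.DIVISION_ID].to_numpy()})
    for term in spec.individual_terms:
        if term == "other_class":
            frame["other_class"] = persons[schema.other_col(spec.outcome_class)].to_numpy()
        else:
            frame[term] = persons[term].to_numpy()
        group_cols.append(term if term != "other_class" else "other_class")
    frame["_y"] = persons[schema.WEIGHT].to_numpy() * outcome.to_numpy()
    frame["_n"] = persons[schema.WEIGHT].to_numpy(dtype=float)

    cells = (frame.groupby([schema.DIVISION_ID, *group_cols], observed=True)
             .sum().reset_index())

    design = pd.DataFrame({
        "cluster": cells[schema.DIVISION_ID].to_numpy(),
        "y": cells["_y"].to_numpy(dtype=float),
        "offset": np.log(cells["_n"].to_numpy(dtype=float)),
    })
    for term in spec.individual_terms:
        if term == "other_class":
            if cells["other_class"].nunique() < 2:
                raise ValueError("covariate 'other_class' has a single observed level")
            design["other_class"] = cells["other_class"].to_numpy(dtype=float)
            continue
        levels, ref = _CATEGORICAL_TERMS[term]
        observed = set(cells[term].unique())
        if len(observed) < 2:
            raise ValueError(f"covariate {term!r} has a single observed level")
        vals = cells[term].to_numpy()
        for lvl in levels:
            if lvl == ref:
                continue
            design[f"{term}[{lvl}]"] = (vals == lvl).astype(float)

    if spec.division_terms:
        div = divisions.set_index(schema.DIVISION_ID)
        for term in spec.division_terms:
            col = div[term].reindex(design["cluster"]).to_numpy(dtype=float)
            if np.unique(col).size < 2:
                raise ValueError(f"covariate {term!r} has a single observed level")
            design[term] = col
    return design


# ---------------------------------------------------------------------
# fitting

def _moment_theta(y: np.ndarray, mu: np.ndarray, n_params: int) -> float | None:
    """NB2 size parameter by method of moments; None falls back to Poisson."""
    num = float(np.sum((y - mu) ** 2 - mu))
    den = float(np.sum(mu ** 2))
    if num <= 0 or den <= 0:
        return None
    return den / num


def _cluster_vinv_apply(M: np.ndarray, r: np.ndarray, var: np.ndarray,
                        n: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(V^-1 M, V^-1 r)`` for one cluster's working covariance.

    The working covariance is the one *induced on aggregated cells* by an
    exchangeable person-level correlation ``rho`` within the cluster:

        V = (1 - rho) * diag(var) + rho * b b',   b_i = sqrt(var_i * n_i)

    where ``n_i`` is the cell size (persons aggregated into cell i).  For
    unit cells (n_i = 1) this is exactly the classical exchangeable
    structure ``A^1/2 [(1-rho) I + rho J] A^1/2``; for unequal cells it is
    the aggregation-consistent generalization (equicorrelation across
    *cells* of very different sizes is not a coherent model).  Inverted by
    Sherman-Morrison, so cost stays linear in cluster size.
    """
    if rho == 0.0:
        return M / var[:, None], r / var
    b = np.sqrt(var * n)
    w = b / var                       # A^-1 b
    s = float(n.sum())                # b' A^-1 b
    c = rho / (1.0 - rho + rho * s)
    Minv = (M / var[:, None] - c * np.outer(w, w @ M)) / (1.0 - rho)
    rinv = (r / var - c * w * (w @ r)) / (1.0 - rho)
    return Minv, rinv


def fit_gee(cells: pd.DataFrame, spec: ModelSpec, tol: float = 1e-8,
            max_iter: int = 100) -> GEEResult:
    """Solve the GEE score equations by Fisher scoring.

    Convergence is declared when the largest absolute coefficient update
    drops below *tol*; non-convergence raises :class:`GEEConvergenceError`
    carrying the last iterate.  The exchangeable correlation parameter is
    a person-level correlation (see :func:`_cluster_vinv_apply`), estimated
    by the moment formula from cross-products of size-standardized
    residuals, and the robust covariance is the usual bread-meat-bread
    sandwich over cluster scores.
    """
    term_cols = [c for c in cells.columns if c not in ("cluster", "y", "offset")]
    names = ["intercept", *term_cols]
    X = np.column_stack([np.ones(len(cells)),
                         cells[term_cols].to_numpy(dtype=float)])
    y = cells["y"].to_numpy(dtype=float)
    offset = cells["offset"].to_numpy(dtype=float)
    cell_n = np.exp(offset)           # aggregated cell sizes
    clusters = cells["cluster"].to_numpy()

    n_obs, n_params = X.shape
    if n_obs <= n_params:
        raise ValueError("more parameters than cells")
    if np.linalg.matrix_rank(X) < n_params:
        raise ValueError("design matrix is rank deficient")
    cluster_ids, cluster_inv = np.unique(clusters, return_inverse=True)
    n_clusters = cluster_ids.size
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    cluster_slices = [np.flatnonzero(cluster_inv == c) for c in range(n_clusters)]

    # start from the intercept-only closed form
    beta = np.zeros(n_params)
    beta[0] = math.log(max(y.sum(), 0.5)) - math.log(cell_n.sum())

    exchangeable = spec.working_correlation == "exchangeable"
    nb = spec.variance_family == "negative_binomial"
    theta: float | None = None
    alpha = 0.0
    phi = 1.0
    max_update = np.inf
    it = 0
    # exchangeable weighting is applied only once the independent (GLM)
    # iterations have settled; starting it cold can overshoot badly
    warmed_up = not exchangeable

    def estimate_alpha(var: np.ndarray, resid_pearson: np.ndarray,
                       mu: np.ndarray) -> float:
        # moment estimator from cross-products of size-standardized
        # residuals t_i = (y_i - mu_i) / sqrt(var_i * n_i); for unit cells
        # this is the classical exchangeable formula. Clusters with a
        # single cell contribute only to phi.
        t = (y - mu) / np.sqrt(var * cell_n)
        num, pairs = 0.0, 0
        for idx in cluster_slices:
            if idx.size < 2:
                continue
            ti = t[idx]
            num += (ti.sum() ** 2 - (ti ** 2).sum()) / 2.0
            pairs += idx.size * (idx.size - 1) // 2
        if pairs == 0:
            return 0.0
        a = num / phi / max(pairs - n_params, 1)
        # keep V positive definite for the most populous cluster:
        # need 1 - a + a * sum(n_i) > 0
        s_max = max(cell_n[idx].sum() for idx in cluster_slices)
        a_lo = -0.95 / (s_max - 1.0) if s_max > 1 else 0.0
        return float(np.clip(a, a_lo, 0.99))

    for it in range(1, max_iter + 1):
        eta = X @ beta + offset
        mu = np.exp(eta)

        if nb:
            theta = _moment_theta(y, mu, n_params)
        var = mu + (mu ** 2 / theta if (nb and theta is not None) else 0.0)
        resid = (y - mu) / np.sqrt(var)
        phi = float(resid @ resid) / (n_obs - n_params)

        if exchangeable and warmed_up:
            alpha = estimate_alpha(var, resid, mu)

        rho = alpha if (exchangeable and warmed_up) else 0.0
        info = np.zeros((n_params, n_params))
        score = np.zeros(n_params)
        for idx in cluster_slices:
            D = mu[idx, None] * X[idx]           # d mu / d beta
            VinvD, Vinvr = _cluster_vinv_apply(D, y[idx] - mu[idx], var[idx],
                                               cell_n[idx], rho)
            info += D.T @ VinvD
            score += D.T @ Vinvr

        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise GEEConvergenceError(
                f"singular working information at iteration {it}: {exc}",
                pd.Series(beta, index=names), it, max_update) from exc
        max_update = float(np.max(np.abs(delta)))
        if max_update > 5.0:  # damp wild steps far from the solution
            delta *= 5.0 / max_update
        beta = beta + delta
        if max_update < tol:
            if warmed_up:
                break
            warmed_up = True  # independent phase settled; switch weighting
    else:
        raise GEEConvergenceError(
            f"GEE did not converge in {max_iter} iterations "
            f"(max |update| = {max_update:.3e})",
            pd.Series(beta, index=names), max_iter, max_update)

    # sandwich covariance at the solution
    eta = X @ beta + offset
    mu = np.exp(eta)
    if nb:
        theta = _moment_theta(y, mu, n_params)
    var = mu + (mu ** 2 / theta if (nb and theta is not None) else 0.0)

    rho = alpha if exchangeable else 0.0
    bread = np.zeros((n_params, n_params))
    meat = np.zeros((n_params, n_params))
    for idx in cluster_slices:
        D = mu[idx, None] * X[idx]
        VinvD, Vinvr = _cluster_vinv_apply(D, y[idx] - mu[idx], var[idx],
                                           cell_n[idx], rho)
        bread += D.T @ VinvD
        g = D.T @ Vinvr          # per-cluster score D' V^-1 (y - mu)
        meat += np.outer(g, g)
    bread_inv = np.linalg.inv(bread)
    robust = bread_inv @ meat @ bread_inv
    robust = (robust + robust.T) / 2.0

    return GEEResult(
        spec=spec,
        params=pd.Series(beta, index=names),
        robust_cov=pd.DataFrame(robust, index=names, columns=names),
        naive_cov=pd.DataFrame(phi * bread_inv, index=names, columns=names),
        alpha_work=float(alpha),
        phi=float(phi),
        theta=theta,
        n_clusters=n_clusters,
        n_obs=n_obs,
        iterations=it,
        converged=True,
        max_abs_update=max_update,
    )


# ---------------------------------------------------------------------
# reporting

def _fmt_rr(rr: float, lo: float, hi: float) -> str:
    return f"{rr:.2f} ({lo:.2f} to {hi:.2f})"


def rr_table(results: dict[str, GEEResult]) -> pd.DataFrame:
    """Formatted rate-ratio table, one column per outcome class.

    *results* maps outcome-class name -> converged :class:`GEEResult`;
    missing classes are omitted with a logged note.  Reference levels are
    rendered as ``1.00``.
    """
    order = [c for c in (ALL_CLASSES, "antidepressant", "antipsychotic",
                         "benzodiazepine", "stimulant")]
    present = [c for c in order if c in results]
    for c in order:
        if c not in results:
            log.info("rate-ratio table: no result for class %r; column omitted", c)

    rows: list[str] = []
    for term in DEFAULT_INDIVIDUAL_TERMS:
        if term == "other_class":
            rows.append("other_class")
            continue
        levels, ref = _CATEGORICAL_TERMS[term]
        for lvl in levels:
            rows.append(f"{term}[{lvl}]" + (" (ref)" if lvl == ref else ""))
    rows.extend(DIVISION_COVARIATES)

    table = pd.DataFrame(index=rows, columns=present, dtype=object)
    table.index.name = "variable"
    for cls_name in present:
        res = results[cls_name]
        if not res.converged:
            raise ValueError(f"result for {cls_name!r} did not converge")
        rr = res.rate_ratios
        for row in rows:
            if row.endswith(" (ref)"):
                table.at[row, cls_name] = "1.00"
            elif row in rr.index:
                table.at[row, cls_name] = _fmt_rr(rr.at[row, "rr"],
                                                  rr.at[row, "ci_low"],
                                                  rr.at[row, "ci_high"])
            else:
                table.at[row, cls_name] = ""
    return table
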