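import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dispvar import schema
from dispvar.gee import (
    DEFAULT_INDIVIDUAL_TERMS, GEEConvergenceError, GEEResult, ModelSpec,
    build_design, fit_gee, rr_table,
)

from conftest import _person, divisions_for


def _simulate_unit_cells(seed=0, n_clusters=40, m=30, sigma=0.4):
    """Person-like clustered Poisson rows (cell size 1) in design-frame form."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clusters):
        u = rng.normal(0, sigma)
        x1 = rng.binomial(1, 0.5, m)
        x2 = rng.normal(0, 1, m)
        mu = np.exp(-1.0 + 0.4 * x1 - 0.2 * x2 + u)
        y = rng.poisson(mu)
        rows += [(f"C{c:02d}", float(y[j]), 0.0, float(x1[j]), float(x2[j]))
                 for j in range(m)]
    return pd.DataFrame(rows, columns=["cluster", "y", "offset", "x1", "x2"])


def _bare_spec(working="independent", variance="poisson_quasi"):
    return ModelSpec(outcome_class="all", individual_terms=(), division_terms=(),
                     working_correlation=working, variance_family=variance)


class TestBuildDesign:
    def test_cell_outcome_and_offset(self, tiny_persons, tiny_divisions):
        spec = ModelSpec(outcome_class="all",
                         individual_terms=(), division_terms=())
        cells = build_design(tiny_persons, tiny_divisions, spec)
        assert len(cells) == 1
        assert cells.loc[0, "y"] == pytest.approx(10.0)
        assert cells.loc[0, "offset"] == pytest.approx(math.log(200.0))

    def test_unknown_division_hard_error(self, tiny_persons, tiny_divisions):
        bad = tiny_persons.copy()
        bad.loc[0, schema.DIVISION_ID] = "D404"
        with pytest.raises(ValueError, match="D404"):
            build_design(bad, tiny_divisions, _bare_spec())

    def test_single_level_covariate_named(self, tiny_persons, tiny_divisions):
        spec = ModelSpec(outcome_class="all", individual_terms=("rurality",),
                         division_terms=())
        with pytest.raises(ValueError, match="rurality"):
            build_design(tiny_persons, tiny_divisions, spec)

    def test_other_class_forbidden_for_pooled_outcome(self):
        with pytest.raises(ValueError, match="other_class"):
            ModelSpec(outcome_class="all", individual_terms=("other_class",))

    def test_reference_levels_not_in_design(self, small_cohort):
        persons, divisions = small_cohort
        spec = ModelSpec(outcome_class="stimulant")
        cells = build_design(persons, divisions, spec)
        for ref_col in ("age_band[5-9]", "sex[female]", "rurality[urban]",
                        "income_quintile[1]", "adg_band[0-5]"):
            assert ref_col not in cells.columns


class TestFitGEE:
    def test_intercept_only_closed_form(self, small_cohort):
        persons, divisions = small_cohort
        spec = _bare_spec()
        cells = build_design(persons, divisions, spec)
        res = fit_gee(cells, spec)
        expected = math.log(cells["y"].sum() / np.exp(cells["offset"]).sum())
        assert res.params["intercept"] == pytest.approx(expected, abs=1e-10)

    def test_independent_matches_quasipoisson_glm(self, small_cohort):
        persons, divisions = small_cohort
        spec = ModelSpec(outcome_class="antipsychotic")
        cells = build_design(persons, divisions, spec)
        res = fit_gee(cells, spec)
        X = sm.add_constant(cells.drop(columns=["cluster", "y", "offset"]))
        glm = sm.GLM(cells["y"], X, family=sm.families.Poisson(),
                     offset=cells["offset"]).fit()
        np.testing.assert_allclose(res.params.to_numpy(), glm.params.to_numpy(),
                                   rtol=1e-6, atol=1e-6)

    def test_independent_sandwich_matches_statsmodels_gee(self, small_cohort):
        persons, divisions = small_cohort
        spec = ModelSpec(outcome_class="stimulant")
        cells = build_design(persons, divisions, spec)
        res = fit_gee(cells, spec)
        X = sm.add_constant(cells.drop(columns=["cluster", "y", "offset"]))
        gm = sm.GEE(cells["y"], X, groups=cells["cluster"],
                    family=sm.families.Poisson(),
                    cov_struct=sm.cov_struct.Independence(),
                    offset=cells["offset"]).fit()
        np.testing.assert_allclose(res.params.to_numpy(), gm.params.to_numpy(),
                                   rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(res.robust_se.to_numpy(), gm.bse.to_numpy(),
                                   rtol=1e-5)

    def test_exchangeable_unit_cells_matches_statsmodels(self):
        cells = _simulate_unit_cells()
        res = fit_gee(cells, _bare_spec("exchangeable"))
        X = sm.add_constant(cells[["x1", "x2"]])
        gm = sm.GEE(cells["y"], X, groups=cells["cluster"],
                    family=sm.families.Poisson(),
                    cov_struct=sm.cov_struct.Exchangeable()).fit(
                        maxiter=200, ctol=1e-10)
        assert res.alpha_work == pytest.approx(gm.cov_struct.dep_params, abs=1e-8)
        np.testing.assert_allclose(res.params.to_numpy(), gm.params.to_numpy(),
                                   rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(res.robust_se.to_numpy(), gm.bse.to_numpy(),
                                   rtol=1e-8)

    def test_exchangeable_reduces_to_independent_when_rho_zero(self):
        # with independent clusters the estimated rho is ~0 and both fits agree
        cells = _simulate_unit_cells(seed=3, sigma=0.0)
        r1 = fit_gee(cells, _bare_spec("exchangeable"))
        r2 = fit_gee(cells, _bare_spec("independent"))
        assert abs(r1.alpha_work) < 0.02
        np.testing.assert_allclose(r1.params.to_numpy(), r2.params.to_numpy(),
                                   atol=0.02)

    def test_collapse_invariance(self, small_cohort):
        # splitting a cell into two rows with the same covariate pattern and
        # the same total exposure must not change the estimating equations
        persons, divisions = small_cohort
        spec = ModelSpec(outcome_class="benzodiazepine",
                         individual_terms=("sex", "age_band"), division_terms=())
        cells = build_design(persons, divisions, spec)
        res = fit_gee(cells, spec)

        first = cells.iloc[[0]].copy()
        rest = cells.iloc[1:]
        n0 = math.exp(first.loc[0, "offset"])
        half = first.copy()
        half["offset"] = math.log(n0 / 2.0)
        a, b = half.copy(), half.copy()
        a["y"] = first.loc[0, "y"]
        b["y"] = 0.0
        split = pd.concat([a, b, rest], ignore_index=True)
        res_split = fit_gee(split, spec)
        np.testing.assert_allclose(res.params.to_numpy(),
                                   res_split.params.to_numpy(), atol=1e-7)

    def test_cell_order_invariance(self, small_cohort):
        persons, divisions = small_cohort
        spec = ModelSpec(outcome_class="stimulant")
        cells = build_design(persons, divisions, spec)
        res1 = fit_gee(cells, spec)
        res2 = fit_gee(cells.sample(frac=1.0, random_state=1).reset_index(drop=True), spec)
        np.testing.assert_allclose(res1.params.to_numpy(), res2.params.to_numpy(),
                                   atol=1e-9)

    def test_negative_binomial_variant(self, small_cohort):
        persons, divisions = small_cohort
        spec = ModelSpec(outcome_class="antidepressant",
                         variance_family="negative_binomial")
        cells = build_design(persons, divisions, spec)
        res = fit_gee(cells, spec)
        assert res.converged
        assert res.theta is None or res.theta > 0
        # NB2 point estimates stay near the quasi-Poisson ones at these counts
        spec_qp = ModelSpec(outcome_class="antidepressant")
        res_qp = fit_gee(cells, spec_qp)
        np.testing.assert_allclose(res.params.to_numpy(), res_qp.params.to_numpy(),
                                   atol=0.15)

    def test_nonconvergence_is_explicit(self):
        cells = _simulate_unit_cells()
        with pytest.raises(GEEConvergenceError) as err:
            fit_gee(cells, _bare_spec(), tol=1e-15, max_iter=2)
        assert err.value.iterations == 2
        assert len(err.value.last_params) == 3

    def test_rank_deficient_design_rejected(self):
        cells = _simulate_unit_cells()
        cells["x3"] = cells["x1"]
        with pytest.raises(ValueError, match="rank"):
            fit_gee(cells, _bare_spec())

    def test_needs_two_clusters(self):
        cells = _simulate_unit_cells(n_clusters=1)
        with pytest.raises(ValueError, match="clusters"):
            fit_gee(cells, _bare_spec())

    def test_ci_brackets_rr(self, small_cohort):
        persons, divisions = small_cohort
        spec = ModelSpec(outcome_class="stimulant")
        res = fit_gee(build_design(persons, divisions, spec), spec)
        rr = res.rate_ratios
        assert (rr["ci_low"] <= rr["rr"]).all()
        assert (rr["rr"] <= rr["ci_high"]).all()
        cov = res.robust_cov.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)


class TestParameterRecovery:
    def test_male_stimulant_rr_small_scale(self):
        # scaled-down version of the acceptance recovery run (3 seeds)
        from dispvar.synthetic import GeneratorConfig, generate
        rrs = []
        for seed in (1, 2, 3):
            cfg = GeneratorConfig(
                n_divisions=20, division_population_range=(3_500, 100_000),
                total_population=80_000, division_effect_sd=0.2, seed=seed)
            with pytest.warns(RuntimeWarning):
                persons, divisions = generate(cfg)
            spec = ModelSpec(outcome_class="stimulant")
            res = fit_gee(build_design(persons, divisions, spec), spec)
            rrs.append(res.rate_ratios.at["sex[male]", "rr"])
        assert np.mean(rrs) == pytest.approx(1.75, abs=0.15)


class TestRRTable:
    def _result_with(self, beta, se, spec):
        names = list(spec.param_names)
        params = pd.Series(0.0, index=names)
        cov = pd.DataFrame(np.eye(len(names)) * 1e-10, index=names, columns=names)
        for k, v in beta.items():
            params[k] = v
        for k, v in se.items():
            cov.at[k, k] = v ** 2
        return GEEResult(spec=spec, params=params, robust_cov=cov,
                         alpha_work=0.0, phi=1.0, theta=None, n_clusters=10,
                         n_obs=100, iterations=3, converged=True,
                         max_abs_update=0.0)

    def test_formats_point_and_ci(self):
        spec = ModelSpec(outcome_class="antipsychotic")
        se = (math.log(1.44) - math.log(1.36)) / (2 * 1.959964)
        res = self._result_with({"sex[male]": math.log(1.40)},
                                {"sex[male]": se}, spec)
        table = rr_table({"antipsychotic": res})
        assert table.at["sex[male]", "antipsychotic"] == "1.40 (1.36 to 1.44)"
        assert table.at["sex[female] (ref)", "antipsychotic"] == "1.00"

    def test_zero_beta_renders_unity(self):
        spec = ModelSpec(outcome_class="stimulant")
        res = self._result_with({}, {}, spec)
        table = rr_table({"stimulant": res})
        assert table.at["sex[male]", "stimulant"].startswith("1.00 (1.00 to 1.00")

    def test_missing_class_column_omitted(self):
        spec = ModelSpec(outcome_class="stimulant")
        res = self._result_with({}, {}, spec)
        table = rr_table({"stimulant": res})
        assert list(table.columns) == ["stimulant"]
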