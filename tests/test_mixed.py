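"""Mixed-model fitting, AICc machinery and top-model-set selection."""

import numpy as np
import pandas as pd
import pytest

from cogbattery.mixed import (
    MixedModelError,
    ModelFit,
    ModelSpec,
    aicc,
    build_candidate_set,
    fit_mixed,
    scale_predictors,
    select_top_models,
)


class TestAICc:
    def test_closed_form(self):
        assert aicc(-50.0, 3, 32) == pytest.approx(106 + 24 / 28)

    def test_zero_parameter_edge(self):
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0)

    def test_approaches_aic_for_large_n(self):
        aic = -2 * (-50.0) + 2 * 5
        assert aicc(-50.0, 5, 10_000_000) == pytest.approx(aic, abs=1e-4)

    def test_undefined_when_correction_blows_up(self):
        with pytest.raises(MixedModelError):
            aicc(-50.0, 5, 6)


class TestScalePredictors:
    def test_centres_and_scales(self):
        df = pd.DataFrame({"x": [2.0, 4.0, 6.0], "label": ["a", "b", "c"]})
        out = scale_predictors(df, ["x"])
        assert out["x"].tolist() == [-1.0, 0.0, 1.0]
        assert out["label"].tolist() == ["a", "b", "c"]

    def test_idempotent(self):
        df = pd.DataFrame({"x": np.arange(1.0, 14.0)})
        once = scale_predictors(df, ["x"])
        twice = scale_predictors(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)
        assert once["x"].std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(MixedModelError):
            scale_predictors(pd.DataFrame({"x": [1.0, 1.0]}), ["x"])


class TestCandidateSets:
    def test_interaction_pool_of_six(self):
        pool = ["sex", "age", "rank", "group_size", "body_mass", "study_year"]
        specs = build_candidate_set([], interaction_pool=pool)
        inter = [s for s in specs if any(":" in t for t in s.fixed_terms)]
        assert len(inter) == 15  # C(6,2)

    def test_single_term_only(self):
        specs = build_candidate_set(["age"])
        assert {s.label for s in specs} == {"null model", "age"}

    def test_fitness_model_set_has_seven_rows(self):
        specs = build_candidate_set(
            ["gcp", "age", "sex", "group_size", "drought"],
            interaction_pool=["gcp", "sex"],
            family="poisson",
            random_terms=("year", "individual_id"),
        )
        assert len(specs) == 7
        labels = {s.label for s in specs}
        assert "null model" in labels and "gcp x sex" in labels

    def test_full_determinant_set_size(self):
        singles = [
            "age", "sex", "rank", "group_size", "latency", "iti",
            "body_mass", "foraging", "order", "time_of_day", "study_year",
        ]
        pool = ["sex", "age", "rank", "group_size", "body_mass", "study_year"]
        specs = build_candidate_set(singles, additive_pool=pool, interaction_pool=pool)
        # null + 11 singles + 15 additive pairs + 15 interactions
        assert len(specs) == 42

    def test_interaction_includes_main_effects(self):
        with pytest.raises(MixedModelError):
            ModelSpec("y", ("a:b",), ("g",))


def _stub_fit(label_terms, aicc_value, coef_rows, n=32):
    coef = pd.DataFrame(
        coef_rows,
        columns=["estimate", "se", "ci_low", "ci_high"],
        index=["Intercept"] + [f"t{k}" for k in range(len(coef_rows) - 1)],
    )
    spec = ModelSpec("y", label_terms, ("g",))
    return ModelFit(
        spec=spec, loglik=0.0, k=3, n=n, aicc=aicc_value,
        coefficients=coef, variance_components={}, converged=True,
    )


class TestSelection:
    def test_delta_matches_reported_pair(self):
        best = _stub_fit(("age", "sex", "age:sex"), 103.53,
                         [[0, 1, -1, 1], [-0.76, 0.19, -1.14, -0.37],
                          [-0.48, 0.28, -1.05, 0.09], [0.90, 0.29, 0.29, 1.49]])
        null = _stub_fit((), 109.46, [[0, 1, -1, 1]])
        table = select_top_models([best, null])
        assert table["delta_aicc"].tolist() == pytest.approx([0.0, 5.93])
        assert table.loc[table["is_null"], "delta_aicc"].iloc[0] == pytest.approx(5.93)

    def test_ci_spanning_zero_excluded_from_top_set(self):
        good = _stub_fit(("a",), 100.0, [[0, 1, -1, 1], [0.9, 0.2, 0.5, 1.3]])
        close = _stub_fit(("b",), 101.3, [[0, 1, -1, 1], [0.4, 0.3, -0.2, 1.0]])
        table = select_top_models([good, close])
        flags = dict(zip(table["model"], table["in_top_set"]))
        assert flags["a"] and not flags["b"]

    def test_single_model_trivially_best(self):
        only = _stub_fit(("a",), 55.0, [[0, 1, -1, 1], [1.0, 0.1, 0.8, 1.2]])
        table = select_top_models([only])
        assert table["delta_aicc"].iloc[0] == 0.0

    def test_exactly_one_zero_delta_with_tie_toward_fewer_parameters(self):
        a = _stub_fit(("a",), 100.0, [[0, 1, -1, 1], [1.0, 0.1, 0.8, 1.2]])
        b = _stub_fit((), 100.0, [[0, 1, -1, 1]])
        b.k = 2
        table = select_top_models([a, b])
        assert (table["delta_aicc"] == 0).sum() == 2
        assert table["model"].iloc[0] == "null model"  # fewer parameters first


@pytest.fixture(scope="module")
def lmm_data():
    rng = np.random.default_rng(5)
    G, n_per = 12, 5
    gid = np.repeat([f"g{i}" for i in range(G)], n_per)
    u = np.repeat(rng.normal(0, 0.7, G), n_per)
    age = rng.normal(0, 1, G * n_per)
    sex = rng.choice(["female", "male"], G * n_per)
    y = 1.0 - 0.8 * age + 0.4 * (sex == "male") + u + rng.normal(0, 1.0, G * n_per)
    return pd.DataFrame({"gcp": y, "age": age, "sex": sex, "group_id": gid})


class TestGaussianFit:
    def test_matches_reference_mixed_model_engine(self, lmm_data):
        import statsmodels.api as sm

        spec = ModelSpec("gcp", ("age", "sex", "age:sex"), ("group_id",))
        fit = fit_mixed(spec, lmm_data)
        ref = sm.MixedLM.from_formula(
            "gcp ~ age + sex + age:sex", groups="group_id", data=lmm_data
        ).fit(reml=False)
        assert fit.loglik == pytest.approx(float(ref.llf), abs=1e-5)
        np.testing.assert_allclose(
            fit.coefficients["estimate"], ref.fe_params, atol=1e-4
        )
        assert fit.variance_components["var_group_id"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), abs=1e-4
        )

    def test_reml_variance_larger_than_ml(self, lmm_data):
        spec = ModelSpec("gcp", ("age",), ("group_id",))
        ml = fit_mixed(spec, lmm_data, reml=False)
        reml = fit_mixed(spec, lmm_data, reml=True)
        assert reml.variance_components["var_group_id"] >= (
            ml.variance_components["var_group_id"] - 1e-10
        )

    def test_boundary_variance_reduces_to_ols(self):
        # grouping that explains nothing: the ML variance hits zero and the
        # coefficients collapse exactly onto ordinary least squares
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 40
        df = pd.DataFrame(
            {
                "y": np.tile([1.0, -1.0], n // 2) + rng.normal(0, 0.1, n),
                "x": rng.normal(size=n),
                "group_id": np.repeat(["a", "b"], n // 2),
            }
        )
        fit = fit_mixed(ModelSpec("y", ("x",), ("group_id",)), df)
        X = np.column_stack([np.ones(n), df["x"]])
        ols = sm.OLS(df["y"], X).fit()
        if fit.variance_components["var_group_id"] < 1e-8:
            np.testing.assert_allclose(
                fit.coefficients["estimate"], ols.params, atol=1e-6
            )

    def test_aicc_invariant_to_response_shift(self, lmm_data):
        spec_a = ModelSpec("gcp", ("age",), ("group_id",))
        spec_b = ModelSpec("gcp", ("sex",), ("group_id",))
        base = [fit_mixed(spec_a, lmm_data), fit_mixed(spec_b, lmm_data)]
        shifted = lmm_data.assign(gcp=lmm_data["gcp"] + 57.0)
        moved = [fit_mixed(spec_a, shifted), fit_mixed(spec_b, shifted)]
        delta_base = base[0].aicc - base[1].aicc
        delta_moved = moved[0].aicc - moved[1].aicc
        assert delta_base == pytest.approx(delta_moved, abs=1e-6)

    def test_rank_deficient_design_rejected(self, lmm_data):
        doubled = lmm_data.assign(age2=lmm_data["age"])
        with pytest.raises(MixedModelError, match="rank"):
            fit_mixed(ModelSpec("gcp", ("age", "age2"), ("group_id",)), doubled)


@pytest.fixture(scope="module")
def poisson_data():
    """Fixed breeding table (the cross-engine reference values below were
    computed once with lme4::glmer on this exact table)."""
    from cogbattery.simulate import SyntheticConfig, simulate_breeding, simulate_roster

    cfg = SyntheticConfig(n_individuals=48, n_groups=24, n_years=10, seed=7)
    roster = simulate_roster(cfg)
    g = pd.Series(
        np.random.default_rng(1).normal(0, 1, len(roster)),
        index=roster["individual_id"],
    )
    br = simulate_breeding(roster, g, cfg)
    br["gcp"] = br["individual_id"].map(g)
    return scale_predictors(br, ["gcp"])


class TestPoissonLaplace:
    def test_matches_glmer_reference(self, poisson_data):
        spec = ModelSpec(
            "fledglings", ("gcp",), ("year", "individual_id"), family="poisson"
        )
        fit = fit_mixed(spec, poisson_data)
        # lme4::glmer(fledglings ~ gcp + (1|year) + (1|individual_id), poisson)
        assert fit.converged
        assert fit.loglik == pytest.approx(-798.3069, abs=2e-3)
        assert fit.coefficients.loc["Intercept", "estimate"] == pytest.approx(
            0.4692, abs=2e-3
        )
        assert fit.coefficients.loc["gcp", "estimate"] == pytest.approx(
            -0.1875, abs=2e-3
        )
        assert fit.coefficients.loc["gcp", "se"] == pytest.approx(0.0630, abs=2e-3)
        assert np.sqrt(fit.variance_components["var_year"]) == pytest.approx(
            0.27609, abs=5e-3
        )
        assert np.sqrt(fit.variance_components["var_individual_id"]) == pytest.approx(
            0.34956, abs=5e-3
        )

    def test_zero_variance_limit_equals_glm(self, poisson_data):
        import patsy
        import statsmodels.api as sm

        from cogbattery.mixed import _PoissonLaplace

        y, X = patsy.dmatrices(
            "fledglings ~ gcp", poisson_data, return_type="dataframe"
        )
        yv, Xv = y.to_numpy().ravel(), X.to_numpy()
        glm = sm.GLM(yv, Xv, family=sm.families.Poisson()).fit()
        factors = [
            pd.factorize(poisson_data[c])[0] for c in ("year", "individual_id")
        ]
        engine = _PoissonLaplace(yv, Xv, factors)
        ll, _ = engine.loglik(
            np.asarray(glm.params), np.full(2, _PoissonLaplace.LOG_SD_MIN)
        )
        assert ll == pytest.approx(float(glm.llf), abs=1e-4)

    def test_non_integer_response_rejected(self, poisson_data):
        bad = poisson_data.assign(fledglings=poisson_data["fledglings"] + 0.5)
        spec = ModelSpec("fledglings", (), ("year",), family="poisson")
        with pytest.raises(MixedModelError):
            fit_mixed(spec, bad)

    def test_k_counts_fixed_effects_and_variances(self, poisson_data):
        spec = ModelSpec(
            "fledglings", ("gcp", "sex"), ("year", "individual_id"), family="poisson"
        )
        fit = fit_mixed(spec, poisson_data)
        assert fit.k == 3 + 2  # intercept, gcp, sex(male) + two variances
        assert fit.n == len(poisson_data)


class TestAgeBySexRecovery:
    def test_generating_interaction_wins_model_selection(self, large_cohort):
        """At a 200-individual cohort, the female-only age decline should be
        picked out as the age-by-sex interaction in the AICc ranking."""
        from cogbattery.gcp import extract_gcp

        cfg, roster, sc = large_cohort
        gcp = extract_gcp(sc).gcp
        data = roster.assign(gcp=gcp.loc[roster["individual_id"]].to_numpy())
        data = scale_predictors(data, ["age"])
        specs = build_candidate_set(
            ["age", "sex"], interaction_pool=["age", "sex"],
            response="gcp", random_terms=("group_id",),
        )
        fits = [fit_mixed(s, data) for s in specs]
        table = select_top_models(fits)
        assert table["model"].iloc[0] == "age x sex"
        assert table.loc[table["model"] == "age x sex", "in_top_set"].iloc[0]
        # female (reference level) age slope is negative and credible
        best = next(f for f in fits if f.label == "age x sex")
        age_row = best.coefficients.loc["age"]
        assert age_row["estimate"] < -0.3
        assert age_row["ci_high"] < 0
        # interaction restores a ~flat male slope
        inter = best.coefficients.loc["age:sex[T.male]"]
        assert inter["estimate"] > 0.3
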