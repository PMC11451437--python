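import numpy as np
import pandas as pd
import pytest

from cognorm.bayes_glm import (
    SUBGROUPS,
    NormativeGLM,
    NormativeGLMResults,
    age_effect_table,
    exact_refit_loo,
    fit_all_subgroups,
    fit_glm,
)
from cognorm.cohort_io import OutcomeSpec
from cognorm.sampler import ConvergenceError, REDUCED_TEST_SAMPLER, SamplerConfig
from cognorm.synthetic_cohort import (
    TrueEffects,
    generate_cohort_frame,
    recovery_fixture,
    single_outcome_config,
)

FAST = SamplerConfig(warmup_iters=300, sampling_iters=500, rhat_max=1.05)


def _results_with_draws(model, beta_age_draws):
    """Wrap a model with injected posterior draws (beta_age column set)."""
    n = len(beta_age_draws)
    d = model.nparams
    draws = np.tile(model.start_params(), (1, n, 1))
    draws[0, :, 1] = beta_age_draws
    out = {
        "draws": draws,
        "mode": model.start_params(),
        "cov": np.eye(d),
        "accept_rate": np.array([1.0]),
        "rhat": np.ones(d),
        "ess": np.full(d, float(n)),
    }
    cfg = SamplerConfig(chains=1, warmup_iters=0, sampling_iters=n)
    return NormativeGLMResults(model, cfg, out)


@pytest.fixture(scope="module")
def zoib_cohort():
    spec, eff = recovery_fixture("zoib", 1.015)
    cfg = single_outcome_config(spec.name, eff, n=728, seed=11)
    return generate_cohort_frame(cfg, specs={spec.name: spec}), spec


class TestModelConstruction:
    def test_complete_cases_per_outcome(self, cohort_frame):
        df = cohort_frame.copy()
        df.loc[df.index[:50], "RVPA"] = np.nan
        m = NormativeGLM(df, "RVPA")
        assert m.nobs == len(df) - 50

    def test_min_cases_floor(self, cohort_frame):
        with pytest.raises(ValueError, match="complete cases"):
            NormativeGLM(cohort_frame.head(10), "RVPA")

    def test_unknown_subgroup(self, cohort_frame):
        with pytest.raises(ValueError):
            NormativeGLM(cohort_frame, "RVPA", subgroup="robot_high")

    def test_beta_boundary_nudge_warns(self):
        df = generate_cohort_frame(single_outcome_config(
            "RVPA", TrueEffects("beta", 3.0, 0.0, aux={"phi": 2.0}),
            n=200, seed=0))
        spec = OutcomeSpec("RVPA", "beta", "higher_better", 0, 1)
        df.loc[df.index[0], "RVPA"] = 1.0
        with pytest.warns(UserWarning, match="boundary"):
            NormativeGLM(df, spec)


class TestDrawCountContract:
    def test_production_default_is_20000(self):
        assert SamplerConfig().total_draws == 20_000

    def test_reduced_fit_draw_count(self, rvpa_fit):
        assert rvpa_fit.n_draws == 4 * 500
        assert rvpa_fit.draws_chains.shape[:2] == (4, 500)
        assert rvpa_fit.diagnostics["n_draws"] == 2000


class TestAgeEffectSummary:
    def test_degenerate_null_draws(self, cohort_frame):
        m = NormativeGLM(cohort_frame, "RVPA")
        res = _results_with_draws(m, np.zeros(100))
        eff = res.age_effect_summary()
        assert (eff.point, eff.ci_low, eff.ci_high) == (1.0, 1.0, 1.0)
        assert not eff.significant

    def test_constructed_grid_quantiles(self, cohort_frame):
        m = NormativeGLM(cohort_frame, "RVPA")
        grid = np.log(np.linspace(1.004, 1.019, 2001))
        res = _results_with_draws(m, grid)
        eff = res.age_effect_summary()
        assert eff.point == pytest.approx(1.0115, abs=2e-4)
        assert eff.ci_low == pytest.approx(1.004, abs=5e-4)
        assert eff.ci_high == pytest.approx(1.019, abs=5e-4)
        assert eff.significant

    def test_label_by_family(self, cohort_frame):
        m_or = NormativeGLM(cohort_frame, "PALTEA")
        assert _results_with_draws(
            m_or, np.zeros(10)
        ).age_effect_summary().label == "Odds ratio"
        m_irr = NormativeGLM(cohort_frame, "SWMBE")
        assert _results_with_draws(
            m_irr, np.zeros(10)
        ).age_effect_summary().label == "Incidence risk ratio"


class TestFitting:
    def test_seeded_determinism(self, zoib_cohort):
        df, spec = zoib_cohort
        a = fit_glm(df, spec, sampler=FAST, check_convergence=False)
        b = fit_glm(df, spec, sampler=FAST, check_convergence=False)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_single_seed_recovery_all_families(self):
        """Posterior medians land near the generating parameters."""
        for family, truth in (("zoib", 1.015), ("hurdle_nb", 1.011)):
            spec, eff = recovery_fixture(family, truth)
            cfg = single_outcome_config(spec.name, eff, n=728, seed=4)
            df = generate_cohort_frame(cfg, specs={spec.name: spec})
            res = fit_glm(df, spec, sampler=FAST, check_convergence=False)
            assert res.age_effect_summary().point == pytest.approx(
                truth, abs=0.01
            )

    def test_null_truth_recovery(self):
        spec, eff = recovery_fixture("zoib", 1.0)
        cfg = single_outcome_config(spec.name, eff, n=2000, seed=9)
        df = generate_cohort_frame(cfg, specs={spec.name: spec})
        res = fit_glm(df, spec, sampler=FAST, check_convergence=False)
        assert 0.99 <= res.age_effect_summary().point <= 1.01

    def test_convergence_gate_raises_with_diagnostics(self, cohort_frame):
        strict = SamplerConfig(warmup_iters=100, sampling_iters=100,
                               rhat_max=0.5)
        with pytest.raises(ConvergenceError) as exc_info:
            fit_glm(cohort_frame, "RVPA", sampler=strict)
        assert "rhat" in exc_info.value.diagnostics


@pytest.fixture(scope="module")
def all_fits(cohort_frame):
    return fit_all_subgroups(cohort_frame, "RVPA", sampler=FAST,
                             check_convergence=False, min_cases=20)


class TestSubgroups:
    def test_seven_models_fitted(self, all_fits):
        fits, errors = all_fits
        assert set(fits) | set(errors) == set(SUBGROUPS)

    def test_partition_conservation(self, all_fits, cohort_frame):
        fits, _ = all_fits
        n = {sg: f.model.nobs for sg, f in fits.items()}
        assert n["male"] + n["female"] == n["all"]
        if "male_high" in n and "male_low" in n:
            assert n["male_high"] + n["male_low"] == n["male"]

    def test_report_table_shape(self, all_fits):
        fits, _ = all_fits
        table = age_effect_table(fits)
        assert set(table["subgroup"]) == set(fits)
        assert {"point", "ci_low", "ci_high", "label", "n"} <= set(table.columns)
        assert (table["label"] == "Odds ratio").all()

    def test_small_subgroup_reported_as_error(self, cohort_frame):
        tiny = cohort_frame[
            (cohort_frame.sex == "male") & (cohort_frame.education_band == "high")
        ].head(60)
        fits, errors = fit_all_subgroups(tiny, "RVPA", sampler=FAST,
                                         check_convergence=False)
        assert "female" in errors and "male" in fits


@pytest.fixture(scope="module")
def tiny_fit():
    eff = TrueEffects("beta", 1.0, 0.01, aux={"phi": 10.0})
    spec = OutcomeSpec("TINY", "beta", "higher_better", 0, 1)
    cfg = single_outcome_config("TINY", eff, n=30, seed=21)
    df = generate_cohort_frame(cfg, specs={"TINY": spec})
    model = NormativeGLM(df, spec, min_cases=10)
    return model, model.fit(REDUCED_TEST_SAMPLER, check_convergence=False)


class TestLoo:
    def test_psis_loo_matches_exact_refit_oracle(self, tiny_fit):
        model, res = tiny_fit
        psis = res.loo()
        exact = exact_refit_loo(model, REDUCED_TEST_SAMPLER)
        assert abs(psis["elpd"] - exact["elpd"]) < 2.0 * psis["se"]

    def test_identical_model_zero_delta(self, tiny_fit):
        _, res = tiny_fit
        assert res.loo()["elpd"] == res.loo()["elpd"]

    def test_true_family_wins_model_selection(self):
        """Common-scale LOO prefers the generating count family over a
        rescaled unit-interval alternative on every replicate."""
        from cognorm.synthetic_cohort import DEFAULT_TRUE_EFFECTS

        wins = 0
        for seed in range(5):
            cfg = single_outcome_config(
                "SWMBE", DEFAULT_TRUE_EFFECTS["SWMBE"], n=600, seed=seed
            )
            df = generate_cohort_frame(cfg)
            true_fit = fit_glm(df, "SWMBE", sampler=FAST,
                               check_convergence=False)
            wrong_fit = fit_glm(df, "SWMBE", family="zoib", sampler=FAST,
                                check_convergence=False)
            if (true_fit.loo()["elpd_common_scale"]
                    > wrong_fit.loo()["elpd_common_scale"]):
                wins += 1
        assert wins == 5


class TestPosteriorPredictiveCheck:
    def test_self_consistency_on_training_data(self, rvpa_fit):
        ppc = rvpa_fit.posterior_predictive_check(n_rep=400, seed=1)
        assert ((ppc["p_value"] > 0.01) & (ppc["p_value"] < 0.99)).all()

    def test_replicated_data_calibration(self, rvpa_fit):
        """Scoring data simulated from the fitted model itself gives
        non-extreme check p-values in nearly all replicates."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            rep = rvpa_fit.replicate_datasets(1, rng)[0]
            df = pd.DataFrame(
                {
                    "age": rvpa_fit.model.age_c + rvpa_fit.model.age_center,
                    "sex": "male",
                    "education_band": "high",
                    "education_level": 4,
                    "RVPA": np.clip(rep, 1e-9, 1 - 1e-9),
                }
            )
            model_rep = NormativeGLM(df, rvpa_fit.model.spec)
            res_rep = NormativeGLMResults(
                rvpa_fit.model, rvpa_fit.sampler,
                {
                    "draws": rvpa_fit.draws_chains,
                    "mode": rvpa_fit.mode,
                    "cov": None,
                    "accept_rate": rvpa_fit.diagnostics["accept_rate"],
                    "rhat": rvpa_fit.diagnostics["rhat"],
                    "ess": rvpa_fit.diagnostics["ess"],
                },
            )
            res_rep.model = model_rep
            ppc = res_rep.posterior_predictive_check(n_rep=200, seed=seed)
            if ((ppc["p_value"] > 0.01) & (ppc["p_value"] < 0.99)).all():
                ok += 1
        assert ok >= 18

    def test_zero_inflation_misfit_detected_under_beta(self):
        """A plain beta model cannot reproduce heavy zero inflation: the
        zero-mass check must fail decisively."""
        spec = OutcomeSpec("ZINF", "zoib", "lower_better", 0, 1)
        eff = TrueEffects("zoib", -1.0, 0.0,
                          aux={"phi": 2.0, "zoi": 0.4, "coi": 0.0})
        df = generate_cohort_frame(single_outcome_config("ZINF", eff, n=400,
                                                         seed=3),
                                   specs={"ZINF": spec})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_glm(df, spec, family="beta", sampler=FAST,
                          check_convergence=False)
        ppc = fit.posterior_predictive_check(n_rep=400, seed=0)
        zero_p = float(ppc.loc[ppc.statistic == "zero_mass", "p_value"].iloc[0])
        assert zero_p < 0.01

    def test_exact_tie_gives_half(self, rvpa_fit):
        # beta family: observed and replicated zero masses are both exactly 0
        ppc = rvpa_fit.posterior_predictive_check(n_rep=100, seed=0)
        assert float(
            ppc.loc[ppc.statistic == "zero_mass", "p_value"].iloc[0]
        ) == 0.5


class TestPersistence:
    def test_save_round_trip(self, rvpa_fit, tmp_path):
        csv_path, json_path = rvpa_fit.save(tmp_path / "fit_rvpa_all")
        tidy = pd.read_csv(csv_path)
        assert set(tidy.columns) == {"chain", "draw", "parameter", "value"}
        assert len(tidy) == rvpa_fit.n_draws * len(rvpa_fit.param_names)
        import json

        payload = json.loads(json_path.read_text())
        assert payload["outcome"] == "RVPA"
        assert payload["age_effect"]["point"] == pytest.approx(
            rvpa_fit.age_effect_summary().point
        )

    def test_summary_text(self, rvpa_fit):
        text = rvpa_fit.summary()
        assert "RVPA" in text and "beta_age" in text and "Odds ratio" in text
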