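import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cognorm.classic_norms import (
    AGE_BANDS,
    NotNormableError,
    age_band,
    fit_regression,
    fit_stratified,
    regression_percentile,
    regression_z,
    stratified_percentile,
    stratified_z,
    z_to_percentile,
)
from cognorm.cohort_io import encode_design
from cognorm.synthetic_cohort import GeneratorConfig, generate_cohort_frame


def _demographics(n, seed):
    """Demographic frame only (no family-based outcomes)."""
    return generate_cohort_frame(GeneratorConfig(n=n, seed=seed, effects={}))


def _linear_cohort(n, seed, intercept=5.039, b_age=0.20, b_sex=-0.10,
                   b_edu=-2.31, sigma=11.3):
    """Gaussian linear outcome over realistic demographics."""
    df = _demographics(n, seed)
    rng = np.random.default_rng(seed + 10_000)
    df["SCORE"] = (
        intercept
        + b_age * df["age"]
        + b_sex * df["sex_code"]
        + b_edu * df["edu_code"]
        + rng.normal(0.0, sigma, size=n)
    )
    return df


class TestAgeBands:
    def test_band_edges(self):
        assert age_band(24) == "18-24"
        assert age_band(25) == "25-34"
        assert age_band(64) == "55-64"
        assert age_band(65) == "65-75"

    def test_bands_partition_range(self):
        edges = [b for lo, hi in AGE_BANDS for b in (lo, hi)]
        assert edges[0] == 18 and edges[-1] == 75
        for i in range(1, len(AGE_BANDS)):
            assert AGE_BANDS[i][0] == AGE_BANDS[i - 1][1] + 1

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            age_band(17)


class TestStratified:
    def test_hand_built_stratum(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "age": [20, 21, 22],
                "sex": "male",
                "education_band": "high",
                "SCORE": [8.0, 10.0, 12.0],
            }
        )
        norms = fit_stratified(df, "SCORE", min_n=3)
        s = norms.stratum(20, "male", "high")
        assert (s.n, s.mean, s.sd) == (3, 10.0, 2.0)
        rec = {"age": 20, "sex": "male", "education_band": "high",
               "SCORE": 13.0}
        assert stratified_z(rec, norms) == pytest.approx(1.5)
        rec["SCORE"] = 10.0
        assert stratified_z(rec, norms) == 0.0
        rec["SCORE"] = 8.0
        assert stratified_z(rec, norms) == pytest.approx(-1.0)

    def test_full_factorial_has_24_strata(self):
        rows = []
        for (lo, hi) in AGE_BANDS:
            for sex in ("male", "female"):
                for edu in ("low", "high"):
                    for k in range(3):
                        rows.append(
                            {"age": lo + k, "sex": sex,
                             "education_band": edu, "SCORE": float(k)}
                        )
        norms = fit_stratified(pd.DataFrame(rows), "SCORE")
        assert len(norms.strata) == 24

    def test_unusable_stratum_raises(self):
        df = pd.DataFrame(
            {"age": [20, 21], "sex": "male", "education_band": "high",
             "SCORE": [5.0, 5.0]}
        )
        norms = fit_stratified(df, "SCORE", min_n=2)
        rec = {"age": 20, "sex": "male", "education_band": "high",
               "SCORE": 5.0}
        with pytest.raises(NotNormableError):
            stratified_z(rec, norms)       # sd == 0

    def test_empty_stratum_flagged_not_fatal(self):
        df = pd.DataFrame(
            {"age": [20] * 10, "sex": "male", "education_band": "high",
             "SCORE": np.arange(10.0)}
        )
        norms = fit_stratified(df, "SCORE")
        with pytest.raises(NotNormableError, match="empty stratum"):
            norms.stratum(70, "female", "low")


class TestRegression:
    def test_noise_free_exact_recovery(self):
        df = _linear_cohort(200, seed=1, sigma=0.0)
        # add negligible noise to avoid a degenerate zero residual SD
        rng = np.random.default_rng(0)
        df["SCORE"] = df["SCORE"] + rng.normal(0, 1e-9, len(df))
        norms = fit_regression(df, "SCORE")
        assert norms.intercept == pytest.approx(5.039, abs=1e-6)
        assert norms.beta_age == pytest.approx(0.20, abs=1e-8)
        assert norms.beta_sex == pytest.approx(-0.10, abs=1e-6)
        assert norms.beta_edu == pytest.approx(-2.31, abs=1e-6)

    def test_recovery_within_two_se_over_seeds(self):
        """The demographic OLS recovers the generating age slope within
        two reported standard errors in nearly all replicates."""
        ok = 0
        for seed in range(20):
            df = _linear_cohort(728, seed=seed)
            norms = fit_regression(df, "SCORE")
            if abs(norms.beta_age - 0.20) <= 2 * 0.03:
                ok += 1
        assert ok >= 18

    def test_planted_outlier_removed_at_4_over_n(self):
        df = _linear_cohort(150, seed=3, sigma=1.0)
        df.loc[df.index[0], "SCORE"] += 200.0      # gross high-leverage error
        outlier_id = df.iloc[0]["id"]
        norms = fit_regression(df, "SCORE")
        assert outlier_id in norms.removed_ids
        assert norms.cooks_threshold == pytest.approx(4 / 150)
        assert norms.n_used < 150
        # oracle: Cook's distance of the planted point exceeds 4/n
        y = df["SCORE"].to_numpy()
        X = np.column_stack(
            [np.ones(len(df)), df["age"], df["sex_code"], df["edu_code"]]
        )
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        resid = y - H @ y
        p = X.shape[1]
        s2 = resid @ resid / (len(df) - p)
        h = np.diag(H)
        cooks = resid**2 / (p * s2) * h / (1 - h) ** 2
        assert cooks[0] > 4 / 150

    def test_regression_z_hand_computed(self):
        df = _linear_cohort(300, seed=5)
        norms = fit_regression(df, "SCORE")
        rec = {"age": 50, "sex": "female", "education_band": "high",
               "SCORE": 30.0}
        pred = (norms.intercept + norms.beta_age * 50 + norms.beta_sex * 1
                + norms.beta_edu * 1)
        assert regression_z(rec, norms) == pytest.approx(
            (30.0 - pred) / norms.residual_sd
        )
        rec["SCORE"] = pred
        assert regression_z(rec, norms) == pytest.approx(0.0)


class TestZToPercentile:
    def test_zero_maps_to_50(self):
        assert z_to_percentile(0.0, "higher_better") == 50
        assert z_to_percentile(0.0, "lower_better") == 50

    def test_95th_percentile_z(self):
        assert z_to_percentile(1.6449, "higher_better") == 95

    def test_sign_reversal_for_error_measures(self):
        # +1.6449 SDs of *errors* is poor performance: 5th percentile
        assert z_to_percentile(1.6449, "lower_better") == 5

    def test_clipping_to_1_99(self):
        assert z_to_percentile(10.0, "higher_better") == 99
        assert z_to_percentile(-10.0, "higher_better") == 1

    def test_residual_over_sd(self):
        assert 3.0 / 1.5 == 2.0 and z_to_percentile(2.0, "higher_better") == 98


class TestAgreementProperties:
    def test_methods_track_latent_rank_on_gaussian_data(self):
        """On homoscedastic Gaussian data both classical percentile methods
        correlate strongly with the generating latent residual rank."""
        df = _linear_cohort(2000, seed=8)
        df["latent"] = df["SCORE"] - (
            5.039 + 0.20 * df["age"] - 0.10 * df["sex_code"]
            - 2.31 * df["edu_code"]
        )
        reg = fit_regression(df, "SCORE")
        strat = fit_stratified(df, "SCORE")
        from cognorm.cohort_io import OutcomeSpec

        spec = OutcomeSpec("SCORE", "beta", "higher_better", -1e9, 1e9)
        recs = df.to_dict("records")
        reg_p, strat_p, latent = [], [], []
        for rec in recs:
            try:
                sp = stratified_percentile(rec, strat, spec)
            except NotNormableError:
                continue
            strat_p.append(sp)
            reg_p.append(regression_percentile(rec, reg, spec))
            latent.append(rec["latent"])
        assert stats.spearmanr(reg_p, latent).statistic > 0.9
        assert stats.spearmanr(strat_p, latent).statistic > 0.9

    def test_ceiling_artefact_limits_stratified_percentile(self):
        """When over a quarter of a stratum scores a perfect 0 on an error
        measure, a perfect score cannot reach a high stratified percentile."""
        rng = np.random.default_rng(4)
        n = 400
        scores = np.where(rng.random(n) < 0.35, 0.0,
                          rng.gamma(2.0, 6.0, size=n))
        df = pd.DataFrame(
            {"age": rng.integers(18, 25, n), "sex": "male",
             "education_band": "high", "ERR": scores}
        )
        norms = fit_stratified(df, "ERR")
        from cognorm.cohort_io import OutcomeSpec

        spec = OutcomeSpec("ERR", "zoib", "lower_better", 0, 1000)
        rec = {"age": 20, "sex": "male", "education_band": "high", "ERR": 0.0}
        assert (df["ERR"] == 0).mean() > 0.25
        assert stratified_percentile(rec, norms, spec) < 90
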