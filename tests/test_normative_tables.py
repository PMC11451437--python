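import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cognorm.cohort_io import DEFAULT_OUTCOMES, OutcomeSpec
from cognorm.likelihoods import BetaParams, beta_rvs, inv_logit
from cognorm.normative_tables import (
    LEVELS,
    PercentileResult,
    PercentileTable,
    build_percentile_table,
    export_norms,
    midband_percentile,
    read_norm_table,
    score_to_percentile,
    smooth_table,
)


class _StubFit:
    """Duck-typed results object with a deterministic predictive."""

    class _Model:
        def __init__(self, spec):
            self.spec = spec

    def __init__(self, spec, draw_fn, subgroup="all"):
        self.model = self._Model(spec)
        self.subgroup = subgroup
        self._draw_fn = draw_fn

    def predictive_draws(self, age, n_draws, rng):
        return self._draw_fn(age, n_draws, rng)


def _table(thresholds, direction="higher_better", ages=None, outcome="RVPA"):
    thresholds = np.asarray(thresholds, dtype=float)
    ages = np.arange(18, 18 + thresholds.shape[1]) if ages is None else ages
    return PercentileTable(
        outcome=outcome, subgroup="all", ages=ages, thresholds=thresholds,
        direction=direction, smoothed=False, n_draws=0,
    )


class TestBuildTable:
    def test_point_mass_predictive_gives_constant_thresholds(self):
        spec = OutcomeSpec("SWMS", "hurdle_nb", "lower_better", 2, 14,
                           offset=2, integer_scored=True)
        fit = _StubFit(spec, lambda age, n, rng: np.full(n, 7.0))
        table = build_percentile_table(fit, ages=[20, 30], n_draws=100)
        assert np.all(table.thresholds == 7.0)

    def test_uniform_predictive_matches_closed_form_quantiles(self):
        spec = OutcomeSpec("U", "beta", "higher_better", 0, 1)
        fit = _StubFit(spec, lambda age, n, rng: rng.random(n))
        table = build_percentile_table(fit, ages=[40], n_draws=20_000, seed=1)
        np.testing.assert_allclose(
            table.thresholds[:, 0], LEVELS / 100.0, atol=0.01
        )

    def test_draw_count_default_is_20000(self, rvpa_fit):
        table = build_percentile_table(rvpa_fit, ages=[30])
        assert table.n_draws == 20_000

    def test_lower_better_thresholds_invert_quantiles(self):
        # fixed uniform sample: performance level k must take the (100-k)%
        # raw quantile for an error score
        spec = OutcomeSpec("E", "zoib", "lower_better", 0, 1)
        fit = _StubFit(spec, lambda age, n, rng: np.linspace(0, 1, n))
        table = build_percentile_table(fit, ages=[40], n_draws=10_000)
        # level 99 (best performance) ~ 1% raw quantile (few errors)
        assert table.thresholds[98, 0] < table.thresholds[0, 0]
        assert table.thresholds[98, 0] == pytest.approx(0.01, abs=0.01)

    def test_levels_monotone_for_fixed_age(self, rvpa_fit):
        table = build_percentile_table(rvpa_fit, ages=[25, 65], n_draws=4000)
        sign = 1.0 if table.direction == "higher_better" else -1.0
        diffs = np.diff(sign * table.thresholds, axis=0)
        assert np.all(diffs >= 0)


class TestSmoothing:
    def test_already_monotone_row_unchanged(self):
        t = _table([[10, 12, 12, 13]] * 99, direction="lower_better")
        smoothed = smooth_table(t)
        np.testing.assert_array_equal(smoothed.thresholds, t.thresholds)
        assert smoothed.smoothed

    def test_rising_trend_equals_running_max_oracle(self):
        row = [10, 12, 11, 13]
        t = _table([row] * 99, direction="lower_better")
        out = smooth_table(t).thresholds[0]
        # brute-force left fold oracle
        acc, oracle = -np.inf, []
        for v in row:
            acc = max(acc, v)
            oracle.append(acc)
        np.testing.assert_array_equal(out, oracle)
        assert list(out) == [10, 12, 12, 13]

    def test_falling_trend_equals_running_min_oracle(self):
        row = [0.9, 0.8, 0.85]
        t = _table([row] * 99, direction="higher_better")
        out = smooth_table(t).thresholds[0]
        assert list(out) == [0.9, 0.8, 0.8]

    @settings(max_examples=50, deadline=None)
    @given(
        hnp.arrays(np.float64, (99, 12),
                   elements=st.floats(0, 100, allow_nan=False)),
        st.sampled_from(["higher_better", "lower_better"]),
    )
    def test_idempotent_and_only_moves_with_trend(self, thresholds, direction):
        t = _table(thresholds, direction=direction)
        once = smooth_table(t)
        twice = smooth_table(once)
        np.testing.assert_array_equal(once.thresholds, twice.thresholds)
        delta = once.thresholds - t.thresholds
        if direction == "lower_better":
            assert np.all(delta >= 0)      # running max never decreases
        else:
            assert np.all(delta <= 0)
        # smoothed rows are monotone in the trend direction
        diffs = np.diff(once.thresholds, axis=1)
        assert np.all(diffs >= 0) if direction == "lower_better" else np.all(
            diffs <= 0
        )


class TestTieRule:
    @pytest.mark.parametrize(
        "lo,hi,expected", [(88, 99, 94), (50, 50, 50), (10, 13, 12), (1, 99, 50)]
    )
    def test_midband_rounds_up(self, lo, hi, expected):
        assert midband_percentile(lo, hi) == expected

    def test_band_invariant_enforced(self):
        with pytest.raises(ValueError):
            PercentileResult(percentile=5, band_low=10, band_high=20,
                             score=0, age=20, subgroup="all")


class TestScoreToPercentile:
    def test_tied_band_lookup_example(self):
        # perfect error score shared by the 88th..99th levels -> 94th
        col = np.concatenate([np.linspace(50, 1, 87), np.zeros(12)])
        t = _table(col[:, None], direction="lower_better", ages=[30],
                   outcome="PALTEA")
        res = score_to_percentile(0.0, 30, t)
        assert (res.band_low, res.band_high, res.percentile) == (88, 99, 94)

    def test_untied_score_single_level(self):
        col = np.arange(1, 100, dtype=float) / 100.0
        t = _table(col[:, None], ages=[40])
        res = score_to_percentile(0.50, 40, t)
        assert res.band_low == res.band_high == 50
        assert res.percentile == 50

    def test_score_between_thresholds(self):
        col = np.arange(1, 100, dtype=float) / 100.0
        t = _table(col[:, None], ages=[40])
        res = score_to_percentile(0.505, 40, t)   # between p50 and p51
        assert (res.band_low, res.band_high) == (50, 50)

    def test_extremes_collapse_to_1_and_99(self):
        col = np.linspace(0.2, 0.9, 99)
        t = _table(col[:, None], ages=[40])
        assert score_to_percentile(0.05, 40, t).percentile == 1
        assert score_to_percentile(0.95, 40, t).band_low == 99

    def test_age_outside_grid_rejected(self):
        t = _table(np.linspace(0.1, 0.9, 99)[:, None], ages=[40])
        with pytest.raises(ValueError, match="not in table grid"):
            score_to_percentile(0.5, 41, t)

    def test_score_outside_outcome_range_rejected(self):
        col = np.linspace(1, 60, 99)
        t = _table(col[:, None], direction="lower_better", ages=[30],
                   outcome="PALTEA")
        with pytest.raises(ValueError, match="outside"):
            score_to_percentile(80.0, 30, t)

    def test_monotone_in_score(self):
        rng = np.random.default_rng(5)
        col = np.sort(np.round(rng.random(99), 2))
        t = _table(col[:, None], ages=[22])
        pcts = [
            score_to_percentile(s, 22, t).percentile
            for s in np.linspace(0, 1, 101)
        ]
        assert np.all(np.diff(pcts) >= 0)


class TestCalibration:
    def test_fresh_draws_score_uniformly(self, rvpa_fit):
        """Percentiles of fresh draws from the fitted model against its own
        table are approximately uniform."""
        table = build_percentile_table(rvpa_fit, ages=[30], n_draws=20_000,
                                       seed=2)
        rng = np.random.default_rng(77)
        fresh = rvpa_fit.predictive_draws(30, n_draws=10_000, rng=rng)
        pcts = np.array(
            [score_to_percentile(s, 30, table).percentile for s in fresh]
        )
        assert abs(pcts.mean() - 50.0) < 1.5
        # Kolmogorov distance from the discrete uniform on 1..99
        ecdf = np.searchsorted(np.sort(pcts), LEVELS, side="right") / pcts.size
        assert np.max(np.abs(ecdf - LEVELS / 99.0)) < 0.03


class TestExport:
    def test_round_trip(self, tmp_path, rvpa_fit):
        table = smooth_table(
            build_percentile_table(rvpa_fit, ages=range(20, 31), n_draws=2000)
        )
        paths = export_norms([table], tmp_path)
        back = read_norm_table(paths[0])
        np.testing.assert_allclose(back.thresholds, table.thresholds)
        assert back.smoothed and back.direction == table.direction
        assert np.array_equal(back.ages, table.ages)

    def test_one_file_per_subgroup_outcome(self, tmp_path):
        tables = []
        col = np.linspace(0.1, 0.9, 99)[:, None]
        for outcome in DEFAULT_OUTCOMES:
            for sg in ("all", "male", "female", "male_high", "male_low",
                       "female_high", "female_low"):
                t = PercentileTable(outcome=outcome, subgroup=sg,
                                    ages=np.array([40]), thresholds=col,
                                    direction="higher_better", smoothed=False,
                                    n_draws=10)
                tables.append(t)
        paths = export_norms(tables, tmp_path)
        assert len(paths) == 42
        assert len(list(tmp_path.glob("*.csv"))) == 42

    def test_metadata_records_smoothing(self, tmp_path, rvpa_fit):
        import json

        table = build_percentile_table(rvpa_fit, ages=[30], n_draws=500)
        export_norms([smooth_table(table)], tmp_path)
        meta = json.loads(
            (tmp_path / "norms_RVPA_all.json").read_text()
        )
        assert meta["smoothed"] is True


def test_plot_table_smoke(rvpa_fit):
    import matplotlib

    matplotlib.use("Agg")
    from cognorm.normative_tables import plot_table

    table = build_percentile_table(rvpa_fit, ages=range(20, 26), n_draws=500)
    ax = plot_table(table)
    assert len(ax.lines) == 5
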