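"""Categorical survey expansion and gamma fitting."""

import numpy as np
import pytest
from scipy import stats

import mndpath as m
from mndpath.survey import DAYS_PER_MONTH, EmptyTableError, SurveyCategory, SurveyTable


def make_table(counts, question="q"):
    return SurveyTable(question, m.standard_categories(counts))


def two_bin_table(c0, c1):
    return SurveyTable(
        "q",
        (
            SurveyCategory(0.0, 30.0, c0),
            SurveyCategory(30.0, 91.0, c1),
        ),
    )


class TestSurveyTable:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            SurveyTable("q", (SurveyCategory(0, 30, 1), SurveyCategory(20, 60, 1)))

    def test_open_ended_only_last(self):
        with pytest.raises(ValueError, match="open-ended"):
            SurveyTable("q", (SurveyCategory(0, None, 1), SurveyCategory(30, 60, 1)))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="count"):
            two_bin_table(-1, 5)

    def test_total_count_sums_usable_responses(self):
        assert make_table([3, 5, 0, 0, 0, 0, 2]).total_count == 10


class TestExpandCategories:
    def test_single_occupied_category_bounds(self):
        table = two_bin_table(0, 50)
        x = m.expand_categories(table, 1000, rng=0)
        assert np.all((x >= 30.0) & (x < 91.0))

    def test_two_equal_categories_split_evenly(self):
        table = two_bin_table(50, 50)
        x = m.expand_categories(table, 100_000, rng=1)
        frac_below = np.mean(x < 30.0)
        se = np.sqrt(0.25 / x.size)
        assert abs(frac_below - 0.5) < 3 * se

    def test_equal_counts_median_falls_in_fourth_category(self):
        # 7 equal bins: the median of the uniform mixture lies in bin 4
        table = make_table([10] * 7)
        x = m.expand_categories(table, 100_000, rng=2)
        med = np.median(x)
        fourth = table.categories[3]
        assert fourth.lower <= med < fourth.upper

    def test_all_zero_counts_is_an_error(self):
        with pytest.raises(EmptyTableError):
            m.expand_categories(make_table([0] * 7), 100, rng=0)

    def test_open_ended_top_width(self):
        table = make_table([0, 0, 0, 0, 0, 0, 9])
        x = m.expand_categories(table, 1000, rng=3, top_width=100.0)
        lower = table.categories[-1].lower
        assert np.all((x >= lower) & (x <= lower + 100.0))

    def test_fixed_seed_is_bit_identical(self):
        table = make_table([5, 10, 20, 10, 5, 3, 1])
        a = m.expand_categories(table, 500, rng=7)
        b = m.expand_categories(table, 500, rng=7)
        np.testing.assert_array_equal(a, b)


class TestFitGammaToSamples:
    def test_parameter_recovery_from_exact_gamma_draws(self):
        rng = np.random.default_rng(10)
        x = rng.gamma(2.0, 90.0, 100_000)
        spec = m.fit_gamma_to_samples(x, minimum=0.0)
        assert spec.mean == pytest.approx(180.0, rel=0.02)
        assert spec.shape == pytest.approx(2.0, rel=0.05)

    def test_constant_samples_give_degenerate_spec(self):
        spec = m.fit_gamma_to_samples(np.full(200, 33.0), minimum=3.0)
        assert spec.is_degenerate
        assert spec.mean == pytest.approx(30.0)
        assert spec.minimum == 3.0

    def test_sample_below_minimum_is_a_domain_error(self):
        with pytest.raises(ValueError, match="minimum"):
            m.fit_gamma_to_samples(np.linspace(1.0, 10.0, 200), minimum=5.0)

    def test_moment_method_matches_sample_moments(self):
        rng = np.random.default_rng(11)
        x = 5.0 + rng.gamma(3.0, 20.0, 50_000)
        spec = m.fit_gamma_to_samples(x, minimum=5.0, method="moments")
        assert spec.mean == pytest.approx(np.mean(x) - 5.0)
        assert spec.sd == pytest.approx(np.std(x - 5.0, ddof=1))


class TestPipelineRecovery:
    """Bin gamma draws into the 7 survey categories, expand, refit."""

    def _censored_mle_oracle(self, table, top_width=365.0):
        # independent route: scipy interval-censored gamma MLE
        low = np.array([c.lower for c in table.categories])
        up = np.array(
            [c.lower + top_width if c.upper is None else c.upper for c in table.categories]
        )
        cnt = np.array([c.count for c in table.categories])
        intervals = np.repeat(np.column_stack([low, up]), cnt, axis=0)
        shape, _, scale = stats.gamma.fit(stats.CensoredData(interval=intervals), floc=0)
        return shape * scale, shape

    @pytest.mark.parametrize("n_draws, tol_mean", [(10_000, 0.04), (100_000, 0.02)])
    def test_recovery_tolerance_shrinks_with_n(self, n_draws, tol_mean):
        rng = np.random.default_rng(42)
        table = m.bin_durations(rng.gamma(2.0, 90.0, n_draws))
        spec = m.fit_survey_table(table, rng=1)
        assert spec.mean == pytest.approx(180.0, rel=tol_mean)

    def test_refined_fit_matches_censored_mle_oracle(self):
        rng = np.random.default_rng(42)
        table = m.bin_durations(rng.gamma(2.0, 90.0, 100_000))
        spec = m.fit_survey_table(table, rng=1)
        oracle_mean, oracle_shape = self._censored_mle_oracle(table)
        assert spec.mean == pytest.approx(oracle_mean, rel=0.01)
        assert spec.shape == pytest.approx(oracle_shape, rel=0.03)

    def test_uniform_expansion_refit_within_ten_percent(self):
        rng = np.random.default_rng(42)
        table = m.bin_durations(rng.gamma(2.0, 90.0, 100_000))
        samples = m.expand_categories(table, 100_000, rng=1)
        spec = m.fit_gamma_to_samples(samples, minimum=0.0)
        assert spec.mean == pytest.approx(180.0, rel=0.10)


class TestSurveyCsv:
    def test_round_trip(self, tmp_path):
        table = SurveyTable(
            "q9.1", m.standard_categories([40, 180, 160, 90, 60, 70, 21]), excluded_count=78
        )
        path = tmp_path / "survey.csv"
        m.write_survey_csv(table, path)
        back = m.read_survey_csv(path)
        assert back == table
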