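"""Association statistics: chi-square, odds ratios, correlation, OLS, logistic."""

import math

import numpy as np
import pandas as pd
import pytest

from climsens.ontology import ValidationError
from climsens.stats import (
    ContingencyTable2x2,
    LogisticModelSpec,
    SeparationWarning,
    chi_square_2x2,
    h_index_quartiles,
    logistic_fit,
    model_frame,
    odds_ratio,
    ols_slope,
    pearson_correlation,
    run_model_battery,
)


def chi2_oracle(t: ContingencyTable2x2) -> float:
    """Hand-rolled sum((O - E)^2 / E) over the four cells."""
    obs = t.as_array()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / t.n
    return float(((obs - exp) ** 2 / exp).sum())


class TestChiSquare:
    def test_independence_gives_zero(self):
        r = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert r.estimate == pytest.approx(0.0, abs=1e-12)
        assert r.effect_size_phi == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_example(self):
        r = chi_square_2x2(ContingencyTable2x2(20, 5, 5, 20))
        assert r.estimate == pytest.approx(18.0, abs=1e-12)
        assert r.effect_size_phi == pytest.approx(0.6, abs=1e-12)
        assert r.df == (1,)

    def test_matches_hand_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            t = ContingencyTable2x2(*rng.integers(1, 40, size=4))
            assert chi_square_2x2(t).estimate == pytest.approx(chi2_oracle(t), rel=1e-10)

    def test_phi_equals_binary_pearson_r(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            t = ContingencyTable2x2(*rng.integers(1, 30, size=4))
            x = np.repeat([1, 1, 0, 0], [t.a, t.b, t.c, t.d])
            y = np.repeat([1, 0, 1, 0], [t.a, t.b, t.c, t.d])
            r = pearson_correlation(x, y).estimate
            assert chi_square_2x2(t).effect_size_phi == pytest.approx(abs(r), abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestOddsRatio:
    def test_cross_product(self):
        assert odds_ratio(ContingencyTable2x2(2, 1, 1, 2)).estimate == pytest.approx(4.0)

    def test_null_table_ci_spans_one(self):
        r = odds_ratio(ContingencyTable2x2(10, 10, 10, 10))
        assert r.estimate == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high

    def test_woolf_interval(self):
        r = odds_ratio(ContingencyTable2x2(30, 10, 10, 30))
        se = math.sqrt(1 / 30 + 1 / 10 + 1 / 10 + 1 / 30)
        assert r.estimate == pytest.approx(9.0)
        assert r.ci_low == pytest.approx(9.0 * math.exp(-1.959963984540054 * se))
        assert r.ci_high == pytest.approx(9.0 * math.exp(1.959963984540054 * se))

    def test_zero_cell(self):
        with pytest.raises(ValidationError):
            odds_ratio(ContingencyTable2x2(5, 0, 3, 4))
        r = odds_ratio(ContingencyTable2x2(5, 0, 3, 4), haldane=True)
        assert r.estimate == pytest.approx((5.5 * 4.5) / (0.5 * 3.5))


class TestCorrelationAndOLS:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x).estimate == pytest.approx(1.0)
        assert pearson_correlation(x, -x).estimate == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), np.arange(5.0))

    def test_exact_line(self):
        x = np.arange(20.0)
        r = ols_slope(x, 2 * x + 3)
        assert r.estimate == pytest.approx(2.0, abs=1e-10)
        assert r.df == (1, 18)

    def test_slope_equals_cov_over_var(self):
        """Two-pass covariance/variance oracle for the slope."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = 1.5 * x + rng.normal(size=200)
        r = ols_slope(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        assert r.estimate == pytest.approx(float((xc * yc).sum() / (xc ** 2).sum()), rel=1e-10)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(11)
        n = 10_000
        x = rng.poisson(2.0, size=n).astype(float)
        y = 1.1 * x + rng.normal(0, 5, size=n)
        r = ols_slope(x, y)
        se = (r.ci_high - r.ci_low) / (2 * 1.959963984540054)
        assert abs(r.estimate - 1.1) < 3 * se


class TestQuartiles:
    def test_examples(self):
        assert list(h_index_quartiles([1, 2, 3, 4])) == [1, 2, 3, 4]
        assert list(h_index_quartiles([5, 5, 5, 5])) == [1, 1, 1, 1]

    def test_permutation_follows_values(self):
        rng = np.random.default_rng(5)
        h = rng.integers(0, 100, size=40)
        labels = h_index_quartiles(h)
        perm = rng.permutation(40)
        assert list(h_index_quartiles(h[perm])) == list(labels[perm])

    def test_labels_monotone_in_value(self):
        rng = np.random.default_rng(9)
        h = rng.integers(0, 50, size=60)
        labels = h_index_quartiles(h)
        order = np.argsort(h, kind="stable")
        assert (np.diff(labels[order]) >= 0).all()


class TestLogistic:
    def test_binary_predictor_matches_cross_product(self):
        t = ContingencyTable2x2(18, 7, 9, 21)
        x = np.repeat([1, 1, 0, 0], [t.a, t.b, t.c, t.d])
        y = np.repeat([1, 0, 1, 0], [t.a, t.b, t.c, t.d])
        (res,) = logistic_fit(pd.DataFrame({"y": y, "x": x}), LogisticModelSpec("y", ("x",)))
        assert res.estimate == pytest.approx(odds_ratio(t).estimate, abs=1e-8)

    def test_constant_predictor_rank_deficient(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1], "x": [1, 1, 1, 1]})
        with pytest.raises(ValidationError):
            logistic_fit(df, LogisticModelSpec("y", ("x",)))

    def test_quartile_expansion_terms(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame({"y": rng.integers(0, 2, 80), "h": rng.integers(0, 60, 80)})
        results = logistic_fit(df, LogisticModelSpec("y", ("h",), frozenset({"h"})))
        assert [r.term for r in results] == ["h:Q2", "h:Q3", "h:Q4"]

    def test_listwise_deletion(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1, np.nan, 1, 0, 1], "x": [0, 1, 0, 1, 1, 0, 1, 1]})
        (res,) = logistic_fit(df, LogisticModelSpec("y", ("x",)))
        assert res.n == 7

    def test_separation_warns_and_flags(self):
        df = pd.DataFrame({"y": [0] * 10 + [1] * 10, "x": [0] * 10 + [1] * 10})
        with pytest.warns(SeparationWarning):
            (res,) = logistic_fit(df, LogisticModelSpec("y", ("x",)))
        assert res.separation

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"y": [0, 1, 2, 1], "x": [0, 1, 0, 1]})
        with pytest.raises(ValidationError):
            logistic_fit(df, LogisticModelSpec("y", ("x",)))


class TestModelBattery:
    def test_model_frame_shape(self, cohort):
        profiles, attributes = cohort
        frame = model_frame(profiles, attributes)
        assert len(frame) == len(profiles)
        assert frame["zoonotic"].isna().sum() == sum(
            1 for a in attributes.values() if a.host_class.value == "unknown"
        )

    def test_battery_structure(self, cohort):
        profiles, attributes = cohort
        report = run_model_battery(profiles, attributes)
        assert report["zoonotic_chi_square"].statistic_name == "chi_square"
        assert report["zoonotic_chi_square"].n == sum(
            1 for a in attributes.values() if a.host_class.value != "unknown"
        )
        assert set(report["zoonotic_univariable"]) == {
            "route_direct_contact", "route_waterborne", "route_foodborne",
        }
        assert set(report["emerging_rain_model"]) == {
            "rain_positive", "h_index:Q2", "h_index:Q3", "h_index:Q4",
        }
        assert report["countries_on_drivers_ols"].df == (1, len(profiles) - 2)
        # multivariable terms are a subset of the univariably significant ones
        significant = {t for t, r in report["zoonotic_univariable"].items() if r.significant}
        assert set(report["zoonotic_multivariable_terms"]) <= significant

    def test_zoonotic_effect_detected_under_strong_or(self, cohort):
        """With a built-in zoonotic/sensitivity odds ratio of 6 the 2x2 should light up."""
        profiles, attributes = cohort
        report = run_model_battery(profiles, attributes)
        assert report["zoonotic_chi_square"].significant
        assert report["or_vs_human_only"].estimate > 1
        assert report["or_vs_animal_only"].estimate > 1
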