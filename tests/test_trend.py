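"""Binned Poisson trend, inter-arrival MLE, risk forecasting and smoothing."""

import math
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from gvtrends.simulate import simulate_nhpp_events
from gvtrends.trend import (
    DAYS_PER_MONTH,
    NHPPTrendModel,
    bin_counts,
    compare_aic,
    fit_trend,
    interarrival_mle,
    predict_monthly_rate,
    risk_table,
    smooth_interarrival,
)

A, B = 0.55683, 0.05033


class TestBinCounts:
    def test_adjacent_years_share_biannual_bin(self):
        df = bin_counts([date(1982, 3, 1), date(1983, 11, 1)], width_years=2)
        assert df["count"].tolist() == [2]
        assert df["year_offset"].tolist() == [0]

    def test_conservation(self):
        dates = simulate_nhpp_events(A, B, 1982.0, 2018.37, seed=10)
        df = bin_counts(dates, width_years=2, study_end=date(2018, 5, 31))
        assert df["count"].sum() == len(dates)

    def test_biannual_equals_summed_annual_pairs(self):
        dates = simulate_nhpp_events(A, B, 1982.0, 2017.99, seed=11)
        end = date(2017, 12, 31)
        annual = bin_counts(dates, width_years=1, study_end=end)["count"].to_numpy()
        biannual = bin_counts(dates, width_years=2, study_end=end)["count"].to_numpy()
        np.testing.assert_array_equal(
            biannual, annual.reshape(-1, 2).sum(axis=1)
        )

    def test_pre_origin_incident_rejected(self):
        with pytest.raises(ValueError, match="origin"):
            bin_counts([date(1979, 1, 1)], origin_year=1982)

    def test_partial_final_bin_flagged(self):
        df = bin_counts([date(1982, 2, 1), date(2018, 5, 1)], width_years=2,
                        study_end=date(2018, 5, 31))
        assert bool(df["partial"].iloc[-1])
        assert 0.0 < df["exposure_frac"].iloc[-1] < 1.0


class TestFitTrend:
    def test_flat_series(self):
        import pandas as pd

        binned = pd.DataFrame(
            {"year_offset": 2 * np.arange(10), "count": [7] * 10,
             "exposure_frac": np.ones(10)}
        )
        f = fit_trend(binned, degree=1)
        assert f.slope == pytest.approx(0.0, abs=1e-8)
        assert f.intercept == pytest.approx(math.log(7), abs=1e-8)

    def test_noiseless_recovery_of_printed_coefficients(self):
        import pandas as pd

        t = 2.0 * np.arange(18)
        counts = np.round(np.exp(0.557 + 0.0503 * t))
        binned = pd.DataFrame(
            {"year_offset": t, "count": counts, "exposure_frac": np.ones(18)}
        )
        f = fit_trend(binned)
        # rounding counts to integers shifts the intercept by ~0.013 (small
        # early-bin counts round up); the slope is recovered well inside 1e-2
        assert f.intercept == pytest.approx(0.557, abs=2e-2)
        assert f.slope == pytest.approx(0.0503, abs=1e-2)

    def test_dispersion_near_one_when_equidispersed(self):
        import pandas as pd

        disps = []
        rng = np.random.default_rng(12)
        t = 2.0 * np.arange(18)
        mu = np.exp(0.55683 + 0.05033 * t)
        for _ in range(100):
            binned = pd.DataFrame(
                {"year_offset": t, "count": rng.poisson(mu),
                 "exposure_frac": np.ones(18)}
            )
            try:
                disps.append(fit_trend(binned).pearson_dispersion)
            except ValueError:
                continue
        assert 0.6 < float(np.median(disps)) < 1.5

    def test_all_zero_counts_rejected(self):
        import pandas as pd

        binned = pd.DataFrame(
            {"year_offset": [0.0, 2.0, 4.0, 6.0], "count": [0, 0, 0, 0],
             "exposure_frac": np.ones(4)}
        )
        with pytest.raises(ValueError):
            fit_trend(binned)

    def test_aic_definition(self):
        import pandas as pd

        binned = pd.DataFrame(
            {"year_offset": 2.0 * np.arange(8), "count": [2, 3, 2, 5, 4, 6, 7, 9],
             "exposure_frac": np.ones(8)}
        )
        f = fit_trend(binned)
        assert f.aic == pytest.approx(-2.0 * f._sm_results.llf + 2 * 2, rel=1e-12)


class TestCompareAic:
    def test_tie_prefers_biannual(self):
        dates = simulate_nhpp_events(A, B, 1982.0, 2017.99, seed=13)
        f = NHPPTrendModel(dates, width_years=2).fit()
        preferred, delta = compare_aic(f, f)
        assert preferred == "biannual" and delta == 0.0

    def test_biannual_usually_preferred_in_study_regime(self):
        wins = 0
        n = 40
        for s in range(n):
            dates = simulate_nhpp_events(A, B, 1982.0, 2018.37, seed=4000 + s)
            end = date(2018, 5, 31)
            fa = NHPPTrendModel(dates, width_years=1, study_end=end).fit()
            fb = NHPPTrendModel(dates, width_years=2, study_end=end).fit()
            wins += compare_aic(fa, fb)[0] == "biannual"
        assert wins > n / 2


class TestInterarrival:
    def test_unit_monthly_rate(self):
        step = timedelta(days=30.4375 * 2)  # exact mean gap 30.4375 needs float days
        d0 = date(1990, 1, 1)
        dates = [d0, d0 + timedelta(days=30), d0 + timedelta(days=61)]
        daily, monthly = interarrival_mle(dates)
        assert daily == pytest.approx(2 / 61)
        assert monthly == pytest.approx(2 / 61 * DAYS_PER_MONTH)

    def test_two_events_hundred_days(self):
        daily, _ = interarrival_mle([date(2000, 1, 1), date(2000, 4, 10)])
        assert daily == pytest.approx(0.01)

    def test_identical_endpoints_rejected(self):
        with pytest.raises(ValueError):
            interarrival_mle([date(2000, 1, 1), date(2000, 1, 1)])

    def test_scale_equivariance(self):
        d0 = date(1990, 1, 1)
        gaps = [13, 55, 8, 89, 34]
        for c in (1, 3):
            dates = [d0]
            for g in gaps:
                dates.append(dates[-1] + timedelta(days=g * c))
            daily, _ = interarrival_mle(dates)
            if c == 1:
                base = daily
        assert daily == pytest.approx(base / 3)


class TestRiskTable:
    def test_monotone_in_horizon_and_rate(self):
        t1 = risk_table(0.227, [1, 2, 3, 6, 9, 12]).table["probability"]
        assert (np.diff(t1) > 0).all()
        t2 = risk_table(0.468, [1, 2, 3, 6, 9, 12]).table["probability"]
        assert (t2.to_numpy() > t1.to_numpy()).all()

    def test_zero_horizon_and_long_horizon_limits(self):
        tab = risk_table(0.3, [0, 1, 1000]).table
        assert tab["probability"].iloc[0] == 0.0
        assert tab["probability"].iloc[-1] == pytest.approx(1.0, abs=1e-12)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            risk_table(0.3, [-1.0])

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            risk_table(0.0, [1.0])


class TestPredictMonthlyRate:
    def test_log24_intercept_gives_unit_rate(self):
        for offset in (0.0, 10.0, 37.0):
            assert predict_monthly_rate((math.log(24.0), 0.0), offset) == pytest.approx(1.0)

    def test_offset_zero_definition(self):
        assert predict_monthly_rate((A, B), 0.0) == pytest.approx(math.exp(A) / 24.0)

    def test_most_recent_year_offset_for_study_window(self):
        dates = [date(1982, 2, 1), date(2000, 1, 1), date(2018, 5, 1)]
        f = NHPPTrendModel(dates, width_years=2, study_end=date(2018, 5, 31)).fit()
        assert f.most_recent_year_offset == 37


class TestSmoother:
    def test_reproduces_linear_data(self):
        y = 2.0 + 3.0 * np.arange(25)
        np.testing.assert_allclose(smooth_interarrival(y, df=4), y, atol=1e-6)

    def test_interpolation_limit(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 40)
        res_low = np.abs(smooth_interarrival(y, df=10) - y).max()
        res_high = np.abs(smooth_interarrival(y, df=39) - y).max()
        assert res_high < res_low
        assert res_high < 0.1

    def test_decreasing_trend_recovered(self):
        rng = np.random.default_rng(8)
        y = np.exp(-np.arange(60) / 25) + 0.05 * rng.standard_normal(60)
        fit = smooth_interarrival(y, df=4)
        assert spearmanr(fit, np.arange(60)).statistic < -0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_interarrival([1.0, 2.0, 3.0], df=4)


@settings(max_examples=30, deadline=None)
@given(
    rate=st.floats(min_value=0.01, max_value=1.0),
    t1=st.floats(min_value=0.1, max_value=20.0),
    t2=st.floats(min_value=0.1, max_value=20.0),
)
def test_risk_probability_monotone_property(rate, t1, t2):
    lo, hi = sorted([t1, t2])
    if hi - lo < 1e-3:
        return
    tab = risk_table(rate, [lo, hi]).table["probability"]
    assert 0.0 < tab.iloc[0] < tab.iloc[1] < 1.0
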