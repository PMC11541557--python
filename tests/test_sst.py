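"""Heat-stress metric unit and property tests with brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefheat.sst import (
    ClimatologyProfile,
    DailySSTSeries,
    WindowCoverageError,
    annual_max_dhw,
    compute_mmm,
    delta_dhw,
    dhw,
    dhw_annual_max_trend,
    dhw_daily_series,
    exposure_metrics,
    EXPOSURE_METRIC_NAMES,
    hotspots,
    hs_exceedance_days,
    hs_mean,
    hs_sum,
    monthly_climatology,
    rotc_annual,
    rotc_clim,
    rotc_recent_max,
    sd_window,
)
from _helpers import make_series, seasonal_series


# ---------------------------------------------------------------------------
# Series validation
# ---------------------------------------------------------------------------


class TestSeriesValidation:
    def test_duplicate_dates_rejected(self):
        dates = pd.DatetimeIndex(["2000-01-01", "2000-01-02", "2000-01-02"])
        with pytest.raises(ValueError, match="duplicate date"):
            DailySSTSeries("s", dates, [27.0, 27.1, 27.2])

    def test_decreasing_dates_rejected(self):
        dates = pd.DatetimeIndex(["2000-01-02", "2000-01-01"])
        with pytest.raises(ValueError, match="increasing"):
            DailySSTSeries("s", dates, [27.0, 27.1])

    def test_implausible_temperature_rejected(self):
        with pytest.raises(ValueError, match="implausible"):
            make_series([27.0, 55.0, 27.0])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            DailySSTSeries("s", pd.DatetimeIndex([]), [])

    def test_short_gap_interpolated_with_warning(self):
        dates = pd.DatetimeIndex(
            ["2000-01-01", "2000-01-02", "2000-01-05", "2000-01-06"]
        )
        with pytest.warns(UserWarning, match="interpolated"):
            s = DailySSTSeries("s", dates, [27.0, 27.0, 30.0, 30.0])
        assert len(s.sst) == 6
        np.testing.assert_allclose(s.sst, [27.0, 27.0, 28.0, 29.0, 30.0, 30.0])

    def test_long_gap_stays_invalid(self):
        dates = pd.DatetimeIndex(["2000-01-01", "2000-01-10"])
        with pytest.warns(UserWarning, match="flagged invalid"):
            s = DailySSTSeries("s", dates, [27.0, 27.0])
        assert np.isnan(s.sst[1:-1]).all()
        with pytest.raises(WindowCoverageError, match="invalid days"):
            s.window_values("2000-01-10", 10)

    def test_window_outside_record_raises(self):
        s = make_series(np.full(30, 27.0))
        with pytest.raises(WindowCoverageError, match="outside"):
            s.window_values(s.end, 31)

    def test_window_includes_end_date(self):
        s = make_series(np.arange(10) + 20.0)
        np.testing.assert_array_equal(s.window_values(s.end, 3), [27.0, 28.0, 29.0])


# ---------------------------------------------------------------------------
# Climatology
# ---------------------------------------------------------------------------


class TestClimatology:
    def test_monthly_means_match_bruteforce(self):
        s = seasonal_series()
        mm = monthly_climatology(s, (1985, 2012))
        df = pd.Series(s.sst, index=s.dates)
        df = df[(df.index.year >= 1985) & (df.index.year <= 2012)]
        expected = df.groupby(df.index.month).mean().to_numpy()
        np.testing.assert_allclose(mm, expected, atol=1e-12)

    def test_mmm_is_hottest_month(self):
        s = seasonal_series(peak_doy=258)  # mid-September peak
        mm = monthly_climatology(s, (1985, 2012))
        assert compute_mmm(mm) == mm.max()
        assert int(np.argmax(mm)) + 1 == 9

    def test_too_few_baseline_years_rejected(self):
        s = seasonal_series(years=(2000, 2012))
        with pytest.raises(ValueError, match="complete baseline years"):
            monthly_climatology(s, (1985, 2012))

    def test_partial_baseline_warns_when_allowed(self):
        s = seasonal_series(years=(1988, 2012))  # 25 of 28 years
        with pytest.warns(UserWarning, match="baseline years"):
            mm = monthly_climatology(s, (1985, 2012))
        assert mm.shape == (12,)

    def test_profile_consistency(self):
        s = seasonal_series()
        prof = ClimatologyProfile.from_series(s, (1985, 2012))
        assert prof.mmm == pytest.approx(prof.monthly_mean.max())
        assert prof.rotc_clim == pytest.approx(rotc_clim(s, (1985, 2012)))


# ---------------------------------------------------------------------------
# Hotspots and DHW
# ---------------------------------------------------------------------------


class TestHotspotsDHW:
    def test_hotspots_clamped_at_zero(self):
        s = make_series([27.0, 28.0, 29.5])
        hs = hotspots(s, 28.0)
        np.testing.assert_allclose(hs.hs, [0.0, 0.0, 1.5])

    def test_constant_unit_hotspot_gives_twelve_dhw(self):
        s = make_series(np.full(84, 29.0))
        hs = hotspots(s, 28.0)
        assert dhw(hs, s.end, 84) == 12.0

    def test_subthreshold_hotspot_gives_zero_dhw(self):
        s = make_series(np.full(84, 28.9))
        hs = hotspots(s, 28.0)
        assert dhw(hs, s.end, 84) == 0.0

    def test_threshold_is_inclusive_for_dhw(self):
        # exactly 1.0 deg C counts toward the accumulation
        s = make_series(np.full(28, 29.0))
        hs = hotspots(s, 28.0)
        assert dhw(hs, s.end, 28) == pytest.approx(28.0 / 7.0)

    def test_exceedance_count_is_strict(self):
        # days at exactly the threshold do not count as exceedances
        s = make_series(np.concatenate([np.full(14, 29.0), np.full(14, 29.5)]))
        hs = hotspots(s, 28.0)
        assert hs_exceedance_days(hs, s.end, 28, 1.0) == 14
        assert hs_exceedance_days(hs, s.end, 28, 0.5) == 28

    def test_hs_sum_and_mean_bruteforce(self):
        rng = np.random.default_rng(0)
        vals = 27.5 + rng.normal(0, 0.8, 120)
        s = make_series(vals)
        hs = hotspots(s, 28.0)
        manual = np.maximum(vals[-28:] - 28.0, 0.0)
        assert hs_sum(hs, s.end, 28) == pytest.approx(manual.sum())
        assert hs_mean(hs, s.end, 3) == pytest.approx(
            np.maximum(vals[-3:] - 28.0, 0.0).mean()
        )

    @given(st.integers(0, 2**31 - 1))
    def test_dhw_window_nesting(self, seed):
        rng = np.random.default_rng(seed)
        vals = 28.0 + rng.normal(0.2, 0.8, 600)
        s = make_series(np.clip(vals, 20.0, 35.0))
        hs = hotspots(s, 28.0)
        d28 = dhw(hs, s.end, 28)
        d84 = dhw(hs, s.end, 84)
        d555 = dhw(hs, s.end, 555)
        assert 0.0 <= d28 <= d84 <= d555

    @given(st.integers(0, 2**31 - 1))
    def test_daily_dhw_matches_pointwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = 28.0 + rng.normal(0.3, 0.7, 200)
        s = make_series(np.clip(vals, 20.0, 35.0))
        daily = dhw_daily_series(s, 28.0, window_days=84)
        assert np.isnan(daily[:83]).all()
        hs = hotspots(s, 28.0)
        for i in (83, 120, 199):
            assert daily[i] == pytest.approx(dhw(hs, s.dates[i], 84))

    def test_delta_dhw_positive_when_current_hotter(self):
        # quiet previous year, hot spell this year
        vals = np.full(730, 27.0)
        vals[500:560] = 29.5  # current-year event
        s = make_series(vals, start="2015-01-01")
        d = delta_dhw(s, 28.0, s.end)
        assert d > 0
        # symmetric construction: event in the previous year flips the sign
        vals2 = np.full(730, 27.0)
        vals2[130:190] = 29.5
        s2 = make_series(vals2, start="2015-01-01")
        assert delta_dhw(s2, 28.0, s2.end) < 0

    def test_delta_dhw_needs_previous_year(self):
        s = make_series(np.full(200, 29.5), start="2015-01-01")
        with pytest.raises(ValueError, match="previous calendar year"):
            delta_dhw(s, 28.0, s.end)


# ---------------------------------------------------------------------------
# ROTC
# ---------------------------------------------------------------------------


class TestROTC:
    def test_linear_ramp_exact(self):
        # 0.03 deg C/day ramp across the whole year: weekly slope is 0.21
        vals = 20.0 + 0.03 * np.arange(365)
        s = make_series(vals, start="2001-01-01")
        assert rotc_annual(s, 2001) == pytest.approx(0.21, abs=1e-9)

    def test_constant_series_zero(self):
        s = make_series(np.full(365, 27.0), start="2001-01-01")
        assert rotc_annual(s, 2001) == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        doy = np.arange(1, 366, dtype=float)
        vals = 27.0 + 1.5 * np.cos(2 * np.pi * (doy - 258) / 365.25)
        vals += rng.normal(0, 0.1, 365)
        s1 = make_series(vals, start="2001-01-01")
        s2 = make_series(vals + 2.0, start="2001-01-01")
        assert rotc_annual(s2, 2001) == pytest.approx(rotc_annual(s1, 2001), abs=1e-12)

    def test_early_maximum_uses_previous_year(self):
        # maximum in week 4: the 12-week window must reach into the prior year
        dates = pd.date_range("2000-01-01", "2001-12-31", freq="D")
        doy = dates.dayofyear.to_numpy().astype(float)
        vals = 27.0 + 1.5 * np.cos(2 * np.pi * (doy - 25) / 365.25)
        s = DailySSTSeries("s", dates, vals)
        r = rotc_annual(s, 2001)
        assert np.isfinite(r) and r > 0

    def test_early_maximum_without_history_raises(self):
        vals = np.concatenate([np.full(40, 30.0), np.full(325, 25.0)])
        s = make_series(vals, start="2001-01-01")
        with pytest.raises(ValueError, match="previous year unavailable"):
            rotc_annual(s, 2001)

    def test_clim_equals_annual_for_identical_years(self):
        s = seasonal_series(years=(1985, 2012))
        annual = rotc_annual(s, 2000)
        assert rotc_clim(s, (1985, 2012)) == pytest.approx(annual, abs=1e-12)

    def test_recent_max_on_pure_ramp(self):
        vals = 20.0 + 0.03 * np.arange(400)
        s = make_series(np.clip(vals, None, 35.0))
        assert rotc_recent_max(s, s.dates[380]) == pytest.approx(0.21, abs=1e-9)

    def test_recent_max_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        vals = 27.0 + rng.normal(0, 0.5, 300)
        s = make_series(np.clip(vals, 20, 35))
        end = s.end
        slopes = []
        for back in range(84):
            w = s.window_values(end - pd.Timedelta(days=back), 84)
            weekly = w.reshape(12, 7).mean(axis=1)
            x = np.arange(12.0)
            x -= x.mean()
            slopes.append(float(x @ (weekly - weekly.mean()) / (x @ x)))
        assert rotc_recent_max(s, end) == pytest.approx(max(slopes), abs=1e-12)


# ---------------------------------------------------------------------------
# Variability, trend and the bundle
# ---------------------------------------------------------------------------


class TestVariabilityTrendBundle:
    def test_sd_window_matches_numpy(self):
        rng = np.random.default_rng(1)
        vals = 27.0 + rng.normal(0, 0.4, 120)
        s = make_series(vals)
        assert sd_window(s, s.end, 84) == pytest.approx(
            np.std(vals[-84:], ddof=1), abs=1e-12
        )

    def test_annual_max_dhw_monotone_events(self):
        # one heat event per year, growing: annual maxima must grow too
        dates = pd.date_range("2000-01-01", "2004-12-31", freq="D")
        vals = np.full(len(dates), 27.0)
        for k, year in enumerate(range(2000, 2005)):
            i0 = (pd.Timestamp(f"{year}-08-01") - dates[0]).days
            vals[i0 : i0 + 60] = 29.2 + 0.3 * k
        s = DailySSTSeries("s", dates, vals)
        maxima = annual_max_dhw(s, 28.0, range(2000, 2005))
        assert np.all(np.diff(maxima) > 0)

    def test_trend_recovers_linear_growth(self):
        # deterministic linearly growing events: GLS trend close to OLS oracle
        dates = pd.date_range("1990-01-01", "2009-12-31", freq="D")
        vals = np.full(len(dates), 27.0)
        for k, year in enumerate(range(1990, 2010)):
            i0 = (pd.Timestamp(f"{year}-08-01") - dates[0]).days
            vals[i0 : i0 + 60] = 29.1 + 0.05 * k
        s = DailySSTSeries("s", dates, vals)
        maxima = annual_max_dhw(s, 28.0, range(1990, 2010))
        t = np.arange(20.0)
        ols = np.polyfit(t, maxima, 1)[0]
        trend = dhw_annual_max_trend(s, 28.0, end_year=2009, start_year=1990)
        assert trend == pytest.approx(ols, rel=0.15)

    def test_trend_needs_ten_years(self):
        s = make_series(np.full(5 * 365, 29.5), start="2010-01-01")
        with pytest.raises(ValueError, match="need >= 10"):
            dhw_annual_max_trend(s, 28.0, end_year=2014, start_year=2010)

    def test_bundle_names_and_error_attribution(self):
        s = seasonal_series(years=(1985, 2017))
        prof = ClimatologyProfile.from_series(s, (1985, 2012))
        em = exposure_metrics(s, prof, "2016-10-15")
        d = em.as_dict()
        assert [k for k in d if k not in ("site_id", "sample_date")] == (
            EXPOSURE_METRIC_NAMES
        )
        # a sampling date too early for the 555-day window names the metric
        with pytest.raises(WindowCoverageError, match="metric hs_555days"):
            exposure_metrics(s, prof, "1986-01-01")
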