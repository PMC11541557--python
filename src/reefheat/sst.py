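"""Heat-stress and thermal-variability metrics from daily sea-surface temperature.

This module implements the remote-sensing side of the bleaching-vulnerability
toolkit: a per-site monthly climatology and its maximum monthly mean (MMM),
hotspots (positive daily anomalies above the MMM), Degree Heating Weeks (DHW)
over configurable trailing windows, hotspot sums / means / exceedance-day
counts, the seasonal warming rate ROTC (trend of weekly mean temperature over
the twelve weeks leading into the annual weekly maximum) and its
climatological average, the generalized-least-squares trend of annual maximum
DHW, and the year-on-year DHW difference.

All window arithmetic is in whole calendar days, trailing windows include the
sampling date, and temperatures are degrees Celsius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailySSTSeries",
    "ClimatologyProfile",
    "HotspotSeries",
    "ExposureMetrics",
    "monthly_climatology",
    "compute_mmm",
    "hotspots",
    "dhw",
    "dhw_daily_series",
    "hs_sum",
    "hs_mean",
    "hs_exceedance_days",
    "rotc_annual",
    "rotc_clim",
    "rotc_recent_max",
    "sd_window",
    "dhw_annual_max_trend",
    "delta_dhw",
    "exposure_metrics",
    "EXPOSURE_METRIC_NAMES",
]

#: Plausible open-ocean SST bounds used for ingest validation (deg C).
SST_RANGE = (-5.0, 40.0)

#: Daily gaps up to this length are linearly interpolated on ingest.
MAX_INTERP_GAP = 3

#: The 17 remote-sensing metric names, in reporting order (Table-style naming).
EXPOSURE_METRIC_NAMES = [
    "mmm",
    "rotc_clim",
    "rotc_84days",
    "sd_84days",
    "hs_3days",
    "hs_28days",
    "hs_84days",
    "hs_555days",
    "hs1_28days",
    "hs1_84days",
    "hs2_28days",
    "hs2_84days",
    "dhw_28days",
    "dhw",
    "dhw_555days",
    "trend_dhw",
    "delta_dhw",
]


class WindowCoverageError(ValueError):
    """A trailing window is not fully covered by valid daily values."""


@dataclass
class DailySSTSeries:
    """Gap-free (or explicitly flagged) daily SST record for one site.

    Parameters
    ----------
    site_id:
        Site identifier.
    dates:
        Daily, strictly increasing calendar dates. Internal storage is a
        contiguous daily index from the first to the last date; gaps of up to
        :data:`MAX_INTERP_GAP` days are linearly interpolated (with a warning),
        longer gaps are kept as NaN and invalidate any window covering them.
    sst:
        Temperatures in deg C, one per input date.
    """

    site_id: str
    dates: pd.DatetimeIndex
    sst: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.sst, dtype=float)
        if len(dates) != len(values):
            raise ValueError("dates and sst must have equal length")
        if len(dates) == 0:
            raise ValueError("empty SST series")
        if dates.has_duplicates:
            dup = dates[dates.duplicated()][0]
            raise ValueError(f"duplicate date in SST series: {dup.date()}")
        if not dates.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < SST_RANGE[0] or finite.max() > SST_RANGE[1]):
            bad = finite[(finite < SST_RANGE[0]) | (finite > SST_RANGE[1])][0]
            raise ValueError(
                f"implausible SST value {bad:.2f} deg C outside {SST_RANGE}"
            )
        full = pd.date_range(dates[0], dates[-1], freq="D")
        if len(full) != len(dates):
            s = pd.Series(values, index=dates).reindex(full)
            isna = s.isna().to_numpy()
            n_missing = int(isna.sum())
            s_interp = s.interpolate(method="linear", limit_area="inside")
            # only whole gaps of at most MAX_INTERP_GAP days are filled;
            # longer gaps stay invalid end to end
            runs = np.split(
                np.flatnonzero(isna), np.where(np.diff(np.flatnonzero(isna)) > 1)[0] + 1
            )
            filled = s_interp.to_numpy()
            for run in runs:
                if len(run) > MAX_INTERP_GAP:
                    filled[run] = np.nan
            s_interp = pd.Series(filled, index=full)
            n_left = int(s_interp.isna().sum())
            warnings.warn(
                f"site {self.site_id}: {n_missing} missing days; "
                f"{n_missing - n_left} interpolated (gap <= {MAX_INTERP_GAP} d), "
                f"{n_left} flagged invalid",
                stacklevel=2,
            )
            dates, values = full, s_interp.to_numpy()
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "sst", values)

    # -- positional helpers -------------------------------------------------

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def _pos(self, date) -> int:
        return (pd.Timestamp(date) - self.start).days

    def window_values(self, end_date, window_days: int) -> np.ndarray:
        """Values of the trailing window of ``window_days`` ending on ``end_date``.

        The window includes ``end_date``. Raises :class:`WindowCoverageError`
        listing missing dates when the window is not fully covered.
        """
        end = pd.Timestamp(end_date)
        p1 = self._pos(end)
        p0 = p1 - window_days + 1
        if p0 < 0 or p1 >= len(self.sst):
            lo = end - pd.Timedelta(days=window_days - 1)
            raise WindowCoverageError(
                f"site {self.site_id}: window {lo.date()}..{end.date()} "
                f"outside record {self.start.date()}..{self.end.date()}"
            )
        vals = self.sst[p0 : p1 + 1]
        if np.isnan(vals).any():
            missing = self.dates[p0 : p1 + 1][np.isnan(vals)]
            raise WindowCoverageError(
                f"site {self.site_id}: window ending {end.date()} has "
                f"{len(missing)} invalid days (first: {missing[0].date()})"
            )
        return vals

    def year_values(self, year: int) -> np.ndarray:
        """All daily values of one calendar year (raises if not fully covered)."""
        start = pd.Timestamp(year=year, month=1, day=1)
        end = pd.Timestamp(year=year, month=12, day=31)
        ndays = (end - start).days + 1
        return self.window_values(end, ndays)

    def complete_years(self, lo: int, hi: int) -> list[int]:
        """Calendar years in [lo, hi] fully covered by valid values."""
        out = []
        for y in range(lo, hi + 1):
            try:
                self.year_values(y)
            except WindowCoverageError:
                continue
            out.append(y)
        return out


@dataclass
class HotspotSeries:
    """Daily positive anomalies above the MMM (deg C, clamped at zero)."""

    site_id: str
    dates: pd.DatetimeIndex
    hs: np.ndarray

    def _pos(self, date) -> int:
        return (pd.Timestamp(date) - self.dates[0]).days

    def window_values(self, end_date, window_days: int) -> np.ndarray:
        end = pd.Timestamp(end_date)
        p1 = self._pos(end)
        p0 = p1 - window_days + 1
        if p0 < 0 or p1 >= len(self.hs):
            raise WindowCoverageError(
                f"site {self.site_id}: hotspot window ending {end.date()} "
                f"({window_days} d) outside record"
            )
        vals = self.hs[p0 : p1 + 1]
        if np.isnan(vals).any():
            missing = self.dates[p0 : p1 + 1][np.isnan(vals)]
            raise WindowCoverageError(
                f"site {self.site_id}: hotspot window ending {end.date()} has "
                f"{len(missing)} invalid days (first: {missing[0].date()})"
            )
        return vals


# ---------------------------------------------------------------------------
# Climatology
# ---------------------------------------------------------------------------


def monthly_climatology(
    series: DailySSTSeries,
    baseline: tuple[int, int] = (1985, 2012),
    allow_partial: bool = False,
) -> np.ndarray:
    """Twelve monthly mean temperatures over the baseline years.

    Month ``m``'s value is the mean of every daily SST whose calendar month is
    ``m`` within the baseline years. Requires at least 20 complete baseline
    years unless ``allow_partial`` is set; partial (but >= 20 y) coverage
    proceeds with a warning.
    """
    lo, hi = baseline
    years = series.complete_years(lo, hi)
    n_target = hi - lo + 1
    if len(years) < 20 and not allow_partial:
        raise ValueError(
            f"site {series.site_id}: only {len(years)} complete baseline years "
            f"in {lo}-{hi} (need >= 20; pass allow_partial=True to override)"
        )
    if len(years) < n_target:
        warnings.warn(
            f"site {series.site_id}: climatology from {len(years)}/{n_target} "
            f"baseline years",
            stacklevel=2,
        )
    if not years:
        raise ValueError(f"site {series.site_id}: no complete baseline years")
    mask = np.isin(series.dates.year, years) & np.isfinite(series.sst)
    months = series.dates.month.to_numpy()[mask]
    vals = series.sst[mask]
    out = np.empty(12)
    for m in range(1, 13):
        out[m - 1] = vals[months == m].mean()
    return out


def compute_mmm(monthly_mean: np.ndarray) -> float:
    """Maximum monthly mean: the climatological mean of the hottest month."""
    monthly_mean = np.asarray(monthly_mean, dtype=float)
    if monthly_mean.shape != (12,):
        raise ValueError("monthly_mean must hold exactly 12 values")
    return float(monthly_mean.max())


@dataclass
class ClimatologyProfile:
    """Per-site baseline climatology: monthly means, MMM and ROTC_clim."""

    site_id: str
    baseline_start: int
    baseline_end: int
    monthly_mean: np.ndarray
    mmm: float
    rotc_clim: float

    def __post_init__(self) -> None:
        self.monthly_mean = np.asarray(self.monthly_mean, dtype=float)
        if self.monthly_mean.shape != (12,):
            raise ValueError("monthly_mean must hold exactly 12 values")
        if not np.isclose(self.mmm, self.monthly_mean.max()):
            raise ValueError("mmm must equal max(monthly_mean)")

    @classmethod
    def from_series(
        cls,
        series: DailySSTSeries,
        baseline: tuple[int, int] = (1985, 2012),
        allow_partial: bool = False,
    ) -> "ClimatologyProfile":
        mm = monthly_climatology(series, baseline, allow_partial=allow_partial)
        return cls(
            site_id=series.site_id,
            baseline_start=baseline[0],
            baseline_end=baseline[1],
            monthly_mean=mm,
            mmm=compute_mmm(mm),
            rotc_clim=rotc_clim(series, baseline, allow_partial=allow_partial),
        )


# ---------------------------------------------------------------------------
# Hotspots and DHW
# ---------------------------------------------------------------------------


def hotspots(series: DailySSTSeries, mmm: float) -> HotspotSeries:
    """Daily hotspot series: ``max(SST - MMM, 0)`` elementwise."""
    if not np.isfinite(mmm):
        raise ValueError("mmm must be finite")
    hs = np.where(np.isnan(series.sst), np.nan, np.maximum(series.sst - mmm, 0.0))
    return HotspotSeries(site_id=series.site_id, dates=series.dates, hs=hs)


def dhw(
    hs: HotspotSeries,
    end_date,
    window_days: int = 84,
    hs_threshold: float = 1.0,
) -> float:
    """Degree Heating Weeks over a trailing window (deg C-weeks).

    Sums hotspots of at least ``hs_threshold`` (inclusive) over the
    ``window_days`` ending on ``end_date`` and divides by 7 to express the
    accumulation per week. The conventional window is 84 days; 28- and 555-day
    variants use the same rule.
    """
    vals = hs.window_values(end_date, window_days)
    return float(vals[vals >= hs_threshold].sum() / 7.0)


def hs_sum(hs: HotspotSeries, end_date, window_days: int) -> float:
    """Sum of hotspots over a trailing window (no 1 deg C threshold)."""
    return float(hs.window_values(end_date, window_days).sum())


def hs_mean(hs: HotspotSeries, end_date, window_days: int = 3) -> float:
    """Mean hotspot over a trailing window (default: the last three days)."""
    return float(hs.window_values(end_date, window_days).mean())


def hs_exceedance_days(
    hs: HotspotSeries, end_date, window_days: int, threshold: float
) -> int:
    """Number of days whose hotspot exceeds ``threshold`` in the window."""
    vals = hs.window_values(end_date, window_days)
    return int((vals > threshold).sum())


def dhw_daily_series(
    series: DailySSTSeries,
    mmm: float,
    window_days: int = 84,
    hs_threshold: float = 1.0,
) -> np.ndarray:
    """Trailing-window DHW evaluated at every date of the record.

    Entries whose window is incomplete (start of record, or covering an
    invalid day) are NaN. Aligned with ``series.dates``.
    """
    hs = np.where(np.isnan(series.sst), np.nan, np.maximum(series.sst - mmm, 0.0))
    contrib = np.where(np.isnan(hs), np.nan, np.where(hs >= hs_threshold, hs, 0.0))
    nan_mask = np.isnan(contrib)
    filled = np.where(nan_mask, 0.0, contrib)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    cnan = np.concatenate([[0], np.cumsum(nan_mask)])
    n = len(filled)
    out = np.full(n, np.nan)
    idx = np.arange(window_days - 1, n)
    window_sum = csum[idx + 1] - csum[idx + 1 - window_days]
    window_nan = cnan[idx + 1] - cnan[idx + 1 - window_days]
    out[idx] = np.where(window_nan > 0, np.nan, window_sum / 7.0)
    return out


# ---------------------------------------------------------------------------
# ROTC: rate of temperature change (seasonal warming rate)
# ---------------------------------------------------------------------------

_ROTC_WEEKS = 12  # trend window: 12 weekly blocks ending at the annual maximum


def _weekly_means_year(series: DailySSTSeries, year: int) -> np.ndarray:
    """52 weekly means for one year: consecutive 7-day blocks from 1 January.

    The partial trailing block (day 365 and any leap day remainder) is
    dropped. Raises when the year is not fully covered.
    """
    vals = series.year_values(year)
    return vals[: 52 * 7].reshape(52, 7).mean(axis=1)


def _slope(y: np.ndarray) -> float:
    """Least-squares slope of y against 0..len(y)-1."""
    x = np.arange(len(y), dtype=float)
    x = x - x.mean()
    return float(x @ (y - y.mean()) / (x @ x))


def rotc_annual(series: DailySSTSeries, year: int) -> float:
    """Seasonal warming rate for one year (deg C per week).

    Weekly mean temperatures are computed over consecutive 7-day blocks
    anchored at 1 January; the least-squares slope of weekly mean against
    week index is taken over the 12 weeks ending at (and including) the
    year's maximum weekly mean. When the maximum falls within the first 11
    weeks the window is completed with the previous year's trailing weeks.
    """
    w = _weekly_means_year(series, year)
    # ties broken toward the latest week (a constant series then yields slope 0)
    kmax = len(w) - 1 - int(np.argmax(w[::-1]))
    if kmax >= _ROTC_WEEKS - 1:
        window = w[kmax - _ROTC_WEEKS + 1 : kmax + 1]
    else:
        need = _ROTC_WEEKS - 1 - kmax
        try:
            prev = _weekly_means_year(series, year - 1)
        except WindowCoverageError as err:
            raise ValueError(
                f"site {series.site_id}: {year} weekly maximum in week "
                f"{kmax + 1} but previous year unavailable for the trend window"
            ) from err
        window = np.concatenate([prev[52 - need :], w[: kmax + 1]])
    return _slope(window)


def rotc_clim(
    series: DailySSTSeries,
    baseline: tuple[int, int] = (1985, 2012),
    allow_partial: bool = False,
) -> float:
    """Climatological seasonal warming rate: mean annual ROTC over the baseline."""
    lo, hi = baseline
    years = series.complete_years(lo, hi)
    n_target = hi - lo + 1
    if len(years) < 20 and not allow_partial:
        raise ValueError(
            f"site {series.site_id}: only {len(years)} complete baseline years "
            f"in {lo}-{hi} (need >= 20; pass allow_partial=True to override)"
        )
    if not years:
        raise ValueError(f"site {series.site_id}: no complete baseline years")
    if len(years) < n_target:
        warnings.warn(
            f"site {series.site_id}: ROTC_clim from {len(years)}/{n_target} "
            f"baseline years",
            stacklevel=2,
        )
    return float(np.mean([rotc_annual(series, y) for y in years]))


def rotc_recent_max(series: DailySSTSeries, sample_date) -> float:
    """Maximum ROTC observed in the 84 days before the sampling date.

    For every day d in the trailing 84 days (inclusive of ``sample_date``)
    the 84 days ending at d are grouped into 12 consecutive 7-day blocks and
    the least-squares slope of the block means is taken; the maximum slope is
    returned (deg C per week).
    """
    end = pd.Timestamp(sample_date)
    scan = 84
    total = scan + 84 - 1  # 167 days of history
    vals = series.window_values(end, total)
    windows = np.lib.stride_tricks.sliding_window_view(vals, 84)  # (84, 84)
    weekly = windows.reshape(scan, _ROTC_WEEKS, 7).mean(axis=2)
    x = np.arange(_ROTC_WEEKS, dtype=float)
    x = x - x.mean()
    slopes = (weekly - weekly.mean(axis=1, keepdims=True)) @ x / (x @ x)
    return float(slopes.max())


def sd_window(series: DailySSTSeries, sample_date, window_days: int = 84) -> float:
    """Sample standard deviation (ddof=1) of SST over a trailing window."""
    vals = series.window_values(sample_date, window_days)
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# Long-term DHW metrics
# ---------------------------------------------------------------------------


def annual_max_dhw(
    series: DailySSTSeries, mmm: float, years: range | list[int]
) -> np.ndarray:
    """Per-year maximum of the daily 84-day DHW (NaN where no day is valid)."""
    daily = dhw_daily_series(series, mmm)
    yr = series.dates.year.to_numpy()
    out = np.full(len(list(years)), np.nan)
    for i, y in enumerate(years):
        sel = daily[yr == y]
        sel = sel[np.isfinite(sel)]
        if sel.size:
            out[i] = sel.max()
    return out


def dhw_annual_max_trend(
    series: DailySSTSeries,
    mmm: float,
    end_year: int,
    start_year: int = 1985,
) -> float:
    """GLS trend of annual maximum DHW (deg C-weeks per year).

    Annual maxima of the daily 84-day DHW from ``start_year`` to ``end_year``
    are regressed on year with an AR(1) error structure estimated by iterated
    feasible GLS (ordinary least squares is used when residuals are
    degenerate or the AR coefficient estimate exceeds 0.98 in magnitude).
    Negative trends are allowed.
    """
    years = list(range(start_year, end_year + 1))
    maxima = annual_max_dhw(series, mmm, years)
    valid = np.isfinite(maxima)
    if valid.sum() < 10:
        raise ValueError(
            f"site {series.site_id}: only {int(valid.sum())} years with valid "
            f"annual DHW maxima (need >= 10)"
        )
    y = maxima[valid]
    t = np.asarray(years, dtype=float)[valid]
    X = np.column_stack([np.ones_like(t), t - t[0]])
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    if np.std(resid) < 1e-12:
        return float(beta_ols[1])
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLSAR(y, X, rho=1)
        res = model.iterative_fit(maxiter=50)
        rho = float(np.atleast_1d(model.rho)[0])
    if not np.isfinite(rho) or abs(rho) > 0.98:
        return float(beta_ols[1])
    return float(res.params[1])


def delta_dhw(series: DailySSTSeries, mmm: float, sample_date) -> float:
    """Year-on-year DHW difference (deg C-weeks).

    (maximum daily 84-day DHW within the sampling calendar year, up to and
    including the sampling date) minus (maximum over the previous calendar
    year). Positive when the current event is hotter than last year's.
    """
    end = pd.Timestamp(sample_date)
    daily = dhw_daily_series(series, mmm)
    yr = series.dates.year.to_numpy()
    up_to = series.dates <= end
    cur = daily[(yr == end.year) & up_to]
    prev = daily[yr == end.year - 1]
    cur = cur[np.isfinite(cur)]
    prev = prev[np.isfinite(prev)]
    if cur.size == 0 or prev.size == 0:
        raise ValueError(
            f"site {series.site_id}: insufficient history for delta DHW at "
            f"{end.date()} (need the previous calendar year plus the current "
            f"year to date)"
        )
    return float(cur.max() - prev.max())


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class ExposureMetrics:
    """The 17 remote-sensing metrics evaluated at one site and sampling date."""

    site_id: str
    sample_date: pd.Timestamp
    mmm: float
    rotc_clim: float
    rotc_84days: float
    sd_84days: float
    hs_3days: float
    hs_28days: float
    hs_84days: float
    hs_555days: float
    hs1_28days: int
    hs1_84days: int
    hs2_28days: int
    hs2_84days: int
    dhw_28days: float
    dhw: float
    dhw_555days: float
    trend_dhw: float
    delta_dhw: float

    def as_dict(self) -> dict:
        d = {"site_id": self.site_id, "sample_date": self.sample_date}
        for name in EXPOSURE_METRIC_NAMES:
            d[name] = getattr(self, name)
        return d


def exposure_metrics(
    series: DailySSTSeries,
    profile: ClimatologyProfile,
    sample_date,
    trend_start_year: int = 1985,
) -> ExposureMetrics:
    """Compute all 17 remote-sensing metrics for one site and sampling date.

    Deterministic given its inputs; component errors are re-raised with the
    metric name attached.
    """
    end = pd.Timestamp(sample_date)
    hs = hotspots(series, profile.mmm)
    out: dict = {"site_id": series.site_id, "sample_date": end}

    def _compute(name, fn):
        try:
            out[name] = fn()
        except Exception as err:
            raise type(err)(f"metric {name}: {err}") from err

    out["mmm"] = profile.mmm
    out["rotc_clim"] = profile.rotc_clim
    _compute("rotc_84days", lambda: rotc_recent_max(series, end))
    _compute("sd_84days", lambda: sd_window(series, end, 84))
    _compute("hs_3days", lambda: hs_mean(hs, end, 3))
    _compute("hs_28days", lambda: hs_sum(hs, end, 28))
    _compute("hs_84days", lambda: hs_sum(hs, end, 84))
    _compute("hs_555days", lambda: hs_sum(hs, end, 555))
    _compute("hs1_28days", lambda: hs_exceedance_days(hs, end, 28, 1.0))
    _compute("hs1_84days", lambda: hs_exceedance_days(hs, end, 84, 1.0))
    _compute("hs2_28days", lambda: hs_exceedance_days(hs, end, 28, 2.0))
    _compute("hs2_84days", lambda: hs_exceedance_days(hs, end, 84, 2.0))
    _compute("dhw_28days", lambda: dhw(hs, end, 28))
    _compute("dhw", lambda: dhw(hs, end, 84))
    _compute("dhw_555days", lambda: dhw(hs, end, 555))
    _compute(
        "trend_dhw",
        lambda: dhw_annual_max_trend(
            series, profile.mmm, end_year=end.year, start_year=trend_start_year
        ),
    )
    _compute("delta_dhw", lambda: delta_dhw(series, profile.mmm, end))
    return ExposureMetrics(**out)
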