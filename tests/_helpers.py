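"""Shared series builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from reefheat.sst import DailySSTSeries


def make_series(values, start="2000-01-01", site_id="s1") -> DailySSTSeries:
    """Daily series from a value array, starting at ``start``."""
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailySSTSeries(site_id, dates, values)


def seasonal_series(
    years=(1985, 2012),
    mean=27.0,
    amplitude=1.5,
    peak_doy=258,
    site_id="s1",
) -> DailySSTSeries:
    """Noise-free seasonal cycle, identical in every year (pure day-of-year)."""
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    vals = mean + amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)
    return DailySSTSeries(site_id, dates, vals)
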