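import numpy as np
import pandas as pd
import pytest

from icepipe.ice_metrics import AnnualIceSeries, DailyIceSeries


@pytest.fixture
def make_daily():
    """Factory for synthetic daily area series on the 365-day calendar."""

    def _make(area_fn, n_years=1, start_year=2000, region_id="R"):
        t = np.arange(n_years * 365)
        year = start_year + t // 365
        doy = t % 365 + 1
        area = np.asarray([area_fn(y, d) for y, d in zip(year, doy)], dtype=float)
        return DailyIceSeries(region_id, year, doy, area)

    return _make


@pytest.fixture
def sinusoid():
    """Seasonal cycle with winter max at doy 75: mean M, amplitude A."""

    def _fn(M, A):
        return lambda y, d: M + A * np.cos(2 * np.pi * (d - 75) / 365.0)

    return _fn


@pytest.fixture
def make_annual():
    def _make(years, ice, region_id="R", midpoint=1e5):
        return AnnualIceSeries(region_id, np.asarray(years), np.asarray(ice), midpoint)

    return _make


@pytest.fixture
def captures_df():
    def _make(rows):
        return pd.DataFrame(rows, columns=["subpopulation", "year", "age", "cub_class"])

    return _make
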