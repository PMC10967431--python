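"""Synthetic daily weather emulating a Dutch annual cycle.

Daily outside temperature is a sinusoid (annual mean ~10.5 degC,
amplitude ~7 degC, peaking in late July) plus Gaussian day-to-day noise;
relative humidity follows an opposite-phase sinusoid around ~80% (drier
summers).  The generator stands in for unpublished on-farm weather logs:
it reproduces the seasonal cycle and day-to-day scatter but not weather
autocorrelation (fronts, heat waves) or diurnal structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["weather_fixture", "load_weather_csv", "save_weather_csv"]

#: day of year at which the temperature sinusoid crosses its mean rising
#: (puts the maximum around 20 July, typical for the Netherlands).
DEFAULT_PHASE_DAY = 110.0


def weather_fixture(
    seed: int,
    n_days: int = 365,
    mean_T: float = 10.5,
    amplitude_T: float = 7.0,
    sigma_T: float = 3.0,
    mean_RH: float = 80.0,
    amplitude_RH: float = 10.0,
    sigma_RH: float = 5.0,
    phase_day: float = DEFAULT_PHASE_DAY,
    start_day_of_year: int = 281,
) -> pd.DataFrame:
    """Generate ``n_days`` of daily weather.

    ``start_day_of_year`` anchors the seasonal phase of day 0 of the
    series (281 = 8 October, the first stocking date of the simulated
    year).  Identical seeds give bitwise-identical series.

    Returns a DataFrame with columns ``day``, ``T_out_C``, ``RH_out_pct``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    doy = (start_day_of_year + np.arange(n_days)) % 365
    cycle = np.sin(2.0 * np.pi * (doy - phase_day) / 365.0)
    t = mean_T + amplitude_T * cycle + rng.normal(0.0, sigma_T, n_days)
    rh = mean_RH - amplitude_RH * cycle + rng.normal(0.0, sigma_RH, n_days)
    rh = np.clip(rh, 20.0, 100.0)
    return pd.DataFrame({"day": np.arange(n_days), "T_out_C": t, "RH_out_pct": rh})


def load_weather_csv(path) -> pd.DataFrame:
    """Read a weather CSV with columns ``T_out_C`` and ``RH_out_pct``
    (a ``day`` or ``date`` column is preserved if present)."""
    df = pd.read_csv(path)
    missing = {"T_out_C", "RH_out_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    return df


def save_weather_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
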