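"""Thermal covariates: growing degree days and trailing-window means.

Annual growing degree days above a 5 degC base (GDD5) summarise the thermal
energy a lake receives in a year; the mean of GDD5 over the 10 years ending
at a survey year (T10bar) is the covariate the growth and longevity models
regress on, after z-scoring across all modelled lake-years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_gdd5",
    "gdd5_by_lake_year",
    "compute_window_mean",
    "window_mean_table",
    "CovariateScaler",
    "scale_covariate",
    "thermal_covariates",
]

GDD_BASE = 5.0


def compute_gdd5(daily_temps, base: float = GDD_BASE) -> float:
    """Cumulative degree-days above ``base`` for one lake-year.

    Sum over days of ``max(temp - base, 0)``; always >= 0.
    """
    t = np.asarray(daily_temps, dtype=float)
    if t.size == 0:
        raise ValueError("empty temperature series")
    return float(np.clip(t - base, 0.0, None).sum())


def _days_in_year(year: int) -> int:
    return 366 if (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)) else 365


def gdd5_by_lake_year(
    daily: pd.DataFrame,
    base: float = GDD_BASE,
    max_missing_frac: float = 0.0,
) -> pd.DataFrame:
    """Annual GDD per lake from a daily temperature table.

    ``daily`` has columns ``lake_id``, ``date`` (ISO-8601), ``temp_c``.
    A lake-year whose fraction of missing calendar days exceeds
    ``max_missing_frac`` raises, naming the lake-year.
    """
    df = daily.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    rows = []
    for (lake, year), grp in df.groupby(["lake_id", "year"], sort=True):
        n_expected = _days_in_year(int(year))
        missing = 1.0 - len(grp) / n_expected
        if missing > max_missing_frac + 1e-12:
            raise ValueError(
                f"lake {lake} year {year}: {missing:.1%} of days missing "
                f"(tolerance {max_missing_frac:.1%})"
            )
        rows.append((lake, int(year), compute_gdd5(grp["temp_c"].to_numpy(), base)))
    return pd.DataFrame(rows, columns=["lake_id", "year", "gdd5"])


def compute_window_mean(
    annual_gdd5: pd.Series,
    survey_year: int,
    window: int = 10,
    policy: str = "strict",
) -> float:
    """Mean annual GDD over the ``window`` years ending at ``survey_year``.

    ``annual_gdd5`` is indexed by calendar year.  Under the default strict
    policy every year of the window must be present; ``policy='available'``
    averages whatever years of the window exist.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    years = np.arange(survey_year - window + 1, survey_year + 1)
    present = annual_gdd5.index.intersection(years)
    if policy == "strict" and len(present) < window:
        missing = sorted(set(years) - set(present))
        raise ValueError(
            f"incomplete {window}-year history ending {survey_year}: missing {missing}"
        )
    if len(present) == 0:
        raise ValueError(f"no annual GDD values in window ending {survey_year}")
    return float(annual_gdd5.loc[present].mean())


def window_mean_table(
    gdd5_table: pd.DataFrame,
    surveys: pd.DataFrame,
    window: int = 10,
    policy: str = "strict",
) -> pd.DataFrame:
    """T-window means for every surveyed lake-year.

    ``surveys`` has (at least) columns ``lake_id`` and ``year``; one output
    row per distinct surveyed lake-year with column ``t_window_mean``.
    """
    out = []
    for lake, grp in gdd5_table.groupby("lake_id"):
        series = grp.set_index("year")["gdd5"]
        for year in sorted(surveys.loc[surveys["lake_id"] == lake, "year"].unique()):
            out.append(
                (lake, int(year), compute_window_mean(series, int(year), window, policy))
            )
    return pd.DataFrame(out, columns=["lake_id", "year", "t_window_mean"])


@dataclass(frozen=True)
class CovariateScaler:
    """Stored z-scoring record so model-scale values map back to degC*day."""

    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def scale_covariate(values) -> tuple[np.ndarray, CovariateScaler]:
    """Z-score ``values`` across all modelled lake-years.

    Returns the scaled array and the scaler needed to report derived
    quantities back on the original degC*day axis.  Requires at least two
    distinct values (zero variance is an error).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to scale")
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd <= 0:
        raise ValueError("zero variance: covariate cannot be scaled")
    scaler = CovariateScaler(mean, sd)
    return scaler.transform(x), scaler


def thermal_covariates(
    daily: pd.DataFrame,
    surveys: pd.DataFrame,
    window: int = 10,
    base: float = GDD_BASE,
    max_missing_frac: float = 0.0,
    policy: str = "strict",
) -> tuple[pd.DataFrame, CovariateScaler]:
    """Full covariate table for the modelled lake-years.

    Returns a table with columns ``lake_id``, ``year``, ``gdd5`` (survey
    year's own GDD), ``t_window_mean`` and ``t_scaled``, plus the scaler.
    """
    gdd = gdd5_by_lake_year(daily, base=base, max_missing_frac=max_missing_frac)
    tw = window_mean_table(gdd, surveys, window=window, policy=policy)
    merged = tw.merge(gdd, on=["lake_id", "year"], how="left")
    scaled, scaler = scale_covariate(merged["t_window_mean"].to_numpy())
    merged["t_scaled"] = scaled
    return merged[["lake_id", "year", "gdd5", "t_window_mean", "t_scaled"]], scaler
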