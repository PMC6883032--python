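"""Relative sea-level rise (RSLR) from annual tide-gauge records.

Each gauge's annual mean-sea-level series is smoothed with an ordinary
least-squares linear trend over the most recent 60 years, the window that
damps the decadal variability known to dominate shorter tide-gauge trends.
Gauges with only ~30 years of record are brought onto the 60-year basis
through a linear bridge fitted on gauges that support both windows.  Each
site is then assigned the trend of its nearest gauge (great-circle
distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from tidalcarbon.errors import TrendUnavailableError, ValidationError
from tidalcarbon.geo import haversine_km

log = logging.getLogger("tidalcarbon.rslr")

DEFAULT_WINDOW_YEARS = 60
DEFAULT_SHORT_WINDOW_YEARS = 30
#: fraction of annual values that must be present inside a trend window
DEFAULT_MIN_COVERAGE = 0.8


@dataclass
class TideGaugeSeries:
    """Annual mean-sea-level record of one gauge (gaps allowed as NaN)."""

    gauge_id: str
    lat: float
    lon: float
    years: np.ndarray
    msl_mm: np.ndarray
    true_slope: float | None = None  # set by the synthetic generator only

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.msl_mm = np.asarray(self.msl_mm, dtype=float)
        if self.years.shape != self.msl_mm.shape:
            raise ValidationError("years and msl_mm must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValidationError("years must be strictly increasing")
        if np.isfinite(self.msl_mm).sum() < 2:
            raise ValidationError("a gauge series needs at least 2 non-missing values")


@dataclass
class LinearTrend:
    """A fitted sea-level trend on the 60-yr (or bridged) basis."""

    gauge_id: str
    slope: float  # mm yr-1
    intercept: float  # mm, at year 0
    slope_se: float  # mm yr-1
    n_years: int
    window: tuple[int, int]
    bridged: bool = False
    lat: float = float("nan")
    lon: float = float("nan")


def fit_gauge_trend(
    series: TideGaugeSeries,
    window_years: int = DEFAULT_WINDOW_YEARS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> LinearTrend:
    """OLS trend of annual MSL on year over the most recent window.

    The window is the ``window_years`` calendar years ending at the last
    observed year.  Raises :class:`TrendUnavailableError` (not a numerical
    error) when fewer than ``min_coverage × window_years`` annual values
    fall inside it.
    """
    if window_years < 2:
        raise ValidationError("window_years must be at least 2")
    end = int(series.years.max())
    start = end - window_years + 1
    inside = (series.years >= start) & (series.years <= end) & np.isfinite(series.msl_mm)
    n = int(inside.sum())
    if n < min_coverage * window_years - 1e-9:
        raise TrendUnavailableError(
            f"gauge {series.gauge_id}: {n} of {window_years} annual values in [{start}, {end}]"
        )
    yrs = series.years[inside].astype(float)
    msl = series.msl_mm[inside]
    if np.allclose(msl, msl[0]):
        # constant series: slope 0 with zero residual variance
        return LinearTrend(series.gauge_id, 0.0, float(msl[0]), 0.0, n, (start, end), lat=series.lat, lon=series.lon)
    fit = sps.linregress(yrs, msl)
    return LinearTrend(
        gauge_id=series.gauge_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        n_years=n,
        window=(start, end),
        lat=series.lat,
        lon=series.lon,
    )


def bridge_short_records(
    pairs: Sequence[tuple[float, float]],
    shorts: Sequence[LinearTrend],
) -> tuple[list[LinearTrend], dict]:
    """Map 30-yr trends onto the 60-yr basis via a linear bridge.

    ``pairs`` are (trend30, trend60) slopes from gauges supporting both
    windows; the bridge is the OLS fit trend60 ~ trend30 (with intercept).
    Each short gauge's slope is mapped through the fit and flagged as
    bridged, with its slope SE inflated in quadrature by the bridge's
    residual SE.  Returns (bridged trends, bridge-fit summary).
    """
    if len(pairs) < 3:
        raise TrendUnavailableError(f"short-record bridging needs >= 3 training pairs, got {len(pairs)}")
    t30 = np.array([p[0] for p in pairs], dtype=float)
    t60 = np.array([p[1] for p in pairs], dtype=float)
    fit = sps.linregress(t30, t60)
    resid = t60 - (fit.intercept + fit.slope * t30)
    dof = len(pairs) - 2
    resid_se = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    summary = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "resid_se": resid_se,
        "n_pairs": len(pairs),
        "r": float(fit.rvalue),
    }
    bridged = []
    for tr in shorts:
        mapped = fit.intercept + fit.slope * tr.slope
        se = float(np.hypot(fit.slope * tr.slope_se, resid_se))
        bridged.append(replace(tr, slope=float(mapped), slope_se=se, bridged=True))
    return bridged, summary


def estimate_trends(
    series_list: Iterable[TideGaugeSeries],
    window_years: int = DEFAULT_WINDOW_YEARS,
    short_window_years: int = DEFAULT_SHORT_WINDOW_YEARS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Fit every gauge, bridging short records, and return a trends table.

    A gauge with a full 60-yr trend is never bridged.  Short gauges are
    bridged through the (trend30, trend60) relation of the long gauges;
    if fewer than 3 long gauges exist the short gauges are dropped with a
    warning.  Columns: gauge_id, lat, lon, slope_mm_yr, slope_se_mm_yr,
    window_start, window_end, n_years, bridged.
    """
    long_trends: list[LinearTrend] = []
    pairs: list[tuple[float, float]] = []
    shorts: list[LinearTrend] = []
    for series in series_list:
        try:
            t60 = fit_gauge_trend(series, window_years, min_coverage)
        except TrendUnavailableError:
            t60 = None
        if t60 is not None:
            long_trends.append(t60)
            try:
                t30 = fit_gauge_trend(series, short_window_years, min_coverage)
                pairs.append((t30.slope, t60.slope))
            except TrendUnavailableError:
                pass
            continue
        try:
            shorts.append(fit_gauge_trend(series, short_window_years, min_coverage))
        except TrendUnavailableError:
            log.warning("gauge %s: insufficient coverage for both windows; dropped", series.gauge_id)
    trends = list(long_trends)
    if shorts:
        try:
            bridged, summary = bridge_short_records(pairs, shorts)
            trends.extend(bridged)
            log.info(
                "bridged %d short gauges (fit slope %.3f, intercept %.3f, r %.3f)",
                len(bridged), summary["slope"], summary["intercept"], summary["r"],
            )
        except TrendUnavailableError as exc:
            log.warning("%s; %d short gauges dropped", exc, len(shorts))
    return pd.DataFrame(
        {
            "gauge_id": [t.gauge_id for t in trends],
            "lat": [t.lat for t in trends],
            "lon": [t.lon for t in trends],
            "slope_mm_yr": [t.slope for t in trends],
            "slope_se_mm_yr": [t.slope_se for t in trends],
            "window_start": [t.window[0] for t in trends],
            "window_end": [t.window[1] for t in trends],
            "n_years": [t.n_years for t in trends],
            "bridged": [t.bridged for t in trends],
        }
    )


def assign_rslr(lat: float, lon: float, trends: pd.DataFrame) -> tuple[float, str, float]:
    """RSLR of the nearest gauge: (slope mm yr⁻¹, gauge_id, distance km).

    Ties on distance break to the lexicographically lower gauge_id so
    assignment is deterministic.
    """
    if len(trends) == 0:
        raise ValidationError("no usable gauge trends to assign from")
    d = haversine_km(lat, lon, trends["lat"].to_numpy(), trends["lon"].to_numpy())
    d = np.atleast_1d(d)
    best = np.min(d)
    candidates = trends.loc[np.isclose(d, best, rtol=0.0, atol=1e-9)]
    row = candidates.sort_values("gauge_id").iloc[0]
    return float(row["slope_mm_yr"]), str(row["gauge_id"]), float(best)


def assign_rslr_sites(sites: pd.DataFrame, trends: pd.DataFrame) -> pd.DataFrame:
    """Overwrite each site's RSLR with its nearest gauge's trend.

    Adds gauge_id and gauge_distance_km provenance columns.
    """
    out = sites.copy()
    slopes, gauges, dists = [], [], []
    for lat, lon in zip(out["lat"].to_numpy(), out["lon"].to_numpy()):
        s, g, d = assign_rslr(lat, lon, trends)
        slopes.append(s)
        gauges.append(g)
        dists.append(d)
    out["rslr_mm_yr"] = slopes
    out["gauge_id"] = gauges
    out["gauge_distance_km"] = dists
    return out
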