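"""Upscale site CAR onto a wetland polygon inventory, with CI propagation.

Three estimators of the national (and regional / state / vegetation-level)
annual C sequestration are provided:

* **uniform** — one national mean CAR times the total wetland area;
* **stratified** — group mean CAR times group area, summed over groups
  (regions or vegetation classes);
* **spatial interpolation** — each polygon's CAR is the unweighted mean of
  the compiled sites within a 100-km radius of its centroid (SE = sample
  SD/√n); polygons with no or only one neighboring site fall back to their
  regional mean and SE.

Per-polygon fluxes are ``CAR × area × 1e-6`` (g C m⁻² yr⁻¹ × km² → Tg
yr⁻¹).  Standard errors of sums propagate assuming independent polygon
errors: ``δ_sum = sqrt(Σ δi²)`` and ``95% CI = 1.96 × δ_sum``.  Neighboring
polygons that share sites are not truly independent; a cluster-aware
variant that groups polygons with identical neighbor sets is available but
off by default (see docs/methods.md).
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from tidalcarbon.errors import ConfigurationError, ValidationError
from tidalcarbon.geo import haversine_km

log = logging.getLogger("tidalcarbon.upscale")

DEFAULT_RADIUS_KM = 100.0
#: g C m-2 yr-1 × km2 → Tg yr-1
KM2_TO_TG = 1e-6
Z95 = 1.96


def neighbors_within(lat: float, lon: float, sites: pd.DataFrame, radius_km: float = DEFAULT_RADIUS_KM) -> pd.DataFrame:
    """Sites within ``radius_km`` (boundary inclusive) of a centroid."""
    if radius_km <= 0:
        raise ValidationError("radius_km must be positive")
    d = haversine_km(lat, lon, sites["lat"].to_numpy(), sites["lon"].to_numpy())
    return sites.loc[np.atleast_1d(d) <= radius_km]


def regional_site_stats(sites: pd.DataFrame, value_col: str = "car_gC_m2_yr") -> pd.DataFrame:
    """Per-region mean and standard error of the mean of site CAR."""
    grouped = sites.groupby("region")[value_col]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    out.columns = ["region", "car_mean", "car_se", "n_sites"]
    out["car_se"] = out["car_se"].fillna(0.0)  # single-site regions
    return out


def polygon_flux(car_mean: float, car_se: float, area_km2: float) -> tuple[float, float]:
    """(flux, flux SE) in Tg yr⁻¹ for one polygon."""
    return car_mean * area_km2 * KM2_TO_TG, car_se * area_km2 * KM2_TO_TG


def upscale_inventory(
    polygons: pd.DataFrame,
    sites: pd.DataFrame,
    regional_stats: pd.DataFrame | None = None,
    radius_km: float = DEFAULT_RADIUS_KM,
) -> pd.DataFrame:
    """Per-polygon CAR estimates by radius interpolation with regional fallback.

    ``regional_stats`` (region, car_mean, car_se) defaults to the site
    table's own regional means.  A polygon with ≥ 2 sites in the radius
    gets their unweighted mean CAR and SE = sample SD/√n; with ≤ 1 it gets
    the regional mean and the regional mean's SE.  Returns one row per
    polygon with car_mean, car_se, ci95, n_neighbors, method, flux Tg yr⁻¹.
    """
    if radius_km <= 0:
        raise ValidationError("radius_km must be positive")
    if regional_stats is None:
        regional_stats = regional_site_stats(sites)
    reg = regional_stats.set_index("region")
    missing = set(polygons["region"]) - set(reg.index)
    if missing:
        raise ConfigurationError(f"regional_stats lacks regions: {sorted(missing)}")

    site_lat = sites["lat"].to_numpy()
    site_lon = sites["lon"].to_numpy()
    site_car = sites["car_gC_m2_yr"].to_numpy()
    p_lat = polygons["lat"].to_numpy()
    p_lon = polygons["lon"].to_numpy()

    car_mean = np.empty(len(polygons))
    car_se = np.empty(len(polygons))
    n_nb = np.empty(len(polygons), dtype=int)
    method = np.empty(len(polygons), dtype=object)

    # distance matrix in chunks to bound memory on large inventories
    chunk = max(1, int(4e6 // max(1, len(sites))))
    for lo in range(0, len(polygons), chunk):
        hi = min(lo + chunk, len(polygons))
        d = haversine_km(p_lat[lo:hi, None], p_lon[lo:hi, None], site_lat[None, :], site_lon[None, :])
        within = d <= radius_km
        for k in range(lo, hi):
            mask = within[k - lo]
            n = int(mask.sum())
            n_nb[k] = n
            if n >= 2:
                vals = site_car[mask]
                car_mean[k] = vals.mean()
                car_se[k] = vals.std(ddof=1) / np.sqrt(n)
                method[k] = "interpolated"
            else:
                row = reg.loc[polygons["region"].iat[k]]
                car_mean[k] = row["car_mean"]
                car_se[k] = row["car_se"]
                method[k] = "regional_fallback"

    out = polygons[["polygon_id", "region", "state", "vegetation", "area_km2"]].copy()
    out["car_mean"] = car_mean
    out["car_se"] = car_se
    out["ci95"] = Z95 * car_se
    out["n_neighbors"] = n_nb
    out["method"] = method
    out["flux_Tg_yr"] = car_mean * out["area_km2"].to_numpy() * KM2_TO_TG
    out["flux_se_Tg_yr"] = car_se * out["area_km2"].to_numpy() * KM2_TO_TG
    n_fb = int((out["method"] == "regional_fallback").sum())
    log.info("upscaled %d polygons (%d regional fallback) at radius %.0f km", len(out), n_fb, radius_km)
    return out


def aggregate(
    estimates: pd.DataFrame,
    by: str | None = None,
    z: float = Z95,
    cluster_col: str | None = None,
) -> pd.DataFrame:
    """Sum polygon fluxes to a level, propagating SEs in quadrature.

    ``by`` is a grouping column (region / state / vegetation) or None for
    the national total.  ``total_flux = Σ flux``, ``flux_se = sqrt(Σ
    flux_se²)`` and ``ci95 = z × flux_se`` under independent polygon
    errors.  ``cluster_col`` switches on the cluster-aware variant: fluxes
    and SEs are first summed *linearly* within each cluster (polygons with
    identical neighbor sets are perfectly correlated), then combined in
    quadrature across clusters.
    """
    if len(estimates) == 0:
        warnings.warn("aggregate() called with no estimates; returning a zero total", stacklevel=2)
        return pd.DataFrame(
            [{"level": "national" if by is None else by, "label": "total",
              "total_flux_Tg_yr": 0.0, "flux_se_Tg_yr": 0.0, "ci95_Tg_yr": 0.0, "n_polygons": 0}]
        )

    def _one(group: pd.DataFrame) -> pd.Series:
        if cluster_col is not None:
            per_cluster_se = group.groupby(cluster_col)["flux_se_Tg_yr"].sum()
            se = float(np.sqrt(np.sum(per_cluster_se.to_numpy() ** 2)))
        else:
            se = float(np.sqrt(np.sum(group["flux_se_Tg_yr"].to_numpy() ** 2)))
        return pd.Series(
            {
                "total_flux_Tg_yr": float(group["flux_Tg_yr"].sum()),
                "flux_se_Tg_yr": se,
                "ci95_Tg_yr": z * se,
                "n_polygons": len(group),
            }
        )

    if by is None:
        row = _one(estimates)
        row["level"] = "national"
        row["label"] = "CONUS"
        return pd.DataFrame([row])[["level", "label", "total_flux_Tg_yr", "flux_se_Tg_yr", "ci95_Tg_yr", "n_polygons"]]
    out = estimates.groupby(by).apply(_one, include_groups=False).reset_index()
    out.insert(0, "level", by)
    out = out.rename(columns={by: "label"})
    out["n_polygons"] = out["n_polygons"].astype(int)
    return out[["level", "label", "total_flux_Tg_yr", "flux_se_Tg_yr", "ci95_Tg_yr", "n_polygons"]]


def upscale_uniform(mean_car: float, total_area_km2: float) -> float:
    """National flux (Tg yr⁻¹) from one mean CAR over the whole area."""
    if total_area_km2 < 0:
        raise ValidationError("area must be non-negative")
    return mean_car * total_area_km2 * KM2_TO_TG


def upscale_stratified(group_means: Mapping[str, float], group_areas: Mapping[str, float]) -> float:
    """National flux (Tg yr⁻¹) from group mean CARs times group areas."""
    if set(group_means) != set(group_areas):
        raise ValidationError(
            f"group keys mismatch: means {sorted(group_means)} vs areas {sorted(group_areas)}"
        )
    if any(a < 0 for a in group_areas.values()):
        raise ValidationError("areas must be non-negative")
    return sum(group_means[g] * group_areas[g] * KM2_TO_TG for g in group_means)


def underestimation_pct(group_mean: float, reference_mean: float, ndigits: int | None = None) -> float:
    """Percent by which a reference mean under-represents a group mean.

    ``100 × (group_mean − reference_mean) / group_mean``; e.g. applying the
    national mean CAR to a hotspot region understates its flux by this
    share.  ``ndigits`` applies report-layer rounding.
    """
    if group_mean <= 0:
        raise ValidationError("group mean must be positive")
    pct = 100.0 * (group_mean - reference_mean) / group_mean
    return round(pct, ndigits) if ndigits is not None else pct
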