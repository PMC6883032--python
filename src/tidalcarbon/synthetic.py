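"""Synthetic site networks, tide gauges, inventories, and scenarios.

The generator emulates the statistical structure of a national tidal-wetland
compilation so every downstream stage is testable without downloads: seven
coastal watershed regions with published-compilation regional CAR / SAR /
RSLR statistics, vegetation-class C densities and area shares, a target
CAR–RSLR correlation of 0.40 across sites, clustered site and polygon
placement so 100-km radius queries find neighbors, gauges with known
ground-truth trends, and decadal RSLR / area-fraction trajectories ordered
by emissions scenario severity.

Geography is schematic — seven labeled bounding boxes along a synthetic
coastline — because the analysis needs distances and labels, not real
shapes.  All randomness flows from one root seed through named substreams
(layout / sites / gauges / inventory / scenarios), so partial pipelines are
reproducible and byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from tidalcarbon.errors import ConfigurationError
from tidalcarbon.project import DECADES, POP_THRESHOLDS, RCP_SCENARIOS, ScenarioSpec
from tidalcarbon.rslr import TideGaugeSeries

log = logging.getLogger("tidalcarbon.synthetic")

REGIONS = (
    "New England",
    "Mid Atlantic",
    "South Atlantic-Gulf",
    "Lower Mississippi",
    "Texas-Gulf",
    "California",
    "Pacific Northwest",
)

#: Regional CAR / C density / SAR / RSLR statistics (mean, SE of the mean,
#: and the compilation's observation count used to recover a site-level SD)
#: plus tidal-wetland area.  These ARE the study conditions the generator
#: reproduces; override them through SynthConfig for experiments.
REGIONAL_STATS: dict[str, dict[str, float]] = {
    "New England":         {"car_mean": 151.3, "car_se": 11.0, "n_car": 64, "sar_mean": 3.72, "sar_se": 0.22, "n_sar": 78, "rslr": 2.78, "area_km2": 512.0},
    "Mid Atlantic":        {"car_mean": 176.5, "car_se": 14.0, "n_car": 85, "sar_mean": 4.46, "sar_se": 0.33, "n_sar": 90, "rslr": 3.82, "area_km2": 3844.0},
    "South Atlantic-Gulf": {"car_mean": 123.6, "car_se": 11.0, "n_car": 69, "sar_mean": 3.95, "sar_se": 0.34, "n_sar": 68, "rslr": 2.95, "area_km2": 10359.0},
    "Lower Mississippi":   {"car_mean": 271.9, "car_se": 18.0, "n_car": 43, "sar_mean": 8.89, "sar_se": 0.44, "n_sar": 43, "rslr": 8.91, "area_km2": 8193.0},
    "Texas-Gulf":          {"car_mean": 237.8, "car_se": 16.0, "n_car": 2,  "sar_mean": 5.30, "sar_se": 0.90, "n_sar": 2,  "rslr": 6.59, "area_km2": 2340.0},
    "California":          {"car_mean": 103.8, "car_se": 8.0,  "n_car": 36, "sar_mean": 4.79, "sar_se": 0.43, "n_sar": 40, "rslr": 0.98, "area_km2": 269.0},
    "Pacific Northwest":   {"car_mean": 110.2, "car_se": 6.0,  "n_car": 11, "sar_mean": 3.27, "sar_se": 0.39, "n_sar": 11, "rslr": 0.98, "area_km2": 373.0},
}

#: Vegetation-class C density and sedimentation statistics plus area (km²).
VEG_STATS: dict[str, dict[str, float]] = {
    "tidal_freshwater": {"cdensity_mean": 0.038, "cdensity_se": 0.003, "n_cd": 44,  "org_mean": 311.0, "org_se": 37.0, "min_mean": 950.0,  "min_se": 206.0, "area_km2": 4828.8},
    "brackish":         {"cdensity_mean": 0.042, "cdensity_se": 0.002, "n_cd": 86,  "org_mean": 374.0, "org_se": 29.0, "min_mean": 1239.0, "min_se": 125.0, "area_km2": 5233.5},
    "salt_marsh":       {"cdensity_mean": 0.035, "cdensity_se": 0.001, "n_cd": 175, "org_mean": 323.0, "org_se": 19.0, "min_mean": 1092.0, "min_se": 94.0,  "area_km2": 13157.3},
    "mangrove":         {"cdensity_mean": 0.046, "cdensity_se": 0.002, "n_cd": 28,  "org_mean": 324.0, "org_se": 36.0, "min_mean": 586.0,  "min_se": 119.0, "area_km2": 2672.4},
}

#: schematic coastline boxes (lon_min, lon_max, lat_min, lat_max) — spaced
#: so 100-km neighborhoods do not leak across regions
REGION_BOXES: dict[str, tuple[float, float, float, float]] = {
    "New England":         (-71.0, -68.0, 42.0, 45.0),
    "Mid Atlantic":        (-76.0, -73.0, 37.0, 40.0),
    "South Atlantic-Gulf": (-82.0, -79.0, 29.0, 32.0),
    "Lower Mississippi":   (-92.0, -89.0, 28.5, 31.5),
    "Texas-Gulf":          (-97.0, -94.0, 26.0, 29.0),
    "California":          (-123.0, -120.0, 34.0, 37.0),
    "Pacific Northwest":   (-126.5, -123.5, 44.0, 47.0),
}

REGION_STATES: dict[str, tuple[str, ...]] = {
    "New England": ("MA", "ME", "CT"),
    "Mid Atlantic": ("NJ", "MD", "VA"),
    "South Atlantic-Gulf": ("FL", "GA", "NC"),
    "Lower Mississippi": ("LA", "MS", "LA"),
    "Texas-Gulf": ("TX", "TX", "TX"),
    "California": ("CA", "CA", "CA"),
    "Pacific Northwest": ("WA", "OR", "WA"),
}

_SUBSTREAMS = {"layout": 1, "sites": 2, "gauges": 3, "inventory": 4, "scenarios": 5}

#: end-of-century RSLR increment (mm yr-1) added on top of today's rate,
#: ordered by scenario severity
RCP_RISE_2100 = {"RCP2.6": 3.0, "RCP4.5": 5.0, "RCP8.5": 9.0}
#: 2100 national area fraction by accommodation-space population threshold:
#: most restricted loses ~a quarter of today's extent, least restricted
#: gains up to ~half through landward migration
AREA_FRACTION_2100 = {5: 0.78, 20: 0.92, 150: 1.20, 300: 1.45}


@dataclass
class SynthConfig:
    """Parameters of the synthetic study system.

    ``n_sites_per_region`` / ``n_polygons_per_region`` accept an int or a
    per-region mapping.  Regional and vegetation statistics default to the
    compilation values in :data:`REGIONAL_STATS` / :data:`VEG_STATS`; SEs
    are SEs of the mean and are converted to site-level SDs internally
    using the stored observation counts.
    """

    seed: int = 0
    n_sites_per_region: int | Mapping[str, int] = 50
    n_polygons_per_region: int | Mapping[str, int] = 200
    n_gauges: int = 42
    regional_stats: dict = field(default_factory=lambda: {r: dict(v) for r, v in REGIONAL_STATS.items()})
    veg_stats: dict = field(default_factory=lambda: {v: dict(s) for v, s in VEG_STATS.items()})
    car_rslr_corr: float = 0.40
    calibrate_car: bool = True
    within_source_sd: float = 0.0  # per-source CAR intercept SD; the compilation's value is unknown
    rslr_site_jitter: float = 0.5
    polygon_area_lognorm_mu: float = -3.0
    polygon_area_lognorm_sigma: float = 1.0
    total_area_km2: float = 25892.0
    gauge_trend_jitter: float = 1.0
    gauge_noise_sd_mm: float = 20.0
    short_gauge_fraction: float = 0.25
    cluster_sd_deg: float = 0.22
    n_clusters_per_region: int = 3

    def __post_init__(self):
        for region, st in self.regional_stats.items():
            if st["car_se"] < 0 or st["sar_se"] < 0:
                raise ConfigurationError(f"{region}: SEs must be non-negative")
        for veg, st in self.veg_stats.items():
            if st["cdensity_se"] < 0:
                raise ConfigurationError(f"{veg}: SEs must be non-negative")
        for name in ("n_sites_per_region", "n_polygons_per_region"):
            val = getattr(self, name)
            counts = val.values() if isinstance(val, Mapping) else [val]
            if any(int(c) < 0 for c in counts) or (not isinstance(val, Mapping) and int(val) <= 0):
                raise ConfigurationError(f"{name} must be positive (or a per-region mapping of counts >= 0)")
        if self.n_gauges <= 0:
            raise ConfigurationError("n_gauges must be positive")
        if not 0 <= self.short_gauge_fraction <= 1:
            raise ConfigurationError("short_gauge_fraction must be in [0, 1]")
        shares = self.veg_area_share
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ConfigurationError("vegetation area shares must sum to 1")

    @property
    def veg_area_share(self) -> dict[str, float]:
        total = sum(st["area_km2"] for st in self.veg_stats.values())
        return {v: st["area_km2"] / total for v, st in self.veg_stats.items()}

    def _count(self, name: str, region: str) -> int:
        val = getattr(self, name)
        return int(val.get(region, 0)) if isinstance(val, Mapping) else int(val)


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), _SUBSTREAMS[stream]]))


@dataclass
class RegionLayout:
    """Cluster centers (and their states) inside one region's box."""

    region: str
    box: tuple[float, float, float, float]
    centers: np.ndarray  # (k, 2) lon, lat
    states: tuple[str, ...]


def make_layout(config: SynthConfig) -> dict[str, RegionLayout]:
    """Cluster centers per region, drawn from the layout substream.

    Sites, polygons, and gauges share this layout, so radius queries and
    nearest-gauge assignment behave like a real coastal network.
    """
    rng = _rng(config, "layout")
    layouts = {}
    for region in REGIONS:
        lon0, lon1, lat0, lat1 = REGION_BOXES[region]
        margin = 0.5
        k = config.n_clusters_per_region
        lon = rng.uniform(lon0 + margin, lon1 - margin, k)
        lat = rng.uniform(lat0 + margin, lat1 - margin, k)
        states = tuple(REGION_STATES[region][i % len(REGION_STATES[region])] for i in range(k))
        layouts[region] = RegionLayout(region, REGION_BOXES[region], np.column_stack([lon, lat]), states)
    return layouts


def _clip_into_box(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(values, lo + 1e-6, hi - 1e-6)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if np.all(sd == 0):
        return np.broadcast_to(np.asarray(mean, dtype=float), size if size else np.shape(mean)).copy()
    a = (lo - mean) / np.where(sd == 0, 1.0, sd)
    b = (hi - mean) / np.where(sd == 0, 1.0, sd)
    draw = sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.where(sd == 0, mean, draw)


def _source_labels(rng, n: int, region_idx: int) -> np.ndarray:
    """Partition a region's sites into literature-source groups of ~5-10."""
    labels = np.empty(n, dtype=object)
    pos, k = 0, 0
    while pos < n:
        size = int(rng.integers(5, 11))
        labels[pos : pos + size] = f"src_{region_idx}_{k}"
        pos += size
        k += 1
    return labels


def _calibrate_correlation(
    rng, car: np.ndarray, rslr: np.ndarray, rslr_centered: np.ndarray, region: np.ndarray, target: float
) -> np.ndarray:
    """Adjust CAR so its in-sample correlation with RSLR hits the target.

    If the structural correlation already exceeds the target, independent
    Gaussian noise (centered within each region) is added, solved for the
    SD; if it falls short, a within-region RSLR-aligned tilt ``c × (rslr −
    regional mean)`` is added.  Either adjustment is mean-zero per region,
    so the configured regional CAR means are untouched; both are solved on
    the realized sample by Brent's method, so the achieved correlation is
    exact up to solver tolerance.  Returns the adjusted CAR.
    """

    def corr(v):
        return float(np.corrcoef(v, rslr)[0, 1])

    r0 = corr(car)
    if abs(r0 - target) < 1e-12:
        return car
    if r0 > target:
        # noise proportional to the regional mean (constant CV), so low-CAR
        # regions are not pushed against the positivity floor
        means = {r: car[region == r].mean() for r in np.unique(region)}
        grand = float(np.mean(list(means.values())))
        w = np.array([means[r] / grand for r in region])
        z = rng.standard_normal(car.size) * w
        for r in np.unique(region):
            mask = region == r
            z[mask] -= z[mask].mean()
        scale = float(np.std(car))

        def f(sigma):
            return corr(car + sigma * z) - target

        hi = 10.0 * scale
        while f(hi) > 0 and hi < 1e4 * scale:
            hi *= 4.0
        sigma = optimize.brentq(f, 0.0, hi, xtol=1e-10)
        return car + sigma * z
    # tilt toward RSLR within regions
    def g(c):
        return corr(car + c * rslr_centered) - target

    hi = 1.0
    while g(hi) < 0 and hi < 1e6:
        hi *= 4.0
    c = optimize.brentq(g, 0.0, hi, xtol=1e-12)
    return car + c * rslr_centered


def generate_sites(config: SynthConfig) -> pd.DataFrame:
    """Generate the compiled site network.

    Per region: SAR around the regional mean, RSLR near the regional rate,
    C density per vegetation class, and CAR = c_density × SAR × 1000 plus a
    stored noise term (column ``car_noise_gC_m2_yr``) that centers each
    region on its configured mean CAR and calibrates the overall CAR–RSLR
    correlation.  The identity CAR = c_density×SAR×1000 + noise holds
    exactly for every record.
    """
    rng = _rng(config, "sites")
    layouts = make_layout(config)
    vegs = list(config.veg_stats.keys())
    shares = np.array([config.veg_area_share[v] for v in vegs])

    frames = []
    for region_idx, region in enumerate(REGIONS):
        if region not in config.regional_stats:
            continue
        n = config._count("n_sites_per_region", region)
        if n == 0:
            continue
        st = config.regional_stats[region]
        lay = layouts[region]
        lon0, lon1, lat0, lat1 = lay.box

        cluster = rng.integers(0, len(lay.centers), n)
        lon = _clip_into_box(lay.centers[cluster, 0] + rng.normal(0.0, config.cluster_sd_deg, n), lon0, lon1)
        lat = _clip_into_box(lay.centers[cluster, 1] + rng.normal(0.0, config.cluster_sd_deg, n), lat0, lat1)
        veg = rng.choice(vegs, size=n, p=shares)

        salinity = np.empty(n)
        for i, v in enumerate(veg):
            if v == "tidal_freshwater":
                salinity[i] = rng.uniform(0.0, 0.5)
            elif v == "brackish":
                salinity[i] = rng.uniform(0.5, 18.0)
            elif v == "salt_marsh":
                salinity[i] = rng.uniform(18.0, 35.0)
            else:  # mangrove spans brackish-to-marine water
                salinity[i] = rng.uniform(10.0, 36.0)
        marsh_zone = np.where(veg == "salt_marsh", rng.choice(["high", "low"], size=n), "NA")

        cd_mean = np.array([config.veg_stats[v]["cdensity_mean"] for v in veg])
        cd_sd = np.array([config.veg_stats[v]["cdensity_se"] * np.sqrt(config.veg_stats[v]["n_cd"]) for v in veg])
        cdensity = _truncnorm(rng, cd_mean, cd_sd, 0.005, 0.59, n)

        sar_sd = st["sar_se"] * np.sqrt(st["n_sar"])
        sar = _truncnorm(rng, np.full(n, st["sar_mean"]), np.full(n, sar_sd), 0.2, 30.0, n)

        rslr = st["rslr"] + (rng.normal(0.0, config.rslr_site_jitter, n) if config.rslr_site_jitter > 0 else 0.0)

        org_mean = np.array([config.veg_stats[v]["org_mean"] for v in veg])
        org_sd = np.array([config.veg_stats[v]["org_se"] * np.sqrt(config.veg_stats[v]["n_cd"]) for v in veg])
        min_mean = np.array([config.veg_stats[v]["min_mean"] for v in veg])
        min_sd = np.array([config.veg_stats[v]["min_se"] * np.sqrt(config.veg_stats[v]["n_cd"]) for v in veg])
        organic_sed = _truncnorm(rng, org_mean, org_sd, 0.0, 5000.0, n)
        mineral_sed = _truncnorm(rng, min_mean, min_sd, 0.0, 20000.0, n)

        tair = 27.0 - 0.5 * lat + rng.normal(0.0, 0.8, n)
        prcp = np.clip(1500.0 - 25.0 * (lat - 25.0) + rng.normal(0.0, 120.0, n), 300.0, None)

        source_id = _source_labels(rng, n, region_idx)
        dating = rng.choice(["Pb210", "Cs137", "SET"], size=n, p=[0.55, 0.38, 0.07])

        frames.append(
            pd.DataFrame(
                {
                    "site_id": [f"site_{region_idx}_{i}" for i in range(n)],
                    "source_id": source_id,
                    "lat": lat,
                    "lon": lon,
                    "region": region,
                    "state": [lay.states[c] for c in cluster],
                    "vegetation": veg,
                    "marsh_zone": marsh_zone,
                    "salinity_ppt": salinity,
                    "sar_mm_yr": sar,
                    "c_density_gC_cm3": cdensity,
                    "rslr_mm_yr": rslr,
                    "tair_c": tair,
                    "prcp_mm_yr": prcp,
                    "organic_sed_g_m2_yr": organic_sed,
                    "mineral_sed_g_m2_yr": mineral_sed,
                    "dating_method": dating,
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)

    base = sites["c_density_gC_cm3"].to_numpy() * sites["sar_mm_yr"].to_numpy() * 1000.0
    if not config.calibrate_car:
        sites["car_gC_m2_yr"] = base
        sites["car_noise_gC_m2_yr"] = 0.0
        return sites

    # center each region's CAR on its configured mean and rescale the
    # within-region dispersion to the compilation-implied site SD
    # (SE of the mean x sqrt(n)); the raw product c_density x SAR disperses
    # far more than the compiled CAR distribution does
    car = base.copy()
    region_arr = sites["region"].to_numpy()
    rslr_arr = sites["rslr_mm_yr"].to_numpy()
    rslr_centered = np.empty_like(rslr_arr)
    for region in np.unique(region_arr):
        mask = region_arr == region
        st = config.regional_stats[region]
        dev = car[mask] - car[mask].mean()
        sd_base = float(dev.std())
        sd_target = st["car_se"] * np.sqrt(st["n_car"])
        if sd_base > 0 and sd_target > 0:
            dev = dev * (sd_target / sd_base)
        elif sd_target == 0:
            dev = np.zeros_like(dev)
        car[mask] = st["car_mean"] + dev
        rslr_centered[mask] = rslr_arr[mask] - rslr_arr[mask].mean()

    if config.within_source_sd > 0:
        for src in pd.unique(sites["source_id"]):
            car[sites["source_id"].to_numpy() == src] += rng.normal(0.0, config.within_source_sd)

    car = _calibrate_correlation(rng, car, rslr_arr, rslr_centered, region_arr, config.car_rslr_corr)
    # positivity floor, re-centering each region on its configured mean;
    # the floored share is small once dispersion is rescaled, so this
    # converges in a few passes
    for _ in range(50):
        car = np.maximum(car, 1.0)
        worst = 0.0
        for region in np.unique(region_arr):
            mask = region_arr == region
            err = config.regional_stats[region]["car_mean"] - car[mask].mean()
            free = mask & (car > 1.0)
            if abs(err) > 1e-9 and free.sum() > 0:
                car[free] += err * mask.sum() / free.sum()
            worst = max(worst, abs(err))
        if worst <= 1e-9 and car.min() >= 1.0:
            break
    sites["car_gC_m2_yr"] = car
    sites["car_noise_gC_m2_yr"] = car - base
    achieved = float(np.corrcoef(car, rslr_arr)[0, 1])
    log.info("generated %d sites; realized CAR-RSLR correlation %.3f", len(sites), achieved)
    return sites


def generate_gauges(config: SynthConfig) -> list[TideGaugeSeries]:
    """Tide gauges with known linear trends plus i.i.d. Gaussian noise.

    Gauges are spread round-robin across regions with true slope = regional
    RSLR ± a uniform jitter; a ``short_gauge_fraction`` share keep only the
    most recent 30 annual values, the rest a full 60.  The ground-truth
    slope is stored on each series.
    """
    rng = _rng(config, "gauges")
    layouts = make_layout(config)
    gauges = []
    for g in range(config.n_gauges):
        region = REGIONS[g % len(REGIONS)]
        lay = layouts[region]
        lon0, lon1, lat0, lat1 = lay.box
        center = lay.centers[int(rng.integers(0, len(lay.centers)))]
        lon = float(_clip_into_box(center[0] + rng.normal(0.0, 0.3), lon0, lon1))
        lat = float(_clip_into_box(center[1] + rng.normal(0.0, 0.3), lat0, lat1))
        slope = config.regional_stats[region]["rslr"] + rng.uniform(-config.gauge_trend_jitter, config.gauge_trend_jitter)
        short = rng.random() < config.short_gauge_fraction
        years = np.arange(1984, 2014) if short else np.arange(1954, 2014)
        noise = rng.normal(0.0, config.gauge_noise_sd_mm, years.size) if config.gauge_noise_sd_mm > 0 else 0.0
        msl = 7000.0 + slope * (years - 1954) + noise
        gauges.append(
            TideGaugeSeries(
                gauge_id=f"g{g:03d}", lat=lat, lon=lon, years=years, msl_mm=msl, true_slope=float(slope)
            )
        )
    return gauges


def generate_inventory(config: SynthConfig) -> pd.DataFrame:
    """Wetland polygon inventory: clustered centroids, log-normal areas.

    Areas are drawn log-normal and rescaled so each region's total equals
    its configured share of ``total_area_km2`` (scaling preserves
    log-normality).  Vegetation follows the configured area shares; states
    follow the site clusters, so labels are consistent with coordinates.
    """
    rng = _rng(config, "inventory")
    layouts = make_layout(config)
    vegs = list(config.veg_stats.keys())
    shares = np.array([config.veg_area_share[v] for v in vegs])
    total_region_area = sum(st["area_km2"] for st in config.regional_stats.values())

    frames = []
    for region_idx, region in enumerate(REGIONS):
        if region not in config.regional_stats:
            continue
        n = config._count("n_polygons_per_region", region)
        if n == 0:
            continue
        st = config.regional_stats[region]
        lay = layouts[region]
        lon0, lon1, lat0, lat1 = lay.box
        cluster = rng.integers(0, len(lay.centers), n)
        lon = _clip_into_box(lay.centers[cluster, 0] + rng.normal(0.0, config.cluster_sd_deg, n), lon0, lon1)
        lat = _clip_into_box(lay.centers[cluster, 1] + rng.normal(0.0, config.cluster_sd_deg, n), lat0, lat1)
        areas = rng.lognormal(config.polygon_area_lognorm_mu, config.polygon_area_lognorm_sigma, n)
        target = config.total_area_km2 * st["area_km2"] / total_region_area
        areas *= target / areas.sum()
        veg = rng.choice(vegs, size=n, p=shares)
        frames.append(
            pd.DataFrame(
                {
                    "polygon_id": [f"poly_{region_idx}_{i}" for i in range(n)],
                    "lat": lat,
                    "lon": lon,
                    "area_km2": areas,
                    "vegetation": veg,
                    "region": region,
                    "state": [lay.states[c] for c in cluster],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["polygon_id", "lat", "lon", "area_km2", "vegetation", "region", "state"])
    return pd.concat(frames, ignore_index=True)


def generate_scenarios(config: SynthConfig, rcp: str, pop_threshold: int = 300) -> ScenarioSpec:
    """Decadal RSLR and area-fraction trajectories for one scenario.

    Segments are the seven regions, carrying their baseline CAR (mean and
    SE), RSLR, and area.  RSLR paths are monotone non-decreasing with the
    2100 increment scaled by scenario severity and a per-segment factor
    drawn independently of the scenario id, so severity ordering holds per
    segment for every seed.  Area fractions run linearly from exactly 1 at
    2020 to a threshold-dependent endpoint.
    """
    if rcp not in RCP_SCENARIOS:
        raise ConfigurationError(f"unknown scenario {rcp!r}; expected one of {RCP_SCENARIOS}")
    if pop_threshold not in POP_THRESHOLDS:
        raise ConfigurationError(f"pop_threshold must be one of {POP_THRESHOLDS}")
    rng = _rng(config, "scenarios")
    # drawn before rcp/threshold enter: identical across scenarios per seed
    rise_factor = rng.uniform(0.8, 1.2, len(REGIONS))
    area_jitter = rng.uniform(-0.05, 0.05, len(REGIONS))

    decades = np.array(DECADES)
    t = (decades - 2020) / 80.0
    seg_rows, path_rows = [], []
    for i, region in enumerate(REGIONS):
        if region not in config.regional_stats:
            continue
        st = config.regional_stats[region]
        seg_rows.append(
            {
                "segment_id": region,
                "car0_gC_m2_yr": st["car_mean"],
                "car0_se_gC_m2_yr": st["car_se"],
                "rslr0_mm_yr": st["rslr"],
                "area_km2": st["area_km2"],
            }
        )
        rslr_path = st["rslr"] + rise_factor[i] * RCP_RISE_2100[rcp] * t**1.2
        final_frac = AREA_FRACTION_2100[pop_threshold] + area_jitter[i]
        frac_path = 1.0 + (final_frac - 1.0) * t
        for d, r, f in zip(decades, rslr_path, frac_path):
            path_rows.append({"segment_id": region, "decade": int(d), "rslr_mm_yr": float(r), "area_fraction": float(f)})
    spec = ScenarioSpec(rcp=rcp, pop_threshold=pop_threshold, segments=pd.DataFrame(seg_rows), paths=pd.DataFrame(path_rows))
    spec.validate()
    return spec
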