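"""CSV schemas, pipeline configuration, and the end-to-end runner.

All tables are UTF-8 CSV with '.' decimals; coordinates are WGS84 decimal
degrees, areas km², fluxes Tg yr⁻¹, with units embedded in column names.
Readers validate mandatory columns (schema errors name the column),
coerce numeric types (row-level errors carry the line number), and
preserve unknown columns as passthrough so ``read(write(x)) == x``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from tidalcarbon import cores, rslr as rslr_mod, stats as stats_mod, upscale as upscale_mod
from tidalcarbon.errors import RowParseError, SchemaError, StageError, ValidationError
from tidalcarbon.project import ProjectionParams, ScenarioSpec, compare_scenarios, project_national
from tidalcarbon.rslr import TideGaugeSeries

log = logging.getLogger("tidalcarbon.io")

SITES_REQUIRED = (
    "site_id", "source_id", "lat", "lon", "region", "state", "vegetation",
    "salinity_ppt", "sar_mm_yr", "c_density_gC_cm3", "car_gC_m2_yr", "rslr_mm_yr",
)
SITES_NUMERIC = (
    "lat", "lon", "salinity_ppt", "sar_mm_yr", "c_density_gC_cm3",
    "car_gC_m2_yr", "rslr_mm_yr", "tair_c", "prcp_mm_yr",
    "organic_sed_g_m2_yr", "mineral_sed_g_m2_yr", "car_noise_gC_m2_yr",
)
GAUGES_REQUIRED = ("gauge_id", "lat", "lon", "year", "msl_mm")
INVENTORY_REQUIRED = ("polygon_id", "lat", "lon", "area_km2", "vegetation", "region", "state")
INVENTORY_NUMERIC = ("lat", "lon", "area_km2")
SCENARIOS_REQUIRED = (
    "rcp", "pop_threshold", "segment_id", "decade", "rslr_mm_yr", "area_fraction",
    "car0_gC_m2_yr", "car0_se_gC_m2_yr", "rslr0_mm_yr", "area_km2",
)


def _read_csv(path, required, numeric=()) -> pd.DataFrame:
    # only empty cells are missing: bare "NA" is a valid label (marsh_zone)
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column '{col}'")
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise RowParseError(
                f"{path}: unparseable value {df.loc[bad.idxmax(), col]!r} in column '{col}' at line {line}",
                line=line,
            )
        df[col] = coerced
    return df


def read_sites(path) -> pd.DataFrame:
    return _read_csv(path, SITES_REQUIRED, SITES_NUMERIC)


def write_sites(path, sites: pd.DataFrame) -> None:
    sites.to_csv(path, index=False)


def read_gauges(path) -> list[TideGaugeSeries]:
    """Read the long-format gauge table into per-gauge series."""
    df = _read_csv(path, GAUGES_REQUIRED, ("lat", "lon", "year", "msl_mm"))
    out = []
    for gid, sub in df.groupby("gauge_id", sort=True):
        sub = sub.sort_values("year")
        out.append(
            TideGaugeSeries(
                gauge_id=str(gid),
                lat=float(sub["lat"].iloc[0]),
                lon=float(sub["lon"].iloc[0]),
                years=sub["year"].to_numpy(dtype=int),
                msl_mm=sub["msl_mm"].to_numpy(dtype=float),
            )
        )
    return out


def write_gauges(path, gauges: list[TideGaugeSeries]) -> None:
    frames = [
        pd.DataFrame(
            {"gauge_id": g.gauge_id, "lat": g.lat, "lon": g.lon, "year": g.years, "msl_mm": g.msl_mm}
        )
        for g in gauges
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_inventory(path) -> pd.DataFrame:
    return _read_csv(path, INVENTORY_REQUIRED, INVENTORY_NUMERIC)


def write_inventory(path, polygons: pd.DataFrame) -> None:
    polygons.to_csv(path, index=False)


def read_scenarios(path) -> list[ScenarioSpec]:
    """Read the long scenario table, one ScenarioSpec per (rcp, threshold)."""
    df = _read_csv(
        path,
        SCENARIOS_REQUIRED,
        ("pop_threshold", "decade", "rslr_mm_yr", "area_fraction",
         "car0_gC_m2_yr", "car0_se_gC_m2_yr", "rslr0_mm_yr", "area_km2"),
    )
    specs = []
    for (rcp, thr), sub in df.groupby(["rcp", "pop_threshold"], sort=True):
        segments = (
            sub.groupby("segment_id", sort=True)
            .first()
            .reset_index()[["segment_id", "car0_gC_m2_yr", "car0_se_gC_m2_yr", "rslr0_mm_yr", "area_km2"]]
        )
        paths = sub[["segment_id", "decade", "rslr_mm_yr", "area_fraction"]].copy()
        paths["decade"] = paths["decade"].astype(int)
        spec = ScenarioSpec(rcp=str(rcp), pop_threshold=int(thr), segments=segments, paths=paths)
        spec.validate()
        specs.append(spec)
    return specs


def write_scenarios(path, specs: list[ScenarioSpec]) -> None:
    frames = []
    for spec in specs:
        merged = spec.paths.merge(spec.segments, on="segment_id")
        merged.insert(0, "rcp", spec.rcp)
        merged.insert(1, "pop_threshold", spec.pop_threshold)
        frames.append(merged)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_estimates(path, estimates: pd.DataFrame) -> None:
    estimates.to_csv(path, index=False)


def write_summaries(path, summaries: pd.DataFrame) -> None:
    summaries.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Paths and parameters of a full pipeline run."""

    sites: str = "sites.csv"
    gauges: str = "gauges.csv"
    inventory: str = "inventory.csv"
    scenarios: str = "scenarios.csv"
    out_dir: str = "out"
    radius_km: float = 100.0
    z: float = 1.96
    critical_rslr: float = 10.0
    fit_mode: str = "cluster_robust"
    n_draws: int = 10_000
    seed: int = 0
    report_decimals: int = 2
    conversion: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.radius_km <= 0:
            raise ValidationError("radius_km must be positive")
        if self.critical_rslr <= 0:
            raise ValidationError("critical_rslr must be positive")
        if self.fit_mode not in stats_mod.FIT_MODES:
            raise ValidationError(f"fit_mode must be one of {stats_mod.FIT_MODES}")
        for name in ("sites", "gauges", "inventory", "scenarios"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"input file for '{name}' not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    version: str
    config_hash: str
    seed: int
    started: str
    finished: str = ""
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int, n_excluded: int = 0, **extra) -> None:
        if n_in != n_out + n_excluded:
            raise StageError(f"stage {stage}: counts do not reconcile ({n_in} != {n_out} + {n_excluded})")
        self.stages[stage] = {"n_in": n_in, "n_out": n_out, "n_excluded": n_excluded, **extra}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute derive → rslr → upscale → stats → project on the configured files.

    Every stage's outputs are written under ``config.out_dir``; a failed
    stage aborts with a stage-named :class:`StageError`.  Returns the
    manifest (also written as ``manifest.json``).
    """
    from tidalcarbon import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrap

    # derive: dating-method filter on the compiled sites
    def _derive():
        sites_in = read_sites(config.sites)
        kept, excluded = cores.filter_dating(sites_in)
        manifest.record("derive", len(sites_in), len(kept), len(excluded))
        return kept
    sites = stage("derive")(_derive)

    # rslr: gauge trends and nearest-gauge assignment
    def _rslr():
        gauges = read_gauges(config.gauges)
        trends = rslr_mod.estimate_trends(gauges)
        trends.to_csv(out / "trends.csv", index=False)
        assigned = rslr_mod.assign_rslr_sites(sites, trends)
        write_sites(out / "sites_derived.csv", assigned)
        manifest.record("rslr", len(gauges), len(trends), len(gauges) - len(trends), n_bridged=int(trends["bridged"].sum()))
        return assigned
    sites = stage("rslr")(_rslr)

    # upscale: per-polygon estimates and level summaries
    def _upscale():
        polygons = read_inventory(config.inventory)
        estimates = upscale_mod.upscale_inventory(polygons, sites, radius_km=config.radius_km)
        write_estimates(out / "estimates.csv", estimates)
        summaries = pd.concat(
            [upscale_mod.aggregate(estimates, by=by, z=config.z) for by in (None, "region", "state", "vegetation")],
            ignore_index=True,
        )
        write_summaries(out / "summaries.csv", summaries)
        manifest.record("upscale", len(polygons), len(estimates))
        return estimates
    stage("upscale")(_upscale)

    # stats: group comparisons, correlations, and the CAR~RSLR model
    def _stats():
        reports = []
        for by in ("vegetation", "region"):
            rep = stats_mod.group_comparison_report(sites, "car_gC_m2_yr", by)
            pairs = rep["pairs"].copy()
            pairs.insert(0, "grouping", by)
            pairs.insert(1, "F", rep["anova"].F)
            pairs.insert(2, "anova_p", rep["anova"].p)
            pairs["letters_a"] = pairs["group_a"].map(rep["letters"])
            pairs["letters_b"] = pairs["group_b"].map(rep["letters"])
            reports.append(pairs)
        pd.concat(reports, ignore_index=True).to_csv(out / "stats_groups.csv", index=False)
        stats_mod.correlation_table(sites).to_csv(out / "stats_correlations.csv", index=False)
        model = stats_mod.fit_car_rslr(sites, fit_mode=config.fit_mode)
        with open(out / "model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
        manifest.record("stats", len(sites), len(sites), model_slope=model.slope, model_slope_se=model.slope_se)
        return model
    model = stage("stats")(_stats)

    # project: scenario paths to 2100
    def _project():
        specs = read_scenarios(config.scenarios)
        params = ProjectionParams(critical_rslr=config.critical_rslr, n_draws=config.n_draws, seed=config.seed)
        results = {f"{s.rcp}/thr{s.pop_threshold}": project_national(s, model, params) for s in specs}
        comparison = compare_scenarios(results)
        comparison.to_csv(out / "projection.csv", index=False)
        manifest.record("project", len(specs), len(specs), n_draws=config.n_draws)
    stage("project")(_project)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    log.info("pipeline complete; outputs in %s", out)
    return manifest
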