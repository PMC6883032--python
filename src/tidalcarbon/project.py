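"""Project national tidal-wetland C sequestration to 2100.

Future CAR per coastal segment follows the fitted CAR ~ RSLR slope applied
to the difference between the future and current decadal RSLR, capped at a
critical RSLR (default 10 mm yr⁻¹, alternate 12): marshes accrete faster —
and bury more carbon — as relative sea level rises, until accretion can no
longer keep pace, beyond which CAR stops increasing.  Segment fluxes
combine projected CAR with baseline area times a decadal area-fraction
trajectory (wetland loss or landward migration under a population-density
accommodation-space constraint).  Uncertainty bands come from Monte-Carlo
draws of baseline CAR and of the regression slope; the decadal RSLR paths
themselves are treated as fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from tidalcarbon.errors import ValidationError
from tidalcarbon.stats import CarRslrModel

log = logging.getLogger("tidalcarbon.project")

DECADES = tuple(range(2020, 2101, 10))
RCP_SCENARIOS = ("RCP2.6", "RCP4.5", "RCP8.5")
POP_THRESHOLDS = (5, 20, 150, 300)


@dataclass(frozen=True)
class ProjectionParams:
    """Knobs of the projection: cap, draw count, seed.

    ``critical_rslr`` is the accretion-limit rate in mm yr⁻¹ (10 for
    typical US/European marshes; 12 reported for southeast US marshes).
    """

    critical_rslr: float = 10.0
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.critical_rslr <= 0:
            raise ValidationError("critical_rslr must be positive")
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")


@dataclass
class ScenarioSpec:
    """One scenario: per-segment baselines plus decadal RSLR / area paths.

    ``segments`` columns: segment_id, car0_gC_m2_yr, car0_se_gC_m2_yr,
    rslr0_mm_yr, area_km2.  ``paths`` columns: segment_id, decade,
    rslr_mm_yr, area_fraction — covering 2020…2100 at 10-yr steps.
    """

    rcp: str
    pop_threshold: int
    segments: pd.DataFrame
    paths: pd.DataFrame

    def validate(self) -> None:
        if self.rcp not in RCP_SCENARIOS:
            raise ValidationError(f"unknown scenario {self.rcp!r}")
        if self.pop_threshold not in POP_THRESHOLDS:
            raise ValidationError(f"pop_threshold must be one of {POP_THRESHOLDS}")
        if np.any(self.paths["area_fraction"].to_numpy() <= 0):
            raise ValidationError("area fractions must be positive")
        for seg, sub in self.paths.groupby("segment_id"):
            missing = set(DECADES) - set(sub["decade"])
            if missing:
                raise ValidationError(f"segment {seg}: missing decades {sorted(missing)}")


def project_car(car0, rslr0, rslr_t, model: CarRslrModel | float, critical_rslr: float = 10.0):
    """Projected CAR (g C m⁻² yr⁻¹) under a future RSLR, with the cap.

    ``CAR_t = max(0, car0 + slope × (min(rslr_t, critical) − min(rslr0,
    critical)))``.  The cap applies to both current and future rates, so a
    segment already beyond the critical rate gains no further CAR.
    Accepts scalars or broadcastable arrays.
    """
    slope = model.slope if isinstance(model, CarRslrModel) else float(model)
    car0 = np.asarray(car0, dtype=float)
    eff_now = np.minimum(np.asarray(rslr0, dtype=float), critical_rslr)
    eff_fut = np.minimum(np.asarray(rslr_t, dtype=float), critical_rslr)
    out = np.maximum(0.0, car0 + slope * (eff_fut - eff_now))
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class ProjectionResult:
    """Decadal national flux path with a 95% Monte-Carlo band."""

    table: pd.DataFrame  # decade, flux_mean_Tg_yr, flux_lo_Tg_yr, flux_hi_Tg_yr
    segment_car: pd.DataFrame  # segment_id, decade, car_gC_m2_yr (deterministic)
    provenance: dict = field(default_factory=dict)


def project_national(spec: ScenarioSpec, model: CarRslrModel, params: ProjectionParams = ProjectionParams()) -> ProjectionResult:
    """National decadal C-flux path for one scenario.

    Per decade and segment, ``flux = CAR_t × baseline_area ×
    area_fraction(t) × 1e-6`` (Tg yr⁻¹), summed nationally.  The band is
    the 2.5th–97.5th percentile of ``n_draws`` replicates drawing baseline
    CAR ~ Normal(car0, se²) per segment and slope ~ Normal(slope, se²),
    with projected CAR floored at zero.  The central path uses the point
    estimates.
    """
    spec.validate()
    seg = spec.segments.set_index("segment_id")
    order = seg.index.to_numpy()
    decades = np.array(DECADES)

    rslr = spec.paths.pivot(index="segment_id", columns="decade", values="rslr_mm_yr").loc[order, decades].to_numpy()
    frac = spec.paths.pivot(index="segment_id", columns="decade", values="area_fraction").loc[order, decades].to_numpy()
    car0 = seg["car0_gC_m2_yr"].to_numpy(dtype=float)
    car0_se = seg["car0_se_gC_m2_yr"].to_numpy(dtype=float)
    rslr0 = seg["rslr0_mm_yr"].to_numpy(dtype=float)
    area = seg["area_km2"].to_numpy(dtype=float)

    # deterministic central path
    car_det = project_car(car0[:, None], rslr0[:, None], rslr, model.slope, params.critical_rslr)
    flux_det = car_det * (area[:, None] * frac) * 1e-6
    national_det = flux_det.sum(axis=0)

    rng = np.random.default_rng(params.seed)
    n = params.n_draws
    car0_draw = car0[None, :] + car0_se[None, :] * rng.standard_normal((n, len(order)))
    slope_draw = model.slope + model.slope_se * rng.standard_normal(n)
    # [draw, segment, decade]
    delta = np.minimum(rslr, params.critical_rslr)[None, :, :] - np.minimum(rslr0, params.critical_rslr)[None, :, None]
    car_mc = np.maximum(0.0, car0_draw[:, :, None] + slope_draw[:, None, None] * delta)
    national_mc = (car_mc * (area[:, None] * frac)[None, :, :] * 1e-6).sum(axis=1)
    lo, hi = np.percentile(national_mc, [2.5, 97.5], axis=0)

    table = pd.DataFrame(
        {
            "decade": decades,
            "flux_mean_Tg_yr": national_det,
            "flux_lo_Tg_yr": lo,
            "flux_hi_Tg_yr": hi,
        }
    )
    segment_car = pd.DataFrame(
        {
            "segment_id": np.repeat(order, len(decades)),
            "decade": np.tile(decades, len(order)),
            "car_gC_m2_yr": car_det.ravel(),
        }
    )
    provenance = {
        "rcp": spec.rcp,
        "pop_threshold": spec.pop_threshold,
        "critical_rslr": params.critical_rslr,
        "n_draws": n,
        "seed": params.seed,
        "slope": model.slope,
        "slope_se": model.slope_se,
        "fit_mode": model.fit_mode,
    }
    return ProjectionResult(table=table, segment_car=segment_car, provenance=provenance)


def compare_scenarios(results: Mapping[str, ProjectionResult]) -> pd.DataFrame:
    """Long-format comparison across scenarios with a ratio-to-baseline column.

    One row per (scenario, decade) with the mean path and band, plus the
    ratio of each decade's mean flux to the scenario's 2020 value.
    """
    if len(results) == 0:
        raise ValidationError("compare_scenarios needs at least one result")
    grids = {name: tuple(res.table["decade"]) for name, res in results.items()}
    if len(set(grids.values())) > 1:
        raise ValidationError(f"inconsistent decade grids across scenarios: {grids}")
    rows = []
    for name, res in results.items():
        base = float(res.table.loc[res.table["decade"] == res.table["decade"].min(), "flux_mean_Tg_yr"].iloc[0])
        for _, r in res.table.iterrows():
            rows.append(
                {
                    "scenario": name,
                    "rcp": res.provenance.get("rcp"),
                    "pop_threshold": res.provenance.get("pop_threshold"),
                    "decade": int(r["decade"]),
                    "flux_mean_Tg_yr": r["flux_mean_Tg_yr"],
                    "flux_lo_Tg_yr": r["flux_lo_Tg_yr"],
                    "flux_hi_Tg_yr": r["flux_hi_Tg_yr"],
                    "ratio_to_baseline": r["flux_mean_Tg_yr"] / base if base != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
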