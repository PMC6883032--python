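"""Group comparisons and association analyses for the site compilation.

One-way ANOVA with Tukey HSD letters compares CAR / SAR / C density across
vegetation classes, watershed regions, and states; Pearson and first-order
partial correlations describe the associations among CAR, SAR, C density,
RSLR, salinity and climate; and the final predictive model — CAR regressed
on RSLR alone — is fitted with source-clustered (default), plain OLS, or
random-intercept standard errors, reflecting that sites from one literature
source are not independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from tidalcarbon.errors import ValidationError

log = logging.getLogger("tidalcarbon.stats")

FIT_MODES = ("ols", "cluster_robust", "random_intercept")


def _check_groups(groups: Mapping[str, Sequence[float]], min_groups: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < min_groups:
        raise ValidationError(f"need at least {min_groups} groups, got {len(groups)}")
    clean = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2 or not np.all(np.isfinite(arr)):
            raise ValidationError(f"group {label!r} needs >= 2 finite values")
        clean[label] = arr
    return clean


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (between/within decomposition)."""
    clean = _check_groups(groups)
    arrays = list(clean.values())
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        raise ValidationError("all values identical: the F statistic is undefined (0/0)")
    F, p = sps.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = pooled.size - len(arrays)
    return AnovaResult(float(F), df1, df2, float(p))


def compact_letters(labels: Sequence[str], significant_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Two groups share a letter iff the pair is not in ``significant_pairs``.
    """
    columns: list[set] = [set(labels)]
    for pair in significant_pairs:
        a, b = tuple(pair)
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.extend([col - {a}, col - {b}])
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [c for c in new_columns if c and not any(c < other for other in new_columns if other is not c)]
        deduped = []
        for c in columns:
            if c not in deduped:
                deduped.append(c)
        columns = deduped
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {lab: "".join(alphabet[i] for i, col in enumerate(columns) if lab in col) for lab in labels}


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tukey HSD pairwise comparisons plus a compact letter display.

    Uses the studentized-range distribution with the Tukey–Kramer harmonic
    adjustment for unequal group sizes.  Returns a pairwise table
    (group_a, group_b, mean_diff, p_adj, significant) and a letters dict
    in which two groups share a letter iff they are not significantly
    different at ``alpha``.
    """
    clean = _check_groups(groups)
    labels = list(clean.keys())
    res = sps.tukey_hsd(*clean.values())
    rows = []
    sig_pairs: set[frozenset] = set()
    for i, j in combinations(range(len(labels)), 2):
        p = float(res.pvalue[i, j])
        sig = p < alpha
        if sig:
            sig_pairs.add(frozenset({labels[i], labels[j]}))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(clean[labels[i]].mean() - clean[labels[j]].mean()),
                "p_adj": p,
                "significant": sig,
            }
        )
    return pd.DataFrame(rows), compact_letters(labels, sig_pairs)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("pearson_r needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in an input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def partial_r(x: Sequence[float], y: Sequence[float], control: Sequence[float]) -> tuple[float, float]:
    """First-order partial correlation of x and y given one control.

    ``r_xy·z = (r_xy − r_xz·r_yz) / sqrt((1−r_xz²)(1−r_yz²))`` with a
    t-transform p-value on n − 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    if x.size < 4:
        raise ValidationError("partial_r needs n >= 4")
    for name, arr in (("x", x), ("y", y), ("control", z)):
        if np.std(arr) == 0:
            raise ValidationError(f"zero variance in {name}")
    r_xy = sps.pearsonr(x, y)[0]
    r_xz = sps.pearsonr(x, z)[0]
    r_yz = sps.pearsonr(y, z)[0]
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        raise ValidationError("control is collinear with x or y")
    r = (r_xy - r_xz * r_yz) / denom
    df = x.size - 3
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


@dataclass
class CarRslrModel:
    """The fitted CAR ~ RSLR relation used for projection."""

    slope: float  # g C m-2 yr-1 per mm yr-1
    intercept: float  # g C m-2 yr-1
    slope_se: float
    intercept_se: float
    fit_mode: str
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "fit_mode": self.fit_mode,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CarRslrModel":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            slope_se=float(d["slope_se"]),
            intercept_se=float(d["intercept_se"]),
            fit_mode=str(d["fit_mode"]),
            n=int(d["n"]),
        )


def fit_car_rslr(records: pd.DataFrame, fit_mode: str = "cluster_robust") -> CarRslrModel:
    """Fit CAR on RSLR with the chosen error structure.

    ``ols`` is plain least squares; ``cluster_robust`` keeps the OLS
    coefficients but clusters standard errors on ``source_id`` (sites from
    one literature source share methodology and location); and
    ``random_intercept`` fits a per-source random-intercept mixed model by
    REML.
    """
    if fit_mode not in FIT_MODES:
        raise ValidationError(f"fit_mode must be one of {FIT_MODES}")
    data = records.dropna(subset=["car_gC_m2_yr", "rslr_mm_yr"])
    if len(data) < 3:
        raise ValidationError("need >= 3 records with CAR and RSLR")
    car = data["car_gC_m2_yr"].to_numpy(dtype=float)
    rslr = data["rslr_mm_yr"].to_numpy(dtype=float)
    if np.allclose(rslr, rslr[0]):
        raise ValidationError("all RSLR values identical: slope is unidentifiable")
    X = sm.add_constant(rslr)
    if fit_mode in ("cluster_robust", "random_intercept") and "source_id" not in data.columns:
        raise ValidationError(f"fit_mode {fit_mode!r} requires a source_id column")

    if fit_mode == "ols":
        res = sm.OLS(car, X).fit()
        params, bse = res.params, res.bse
    elif fit_mode == "cluster_robust":
        groups = pd.Categorical(data["source_id"]).codes
        res = sm.OLS(car, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
        params, bse = res.params, res.bse
    else:  # random_intercept
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary variance warnings on clean data
            res = sm.MixedLM(car, X, groups=data["source_id"].to_numpy()).fit(reml=True)
        params, bse = res.fe_params, res.bse_fe
    return CarRslrModel(
        slope=float(params[1]),
        intercept=float(params[0]),
        slope_se=float(bse[1]),
        intercept_se=float(bse[0]),
        fit_mode=fit_mode,
        n=len(data),
    )


# ---------------------------------------------------------------------------
# reporting helpers

_CORR_VARS = {
    "SAR": "sar_mm_yr",
    "C density": "c_density_gC_cm3",
    "RSLR": "rslr_mm_yr",
    "Salinity": "salinity_ppt",
    "Tair": "tair_c",
    "Prcp": "prcp_mm_yr",
    "Latitude": "lat",
    "Longitude": "lon",
}


def correlation_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Correlations of CAR (and SAR, C density) with site covariates.

    Mirrors the conventional compilation layout: the CAR–SAR and CAR–C
    density entries are first-order partial correlations controlling for
    the respective other driver (SAR and C density jointly set CAR, so the
    raw pairwise r double-counts their shared variance); all other entries
    are plain Pearson correlations.  No multiplicity correction is applied.
    """
    rows = []
    for row_var, row_col in (("CAR", "car_gC_m2_yr"), ("SAR", "sar_mm_yr"), ("C density", "c_density_gC_cm3")):
        for col_name, col in _CORR_VARS.items():
            if col == row_col or col not in sites.columns:
                continue
            sub = sites.dropna(subset=[row_col, col])
            if row_var == "CAR" and col_name in ("SAR", "C density"):
                other = "c_density_gC_cm3" if col_name == "SAR" else "sar_mm_yr"
                sub = sub.dropna(subset=[other])
                r, p = partial_r(sub[row_col], sub[col], sub[other])
                kind = "partial"
            else:
                r, p = pearson_r(sub[row_col], sub[col])
                kind = "pearson"
            rows.append({"variable": row_var, "covariate": col_name, "r": r, "p": p, "kind": kind, "n": len(sub)})
    return pd.DataFrame(rows)


def group_comparison_report(sites: pd.DataFrame, value_col: str, by: str) -> dict:
    """ANOVA + Tukey letters of one variable over one grouping factor."""
    groups = {
        str(label): sub[value_col].dropna().to_numpy()
        for label, sub in sites.groupby(by)
        if sub[value_col].notna().sum() >= 2
    }
    anova = oneway_anova(groups)
    pairs, letters = tukey_hsd(groups)
    return {"anova": anova, "pairs": pairs, "letters": letters}
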