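"""PDX tumor growth-velocity analysis (rate-based T/C framework).

Caliper measurements (long diameter a, short diameter b) give volumes
``V = 0.5 a b^2``.  Volumes are log10-transformed with an absolute floor
(default 50 mm^3) to avoid small-volume skew, and each animal's growth
velocity is the ordinary-least-squares slope of floored log10 volume
against day, in log10(mm^3)/day.  Treatment arms are compared with a
two-sample Student t-test on the per-animal slopes, and the treated arm
is classified as regression / stasis / growth from its mean slope
against a stasis tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_FLOOR_MM3",
    "DEFAULT_STASIS_TOL",
    "GrowthVelocity",
    "ArmComparison",
    "caliper_volume",
    "floored_log_volume",
    "fit_growth_velocity",
    "fit_cohort_velocities",
    "two_sample_t",
    "compare_arms",
    "normalize_cohort_curves",
    "subtype_arm_anova",
]

DEFAULT_FLOOR_MM3 = 50.0
DEFAULT_STASIS_TOL = 0.005  # log10(mm^3)/day, ~12% volume change per week


@dataclass(frozen=True)
class GrowthVelocity:
    animal: str
    slope: float  # log10(mm^3)/day
    intercept: float  # log10(mm^3)
    n_points: int
    r_squared: float


@dataclass(frozen=True)
class ArmComparison:
    model: str
    drug: str
    mean_slope_vehicle: float
    mean_slope_treated: float
    t_statistic: float
    p_value: float
    response_class: str  # regression | stasis | growth


def caliper_volume(a, b):
    """Tumor volume 0.5*a*b^2 (mm^3) from long/short caliper diameters.

    If b > a the diameters were mis-entered; they are swapped with a
    warning so the convention a >= b always holds.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("diameters must be positive")
    swapped = b > a
    if np.any(swapped):
        warnings.warn(
            f"{int(np.sum(swapped))} measurement(s) with b > a; swapped to "
            "enforce a >= b"
        )
        a, b = np.where(swapped, b, a), np.where(swapped, a, b)
    v = 0.5 * a * b**2
    return float(v) if v.ndim == 0 else v


def floored_log_volume(v, floor: float = DEFAULT_FLOOR_MM3):
    """log10 volume with an absolute minimum tumor size applied first."""
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("volumes must be >= 0")
    out = np.log10(np.maximum(v, floor))
    return float(out) if out.ndim == 0 else out


def fit_growth_velocity(
    days, volumes, animal: str = "", floor: float = DEFAULT_FLOOR_MM3
) -> GrowthVelocity:
    """OLS slope of floored log10 volume vs day for one animal."""
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if days.size != volumes.size:
        raise ValueError("days and volumes differ in length")
    if np.unique(days).size < 2:
        raise ValueError("need >= 2 distinct measurement days")
    y = floored_log_volume(volumes, floor=floor)
    res = stats.linregress(days, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return GrowthVelocity(
        animal=animal,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=int(days.size),
        r_squared=r2,
    )


def fit_cohort_velocities(
    measurements: pd.DataFrame, floor: float = DEFAULT_FLOOR_MM3
) -> pd.DataFrame:
    """Per-animal growth velocities from a caliper log.

    ``measurements`` has columns ``model, animal, arm, day, a_mm, b_mm``.
    Returns one row per animal with
    ``model, animal, arm, slope, intercept, n_points, r_squared``.
    """
    rows = []
    for (model, animal, arm), g in measurements.groupby(
        ["model", "animal", "arm"], sort=True
    ):
        v = caliper_volume(g["a_mm"], g["b_mm"])
        gv = fit_growth_velocity(g["day"], v, animal=animal, floor=floor)
        rows.append(
            (model, animal, arm, gv.slope, gv.intercept, gv.n_points, gv.r_squared)
        )
    return pd.DataFrame(
        rows,
        columns=["model", "animal", "arm", "slope", "intercept", "n_points",
                 "r_squared"],
    )


def two_sample_t(x, y, equal_var: bool = True):
    """Two-sided two-sample t-test, degenerate-variance safe.

    With zero pooled variance: equal means give (t=0, p=1), unequal
    means give (t=+/-inf, p=0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def compare_arms(
    vehicle_slopes,
    treated_slopes,
    model: str = "",
    drug: str = "",
    stasis_tol: float = DEFAULT_STASIS_TOL,
    equal_var: bool = True,
) -> ArmComparison:
    """Rate-based T/C comparison of vehicle vs treated growth velocities.

    Pooled-variance Student t-test by default (Welch via
    ``equal_var=False``).  The response class is read off the mean
    treated slope: regression below ``-stasis_tol``, growth above
    ``+stasis_tol``, stasis between.
    """
    v = np.asarray(vehicle_slopes, dtype=float)
    t_arr = np.asarray(treated_slopes, dtype=float)
    t_stat, p = two_sample_t(v, t_arr, equal_var=equal_var)
    mean_treated = float(np.mean(t_arr))
    if mean_treated < -stasis_tol:
        cls = "regression"
    elif mean_treated > stasis_tol:
        cls = "growth"
    else:
        cls = "stasis"
    return ArmComparison(
        model=model,
        drug=drug,
        mean_slope_vehicle=float(np.mean(v)),
        mean_slope_treated=mean_treated,
        t_statistic=t_stat,
        p_value=p,
        response_class=cls,
    )


def normalize_cohort_curves(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM day-0-normalized volume per arm per day.

    Each animal's volumes are divided by its own day-0 volume; animals
    without a day-0 measurement are excluded with a warning.  Returns a
    table with ``arm, day, mean_norm_volume, sem_norm_volume, n``.
    """
    per_animal = []
    for (animal, arm), g in measurements.groupby(["animal", "arm"]):
        g = g.sort_values("day")
        v = caliper_volume(g["a_mm"], g["b_mm"])
        day = g["day"].to_numpy(dtype=float)
        if 0.0 not in day:
            warnings.warn(f"animal {animal!r} lacks a day-0 measurement; excluded")
            continue
        v0 = v[day == 0.0][0]
        per_animal.append(
            pd.DataFrame({"animal": animal, "arm": arm, "day": day, "norm": v / v0})
        )
    if not per_animal:
        raise ValueError("no animal has a day-0 measurement")
    long = pd.concat(per_animal, ignore_index=True)
    out = (
        long.groupby(["arm", "day"])["norm"]
        .agg(mean_norm_volume="mean", sem_norm_volume="sem", n="size")
        .reset_index()
    )
    out["sem_norm_volume"] = out["sem_norm_volume"].fillna(0.0)
    return out


def subtype_arm_anova(velocities: pd.DataFrame) -> pd.DataFrame:
    """Two-factor fixed-effects ANOVA of slope ~ subtype * arm.

    ``velocities`` needs columns ``slope, subtype, arm`` (e.g. AM/CM x
    vehicle/drug).  Returns the statsmodels ANOVA table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("slope ~ C(subtype) * C(arm)", data=velocities).fit()
    return sm.stats.anova_lm(model, typ=2)
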