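"""Sequential-harvest growth analysis: RGR, NAR, allocation components, Δ.

Growth rates are cross-sectional: different individuals are destructively
harvested at successive ages, and the relative growth rate (RGR, day⁻¹) is
the ordinary least-squares slope of ln(total dry mass) on age. Net
assimilation rate is defined operationally as the slope of ln(mass per leaf
area) on age, and the leaf-area expansion rate as the slope of ln(leaf area)
on age; by linearity of least squares the three slopes satisfy
RGR = NAR_slope + leaf_area_rgr exactly on a shared set of plants.

Allocation components per harvested plant:

* SLA  = leaf area / leaf dry mass              (cm²·g⁻¹)
* LAR  = leaf area / total dry mass             (cm²·g⁻¹)
* LMR  = leaf dry mass / total dry mass         (–)
* RMR  = root dry mass / total dry mass         (–)
* root:shoot = root dry mass / shoot dry mass   (–)

so that LAR = SLA × LMR identically. Carbon isotope discrimination
Δ = (δ13C_air − δ13C_plant)/(1 + δ13C_plant/1000), per mil, is a proxy for
time-integrated water-use efficiency; air defaults to −8.0‰.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linear_models import ModelSpec, fit_ancova, fit_anova

__all__ = [
    "GrowthRates",
    "compute_components",
    "fit_growth_rates",
    "relative_change_lar",
    "delta_from_d13c",
    "d13c_from_delta",
    "rgr_ancova",
    "nar_ancova",
    "midseason_anova",
    "leafchem_anova",
    "DELTA_AIR_DEFAULT",
    "MIDSEASON_AGE",
    "EARLY_AGE",
]

DELTA_AIR_DEFAULT = -8.0  # per mil, standard tropospheric δ13C
#: Mid-season anchor ages (days after germination) for allocation contrasts.
EARLY_AGE = 53
MIDSEASON_AGE = 95

COMPONENT_NAMES = ("sla", "lar", "lmr", "rmr", "root_shoot")


@dataclass
class GrowthRates:
    """Fitted log-linear growth slopes (day⁻¹) with standard errors for one group."""

    group: tuple
    rgr: float
    rgr_se: float
    nar_slope: float
    nar_se: float
    leaf_area_rgr: float
    leaf_area_rgr_se: float
    n: int


def compute_components(records: pd.DataFrame) -> pd.DataFrame:
    """Per-record allocation components appended as new columns.

    Requires columns ``total_mass, leaf_mass, root_mass, shoot_mass,
    leaf_area``. Records with a non-positive denominator are flagged in a
    boolean ``component_flag`` column (their components are NaN), never
    silently dropped.
    """
    req = {"total_mass", "leaf_mass", "root_mass", "shoot_mass", "leaf_area"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = records.copy()
    total = out["total_mass"].to_numpy(float)
    leaf = out["leaf_mass"].to_numpy(float)
    root = out["root_mass"].to_numpy(float)
    shoot = out["shoot_mass"].to_numpy(float)
    area = out["leaf_area"].to_numpy(float)

    bad = (total <= 0) | (leaf <= 0) | (shoot <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["sla"] = np.where(leaf > 0, area / leaf, np.nan)
        out["lar"] = np.where(total > 0, area / total, np.nan)
        out["lmr"] = np.where(total > 0, leaf / total, np.nan)
        out["rmr"] = np.where(total > 0, root / total, np.nan)
        out["root_shoot"] = np.where(shoot > 0, root / shoot, np.nan)
    out["component_flag"] = bad
    return out


def fit_growth_rates(
    records: pd.DataFrame, group_keys: list[str] = ["species", "year"]
) -> list[GrowthRates]:
    """OLS growth slopes per group: ln(mass), ln(mass/area), ln(area) on age."""
    req = {"age", "total_mass", "leaf_area"} | set(group_keys)
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {missing}")
    results: list[GrowthRates] = []
    for key, grp in records.groupby(group_keys, sort=True):
        if grp["age"].nunique() < 2:
            raise ValueError(f"group {key}: need at least two distinct ages")
        w = grp["total_mass"].to_numpy(float)
        a = grp["leaf_area"].to_numpy(float)
        if np.any(w <= 0) or np.any(a <= 0):
            raise ValueError(f"group {key}: non-positive mass or leaf area")
        age = grp["age"].to_numpy(float)
        fits = [
            stats.linregress(age, np.log(w)),
            stats.linregress(age, np.log(w / a)),
            stats.linregress(age, np.log(a)),
        ]
        key_t = key if isinstance(key, tuple) else (key,)
        results.append(
            GrowthRates(
                group=key_t,
                rgr=fits[0].slope,
                rgr_se=fits[0].stderr,
                nar_slope=fits[1].slope,
                nar_se=fits[1].stderr,
                leaf_area_rgr=fits[2].slope,
                leaf_area_rgr_se=fits[2].stderr,
                n=len(grp),
            )
        )
    return results


def relative_change_lar(mean_lar_early: float, mean_lar_late: float) -> float:
    """(LAR_late − LAR_early)/LAR_early; negative means declining leafiness."""
    if mean_lar_early <= 0:
        raise ValueError("early mean LAR must be positive")
    return (mean_lar_late - mean_lar_early) / mean_lar_early


def delta_from_d13c(d13c_plant, d13c_air: float = DELTA_AIR_DEFAULT):
    """Carbon isotope discrimination Δ (per mil) from tissue and air δ13C.

    Δ = (δ_air − δ_plant)/(1 + δ_plant/1000); strictly decreasing in δ_plant.
    """
    d13c_plant = np.asarray(d13c_plant, dtype=float)
    if np.any(d13c_plant == -1000.0):
        raise ValueError("δ13C_plant = −1000 per mil is a singularity")
    out = (d13c_air - d13c_plant) / (1.0 + d13c_plant / 1000.0)
    return float(out) if out.ndim == 0 else out


def d13c_from_delta(delta, d13c_air: float = DELTA_AIR_DEFAULT):
    """Inverse of :func:`delta_from_d13c` (round-trips to machine precision)."""
    delta = np.asarray(delta, dtype=float)
    out = (d13c_air - delta) / (1.0 + delta / 1000.0)
    return float(out) if out.ndim == 0 else out


def rgr_ancova(records: pd.DataFrame, ss_type: int = 2) -> pd.DataFrame:
    """Mixed ANCOVA on RGR: ln(total mass) ~ age + species*year, plot random.

    The species-by-year term is the question of interest: does relative
    growth differ between the invader and the native across contrasting
    growing seasons? Returns the per-term F table.
    """
    return _mass_ancova(records, "total_mass", ss_type)


def nar_ancova(records: pd.DataFrame, ss_type: int = 2) -> pd.DataFrame:
    """Mixed ANCOVA on NAR: ln(mass per leaf area) ~ age + species*year, plot random."""
    recs = records.copy()
    if np.any(recs["leaf_area"].to_numpy(float) <= 0):
        raise ValueError("non-positive leaf area")
    recs["mass_per_area"] = recs["total_mass"] / recs["leaf_area"]
    return _mass_ancova(recs, "mass_per_area", ss_type)


def _mass_ancova(records: pd.DataFrame, response: str, ss_type: int) -> pd.DataFrame:
    for col in ("species", "year"):
        if records[col].nunique() < 2:
            raise ValueError(f"need both levels of {col!r}")
    spec = ModelSpec(
        response=response,
        covariates=["age"],
        fixed_factors=["species", "year"],
        interactions=[("species", "year")],
        random_factor="plot",
        transform="log",
    )
    return fit_ancova(records, spec, ss_type=ss_type)


def midseason_anova(
    records: pd.DataFrame, component: str, age: float = MIDSEASON_AGE, ss_type: int = 2
) -> pd.DataFrame:
    """Mixed ANOVA of one ln-transformed allocation component at the anchor age.

    ``component`` is one of sla, lar, lmr, rmr, root_shoot; components are
    computed on the fly if absent. Model: ln(component) ~ species*year with
    plot random, fitted to records harvested at ``age`` only.
    """
    if component not in COMPONENT_NAMES:
        raise ValueError(f"unknown component {component!r}")
    recs = records if component in records.columns else compute_components(records)
    at_age = recs[recs["age"] == age]
    cells = at_age.groupby(["species", "year"], observed=True).size()
    if len(cells) < 4:
        raise ValueError(f"missing species×year cell at age {age}")
    spec = ModelSpec(
        response=component,
        fixed_factors=["species", "year"],
        interactions=[("species", "year")],
        random_factor="plot",
        transform="log",
    )
    return fit_anova(at_age, spec, ss_type=ss_type)


def leafchem_anova(
    isotope_records: pd.DataFrame, response: str, ss_type: int = 2
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA for leaf chemistry (leaf N or Δ).

    Model: response ~ species + year + species×year, no random factor;
    with n records per cell the error df is N − 4.
    """
    cells = isotope_records.groupby(["species", "year"], observed=True).size()
    if len(cells) < 4 or (cells < 2).any():
        raise ValueError("need ≥2 records in every species×year cell")
    spec = ModelSpec(
        response=response,
        fixed_factors=["species", "year"],
        interactions=[("species", "year")],
    )
    return fit_anova(isotope_records, spec, ss_type=ss_type)
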