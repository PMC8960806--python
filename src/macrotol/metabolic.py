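"""Indirect calorimetry: CO2 production to standardized resting metabolic rate.

Flow-through respirometry yields a fly's rate of CO2 production (V̇CO2,
μL h⁻¹).  Converting that to a rate of energy metabolism requires the
respiratory quotient (RQ, the ratio of CO2 produced to O2 consumed),
which depends on the substrate mixture being catabolized.  Assuming
flies catabolize the substrate mix of their diet, RQ is predicted from
the dietary sugar-to-yeast (S:Y) mass ratio,

    RQ = 0.872 + 0.125 * log10(S:Y + 1),

and the energy equivalent of CO2 (J per mL) by linear interpolation
between mixed protein catabolism in a uricotelic species
(25.4 J mL⁻¹ at RQ 0.74) and pure carbohydrate catabolism
(21.1 J mL⁻¹ at RQ 1.0):

    EE = 37.64 - 16.54 * RQ.

Power (mJ h⁻¹) is then V̇CO2 x EE.  Finally, an ordinary linear model of
metabolic rate on experimental condition + fresh mass + activity
provides slopes used to standardize each fly to its RNAi library's
reference mass (GD 0.83 mg, kk 0.77 mg, Trip 0.81 mg) and to zero
activity, giving a mass-independent resting metabolic rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EnergyModel",
    "DEFAULT_ENERGY_MODEL",
    "DietSpec",
    "DIET_RECIPES",
    "diet_sy_ratio",
    "predict_rq",
    "energy_equivalent",
    "vco2_to_power",
    "convert_records",
    "StandardizationFit",
    "fit_standardization",
    "adjust_mr",
]

_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DietSpec:
    """Sucrose and yeast content of a diet, in % w/v."""

    sucrose_wv: float
    yeast_wv: float


#: Sucrose/yeast composition of the six screen diets (all share the 10%
#: w/v yeast base; fat and starch supplements carry no sugar, so their
#: S:Y ratio is that of their sucrose content alone).
DIET_RECIPES: Mapping[str, DietSpec] = {
    "HPD": DietSpec(0.0, 10.0),
    "HSD": DietSpec(20.0, 10.0),
    "HFDcoco": DietSpec(0.0, 10.0),
    "HFDlard": DietSpec(0.0, 10.0),
    "WD": DietSpec(10.0, 10.0),
    "HStD": DietSpec(0.0, 10.0),
}


@dataclass(frozen=True)
class EnergyModel:
    """Fixed coefficients of the RQ and energy-equivalent relationships.

    The energy-equivalent line must pass through both anchor points
    (protein/uricotelic and carbohydrate catabolism) to within
    0.01 J mL⁻¹; this is asserted at construction.
    """

    rq_intercept: float = 0.872
    rq_slope: float = 0.125  # per log10(S:Y + 1)
    ee_intercept: float = 37.64  # J mL^-1
    ee_slope: float = -16.54  # J mL^-1 per RQ unit
    anchors: tuple = ((0.74, 25.4), (1.0, 21.1))  # (RQ, J mL^-1)
    reference_masses: Mapping[str, float] = field(
        default_factory=lambda: {"GD": 0.83, "kk": 0.77, "Trip": 0.81}
    )

    def __post_init__(self) -> None:
        for rq, ee in self.anchors:
            pred = self.ee_intercept + self.ee_slope * rq
            if abs(pred - ee) > 0.01:
                raise ValueError(
                    f"energy-equivalent line misses anchor (RQ={rq}, {ee} J/mL) "
                    f"by {abs(pred - ee):.4f} J/mL"
                )


DEFAULT_ENERGY_MODEL = EnergyModel()


def diet_sy_ratio(diet: DietSpec) -> float:
    """Sugar-to-yeast mass ratio of a diet (sucrose w/v over yeast w/v)."""
    if diet.yeast_wv <= 0:
        raise ValueError("diet must contain yeast (yeast_wv > 0)")
    return diet.sucrose_wv / diet.yeast_wv


def predict_rq(sy_ratio: float, model: EnergyModel = DEFAULT_ENERGY_MODEL) -> float:
    """Respiratory quotient predicted from the dietary S:Y ratio."""
    if sy_ratio < 0:
        raise ValueError("S:Y ratio must be non-negative")
    rq = model.rq_intercept + model.rq_slope * math.log10(sy_ratio + 1.0)
    if not 0.7 < rq <= 1.0:
        _log.warning("predicted RQ %.3f outside the physiological range (0.7, 1.0]", rq)
    return rq


def energy_equivalent(rq: float, model: EnergyModel = DEFAULT_ENERGY_MODEL) -> float:
    """Energy equivalent of CO2 (J mL⁻¹) at a given RQ."""
    if not 0.7 <= rq <= 1.0:
        _log.warning("RQ %.3f outside the interpolation range [0.74, 1.0]", rq)
    return model.ee_intercept + model.ee_slope * rq


def vco2_to_power(vco2: float, rq: float, model: EnergyModel = DEFAULT_ENERGY_MODEL) -> float:
    """Convert CO2 production (μL h⁻¹) to metabolic power (mJ h⁻¹).

    μL x J mL⁻¹ = mJ, so no further unit factor is needed.
    """
    if vco2 < 0:
        raise ValueError("vco2 must be non-negative")
    return vco2 * energy_equivalent(rq, model)


def convert_records(
    records: pd.DataFrame,
    model: EnergyModel = DEFAULT_ENERGY_MODEL,
    recipes: Mapping[str, DietSpec] = DIET_RECIPES,
) -> pd.DataFrame:
    """Add ``rq`` and ``mr_mj_per_h`` columns to per-fly respirometry records.

    Requires ``vco2`` (μL h⁻¹) and ``diet`` columns; the diet label is
    looked up in ``recipes``.
    """
    out = records.copy()
    try:
        sy = out["diet"].map(lambda d: diet_sy_ratio(recipes[d]))
    except KeyError as exc:
        raise ValueError(f"no diet recipe for {exc.args[0]!r}") from exc
    out["rq"] = sy.map(lambda r: predict_rq(r, model))
    out["mr_mj_per_h"] = [
        vco2_to_power(v, q, model) for v, q in zip(out["vco2"], out["rq"])
    ]
    return out


@dataclass
class StandardizationFit:
    """OLS fit of metabolic rate on condition + mass + activity."""

    condition_means: pd.Series
    mass_slope: float
    mass_se: float
    mass_t: float
    activity_slope: float
    activity_se: float
    activity_t: float
    df_resid: float
    n_records: int
    results: object = None  # statsmodels results, for diagnostics


def fit_standardization(
    records: pd.DataFrame,
    condition_cols: Sequence[str] = ("genotype", "diet"),
) -> StandardizationFit:
    """Fit the linear standardization model by ordinary least squares.

    The experimental condition is the cell of ``condition_cols`` (by
    default genotype x diet); mass and activity enter as continuous
    covariates.  Raises on rank-deficient designs, naming the aliased
    terms.
    """
    required = {"mr_mj_per_h", "fresh_mass", "activity"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.copy()
    if len(df) == 0:
        raise ValueError("no records to fit")
    cond = df[list(condition_cols)].astype(str).agg(":".join, axis=1)
    dummies = pd.get_dummies(cond, prefix="", prefix_sep="", dtype=float)
    X = pd.concat([dummies, df[["fresh_mass", "activity"]].astype(float)], axis=1)
    y = df["mr_mj_per_h"].astype(float)
    if len(df) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} records for {X.shape[1]} terms"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # locate aliased columns via QR pivoting on the correlation structure
        q, r = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased or 'unknown'}")
    res = sm.OLS(y, X).fit()
    return StandardizationFit(
        condition_means=res.params[dummies.columns],
        mass_slope=float(res.params["fresh_mass"]),
        mass_se=float(res.bse["fresh_mass"]),
        mass_t=float(res.tvalues["fresh_mass"]),
        activity_slope=float(res.params["activity"]),
        activity_se=float(res.bse["activity"]),
        activity_t=float(res.tvalues["activity"]),
        df_resid=float(res.df_resid),
        n_records=len(df),
        results=res,
    )


def adjust_mr(
    record: Mapping,
    fit: StandardizationFit,
    library: str | None = None,
    model: EnergyModel = DEFAULT_ENERGY_MODEL,
) -> float:
    """Standardize one fly's metabolic rate to reference mass and zero activity.

    mr_adjusted = mr - mass_slope * (fresh_mass - reference_mass)
                     - activity_slope * activity

    The reference mass is looked up by RNAi library label (``library``
    argument or a ``library`` key in the record).
    """
    lib = library if library is not None else record.get("library")
    if lib not in model.reference_masses:
        raise ValueError(
            f"unknown library {lib!r}; reference masses exist for "
            f"{sorted(model.reference_masses)}"
        )
    ref = model.reference_masses[lib]
    return float(
        record["mr_mj_per_h"]
        - fit.mass_slope * (record["fresh_mass"] - ref)
        - fit.activity_slope * record["activity"]
    )
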