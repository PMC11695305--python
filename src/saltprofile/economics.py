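"""Seed-cotton yield models on layer conductivities, and field economics.

Yield (kg/hm²) is modelled as a linear function of June (bud-stage) or July
(boll-stage) layer conductivities:

    June:  y = 5630.70 - 157.7125 x3 - 33.93 x4
    July:  y = 5280.58 + 259.50 x2 - 338.78 x5

where x_k is the ECe (dS/m) of layer k (1 = 0-20 cm ... 5 = 80-100 cm).
These presets reflect the agronomy: bud-stage yield responds to root-zone
salinity at 40-80 cm, boll-stage yield to the deeper accumulation zone.
``fit_yield_model`` refits the same form from multi-year data (first years
modelling, later years validation).

Economics converts per-hectare yield to production and income with the
regional figures: farm-gate price 7.15 RMB/kg, planting cost 32,250 RMB/hm²,
study area 15 hm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .metrics import FitMetrics, fit_metrics
from .synthetic import JULY_YIELD_COEFFICIENTS, JUNE_YIELD_COEFFICIENTS

#: Default predictor subsets per month (layer indices, 1 = 0-20 cm).
MONTH_VARIABLE_SUBSETS: dict[str, tuple[int, ...]] = {"June": (3, 4), "July": (2, 5)}


@dataclass(frozen=True)
class YieldModel:
    """Linear yield model for one month: intercept + per-layer slopes."""

    month: str
    intercept: float
    coefficients: dict[int, float]  # layer index -> kg/hm^2 per dS/m
    metrics: FitMetrics | None = None
    metrics_validation: FitMetrics | None = None

    def __post_init__(self) -> None:
        bad = [k for k in self.coefficients if k not in range(1, 6)]
        if bad:
            raise ValueError(f"coefficient keys must be layer indices 1..5, got {bad}")


#: Preset models with the reference calibration coefficients.
JUNE_MODEL = YieldModel("June", *JUNE_YIELD_COEFFICIENTS)
JULY_MODEL = YieldModel("July", *JULY_YIELD_COEFFICIENTS)


@dataclass(frozen=True)
class EconomicsConfig:
    """Regional price, cost and area figures."""

    price_per_kg: float = 7.15  # RMB/kg
    cost_per_ha: float = 32250.0  # RMB/hm^2
    area_ha: float = 15.0  # hm^2

    def __post_init__(self) -> None:
        for name in ("price_per_kg", "cost_per_ha", "area_ha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def fit_yield_model(
    layer_ec_by_year: list[dict[int, float]],
    yields,
    month: str,
    variable_subset: tuple[int, ...] | None = None,
    *,
    n_modelling_years: int = 3,
) -> YieldModel:
    """OLS fit of the monthly yield model on the first ``n_modelling_years``.

    ``layer_ec_by_year`` holds one layer-indexed ECe mapping per year, in
    chronological order; later years are the validation set.  The default
    predictor subset is the month's preset (June: layers 3-4, July: 2 and 5).
    """
    if variable_subset is None:
        if month not in MONTH_VARIABLE_SUBSETS:
            raise ValueError(f"no default variable subset for month {month!r}")
        variable_subset = MONTH_VARIABLE_SUBSETS[month]
    y = np.asarray(yields, dtype=float).ravel()
    if y.size != len(layer_ec_by_year):
        raise ValueError("layer_ec_by_year and yields must cover the same years")
    if n_modelling_years < len(variable_subset) + 1:
        raise ValueError(
            f"{len(variable_subset)} predictors need >= {len(variable_subset) + 1} "
            f"modelling years, got {n_modelling_years}"
        )
    missing = [
        (i, k) for i, ec in enumerate(layer_ec_by_year) for k in variable_subset if k not in ec
    ]
    if missing:
        raise ValueError(f"missing layer variables (year, layer): {missing}")
    X = np.array([[ec[k] for k in variable_subset] for ec in layer_ec_by_year])

    Xm, ym = X[:n_modelling_years], y[:n_modelling_years]
    res = sm.OLS(ym, sm.add_constant(Xm, has_constant="add")).fit()
    model = YieldModel(
        month=month,
        intercept=float(res.params[0]),
        coefficients={k: float(b) for k, b in zip(variable_subset, res.params[1:])},
        metrics=fit_metrics(ym, res.fittedvalues) if ym.size >= 2 and np.ptp(ym) > 0 else None,
    )
    if y.size - n_modelling_years >= 2:
        pred_v = np.array([predict_yield(model, ec) for ec in layer_ec_by_year[n_modelling_years:]])
        yv = y[n_modelling_years:]
        if np.ptp(yv) > 0:
            object.__setattr__(model, "metrics_validation", fit_metrics(yv, pred_v))
    return model


def predict_yield(model: YieldModel, layer_ec: dict[int, float]) -> float:
    """Predicted yield (kg/hm²) from a layer-indexed ECe mapping, floored at 0."""
    missing = [k for k in model.coefficients if k not in layer_ec]
    if missing:
        raise ValueError(f"layer_ec missing required layers: {missing}")
    y = model.intercept + sum(b * layer_ec[k] for k, b in model.coefficients.items())
    return max(y, 0.0)


def total_production(yield_per_ha: float, config: EconomicsConfig = EconomicsConfig()) -> float:
    """Total seed-cotton production (kg) over the study area."""
    if yield_per_ha < 0:
        raise ValueError(f"yield must be >= 0, got {yield_per_ha}")
    return yield_per_ha * config.area_ha


def income(
    yield_per_ha: float, config: EconomicsConfig = EconomicsConfig()
) -> tuple[float, float]:
    """Net income per hectare (RMB/hm²) and total revenue (RMB) over the area.

    income_per_ha = yield * price - planting cost; total = income_per_ha * area.
    """
    income_per_ha = yield_per_ha * config.price_per_kg - config.cost_per_ha
    return income_per_ha, income_per_ha * config.area_ha
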