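"""Shared goodness-of-fit metrics and the gravimetric moisture computation.

Two forms of the coefficient of determination are exposed: the standard
``1 - SS_res/SS_tot`` (default everywhere in this package, because Kalman
analyses are not OLS fitted values and the explained-variance ratio can
exceed 1 for them) and the explained-variance ratio
``sum((yhat - ybar)^2) / sum((y - ybar)^2)``, which coincides with the
standard form for OLS fitted values on their own training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


class MeasurementInconsistencyError(ValueError):
    """Raised when laboratory masses are physically inconsistent."""


@dataclass(frozen=True)
class FitMetrics:
    """R², RMSE and sample count for one fitted model or prediction set."""

    r2: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError(f"rmse must be >= 0, got {self.rmse}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


def _as_vectors(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(
            f"observed and predicted must have equal length, got {obs.size} and {pred.size}"
        )
    return obs, pred


def r_squared(observed, predicted, *, form: str = "residual") -> float:
    """Coefficient of determination between observations and predictions.

    Parameters
    ----------
    observed, predicted
        Equal-length 1-d sequences; ``observed`` must not be constant.
    form
        ``"residual"`` (default): ``1 - SS_res/SS_tot``.
        ``"explained"``: ``SS_reg/SS_tot``, the explained-variance ratio.
        The two agree for OLS fitted values evaluated on the training data.
    """
    obs, pred = _as_vectors(observed, predicted)
    if obs.size < 2:
        raise ValueError("r_squared requires at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("observed values have zero variance; R^2 undefined")
    if form == "residual":
        ss_res = float(np.sum((obs - pred) ** 2))
        return 1.0 - ss_res / ss_tot
    if form == "explained":
        ss_reg = float(np.sum((pred - obs.mean()) ** 2))
        return ss_reg / ss_tot
    raise ValueError(f"unknown form {form!r}; expected 'residual' or 'explained'")


def rmse(observed, predicted) -> float:
    """Root-mean-square error, in the units of the response."""
    obs, pred = _as_vectors(observed, predicted)
    if obs.size == 0:
        raise ValueError("rmse requires at least one pair")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def fit_metrics(observed, predicted) -> FitMetrics:
    """Bundle R² (residual form) and RMSE for one prediction set."""
    obs, pred = _as_vectors(observed, predicted)
    return FitMetrics(r2=r_squared(obs, pred), rmse=rmse(obs, pred), n=int(obs.size))


def gravimetric_water_content(wet_mass: float, dry_mass: float, tare_mass: float = 0.0) -> float:
    """Mass-basis water content θ from oven-drying masses (grams).

    θ = (wet − dry) / (dry − tare), i.e. water mass over dry-soil mass.
    The tare is the empty container; masses include it.
    """
    if dry_mass <= tare_mass:
        raise MeasurementInconsistencyError(
            f"dry mass ({dry_mass} g) must exceed tare ({tare_mass} g)"
        )
    if wet_mass < dry_mass:
        raise MeasurementInconsistencyError(
            f"wet mass ({wet_mass} g) must be >= dry mass ({dry_mass} g)"
        )
    return (wet_mass - dry_mass) / (dry_mass - tare_mass)
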