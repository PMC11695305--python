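"""Dummy-variable regression of profile salinity on depth layer and sample index.

Layer salinity within one survey period is modelled as

    ECe = beta_t * t + sum_i beta_i * d_i + C

where ``t`` is the 1-based sample index in acquisition order (the stream is
site-major with the five depth layers cycling, so with 18 sites there are 90
points and the depth cycle has period 5), ``d_i`` are indicator variables for
the four non-baseline depth layers (baseline 0-20 cm), and C is the
intercept.  Fitting is ordinary least squares on a random modelling subset
of the sampling sites (12 of 18 by default), with held-out sites providing
validation metrics.

The module also provides the stream preprocessing used before assimilation:
a centred moving-average detrend (window truncated at the boundaries so that
trend + residual reconstructs the series exactly) and residual-based outlier
screening (z-score or Tukey-fence rules).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .inversion import split_modelling_validation
from .metrics import FitMetrics, fit_metrics
from .synthetic import LAYERS


@dataclass(frozen=True)
class DetrendConfig:
    """Moving-average window and outlier rule for stream preprocessing."""

    window: int = 5  # default = the depth-cycle length
    outlier_rule: str = "none"  # none | iqr | zscore
    zscore_k: float = 3.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if self.outlier_rule not in ("none", "iqr", "zscore"):
            raise ValueError(f"unknown outlier_rule {self.outlier_rule!r}")


@dataclass
class DepthRegressionModel:
    """Fitted depth/sample-index linear model for one period."""

    period: str
    beta_t: float
    beta_depth: tuple[float, ...]  # coefficients of non-baseline layers, shallow -> deep
    intercept: float
    layers: tuple[tuple[int, int], ...] = LAYERS
    metrics_modelling: FitMetrics | None = None
    metrics_validation: FitMetrics | None = None
    modelling_sites: tuple = ()
    validation_sites: tuple = ()

    def __post_init__(self) -> None:
        if len(self.beta_depth) != len(self.layers) - 1:
            raise ValueError(
                f"expected {len(self.layers) - 1} depth coefficients, got {len(self.beta_depth)}"
            )


def encode_depth_dummies(layer: tuple[int, int], layers=LAYERS) -> np.ndarray:
    """Indicator vector of a depth layer against the shallowest baseline.

    The baseline (first) layer maps to the all-zero vector; layer k (k >= 2)
    maps to the unit vector with a one at position k-2.
    """
    layer = (int(layer[0]), int(layer[1]))
    try:
        idx = list(layers).index(layer)
    except ValueError:
        raise ValueError(f"unknown layer {layer}; configured layers: {layers}") from None
    out = np.zeros(len(layers) - 1)
    if idx > 0:
        out[idx - 1] = 1.0
    return out


def moving_average_detrend(series, config: DetrendConfig = DetrendConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Centred moving-average trend and residual of a series.

    The window shrinks at the boundaries (mean over the in-range part), so
    ``trend + residual`` reconstructs the input exactly at every position.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < config.window:
        raise ValueError(f"series length {x.size} is shorter than window {config.window}")
    trend = (
        pd.Series(x).rolling(window=config.window, center=True, min_periods=1).mean().to_numpy()
    )
    return trend, x - trend


def remove_outliers(series, config: DetrendConfig) -> tuple[np.ndarray, np.ndarray]:
    """Indices kept/removed by residual-based outlier screening.

    The series is first detrended with the configured moving average; the
    rule is applied to the residual.  ``zscore`` removes |z| > k; ``iqr``
    removes points outside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].
    A zero-spread residual removes nothing.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"need at least 4 points for outlier screening, got {x.size}")
    idx = np.arange(x.size)
    if config.outlier_rule == "none":
        return idx, np.array([], dtype=int)
    if x.size < config.window:
        # shrink to the largest odd window that fits
        w = x.size if x.size % 2 == 1 else x.size - 1
        config = DetrendConfig(window=w, outlier_rule=config.outlier_rule, zscore_k=config.zscore_k)
    _, resid = moving_average_detrend(x, config)
    if config.outlier_rule == "zscore":
        sd = resid.std()
        if sd == 0:
            return idx, np.array([], dtype=int)
        mask = np.abs(resid - resid.mean()) / sd > config.zscore_k
    else:  # iqr
        q1, q3 = np.percentile(resid, [25, 75])
        iqr = q3 - q1
        mask = (resid < q1 - 1.5 * iqr) | (resid > q3 + 1.5 * iqr)
    return idx[~mask], idx[mask]


def _design_matrix(samples: pd.DataFrame, layers) -> np.ndarray:
    dummies = np.vstack(
        [
            encode_depth_dummies((t, b), layers)
            for t, b in zip(samples["layer_top_cm"], samples["layer_bottom_cm"])
        ]
    )
    t = samples["t"].to_numpy(dtype=float)
    return np.column_stack([t, dummies])


def assign_sample_index(samples: pd.DataFrame) -> pd.DataFrame:
    """Attach the 1-based acquisition index ``t`` (site-major, layers cycling)."""
    out = samples.sort_values(["site_id", "layer_top_cm"], kind="stable").reset_index(drop=True)
    out["t"] = np.arange(1, len(out) + 1)
    return out


def fit_depth_model(
    samples: pd.DataFrame,
    period: str | None = None,
    split_seed: int = 0,
    *,
    modelling_fraction: float = 2.0 / 3.0,
    layers=LAYERS,
) -> DepthRegressionModel:
    """Fit the depth/sample-index model for one period with a site-group split.

    ``samples`` must hold a single period.  Sites are split into modelling
    and validation groups (12:6 at the default fraction with 18 sites); the
    model is fitted on the modelling sites and both metric sets are computed.
    """
    if period is not None:
        samples = samples[samples["period"] == period]
    periods = samples["period"].unique()
    if len(periods) != 1:
        raise ValueError(f"fit_depth_model expects one period at a time, got {list(periods)}")
    period = str(periods[0])
    if len(samples) < 7:
        raise ValueError(f"need at least 7 observations, got {len(samples)}")

    indexed = assign_sample_index(samples)
    sites = sorted(indexed["site_id"].unique())
    model_sites, valid_sites = split_modelling_validation(
        sites, modelling_fraction, seed=split_seed
    )
    train = indexed[indexed["site_id"].isin(model_sites)]
    test = indexed[indexed["site_id"].isin(valid_sites)]

    X = sm.add_constant(_design_matrix(train, layers), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = ["const", "t"] + [f"d{i + 2}" for i in range(len(layers) - 1)]
        raise ValueError(f"rank-deficient design matrix; columns {names} are collinear")
    y = train["ece_dsm"].to_numpy()
    res = sm.OLS(y, X).fit()
    model = DepthRegressionModel(
        period=period,
        beta_t=float(res.params[1]),
        beta_depth=tuple(float(b) for b in res.params[2:]),
        intercept=float(res.params[0]),
        layers=tuple(layers),
        modelling_sites=tuple(model_sites),
        validation_sites=tuple(valid_sites),
    )
    model.metrics_modelling = fit_metrics(y, res.fittedvalues)
    if len(test) >= 2:
        pred = predict_depth_frame(model, test)
        model.metrics_validation = fit_metrics(test["ece_dsm"].to_numpy(), pred)
    return model


def predict_depth_model(model: DepthRegressionModel, t: float, layer: tuple[int, int]) -> float:
    """Predicted ECe (dS/m) at sample index ``t`` for one depth layer."""
    d = encode_depth_dummies(layer, model.layers)
    return model.beta_t * t + float(np.dot(model.beta_depth, d)) + model.intercept


def predict_depth_frame(model: DepthRegressionModel, samples: pd.DataFrame) -> np.ndarray:
    """Vectorized prediction over an indexed sample table (needs a ``t`` column)."""
    if "t" not in samples.columns:
        samples = assign_sample_index(samples)
    return np.array(
        [
            predict_depth_model(model, t, (top, bottom))
            for t, top, bottom in zip(
                samples["t"], samples["layer_top_cm"], samples["layer_bottom_cm"]
            )
        ]
    )
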