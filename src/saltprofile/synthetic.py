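"""Synthetic soil-profile, EM38 survey, and yield generators.

Field campaigns of this kind — repeated stratified augering of a drip-irrigated
cotton field plus EM38-MK2 apparent-conductivity transects — rarely release
their raw tables.  This module generates data with the same statistical
structure so that every downstream stage (layer inversion, depth regression,
Kalman calibration, yield economics) is testable end to end.

The profile generator follows an additive decomposition of layer salinity:
a per-layer long-term depth trend, a per-period seasonal offset, and white
measurement noise.  The instrument simulator maps layered true conductivity
to the four EM38-MK2 channels through the standard cumulative depth-response
functions for a coil at height zero: for normalized depth ``z = depth/spacing``

    R_V(z) = 1 / sqrt(4 z^2 + 1)          (vertical dipole)
    R_H(z) = sqrt(4 z^2 + 1) - 2 z        (horizontal dipole)

A layer spanning ``[z_top, z_bot]`` contributes weight ``R(z_top) - R(z_bot)``
and the unobserved halfspace below the deepest sampled layer contributes the
residual ``R(z_bot_last)``; the weights telescope to 1 because ``R(0) = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Depth layers sampled by the auger campaign, cm (top, bottom).
LAYERS: tuple[tuple[int, int], ...] = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))

#: Survey periods: pre-sowing, bud stage, boll stage, harvest.
PERIODS: tuple[str, ...] = ("March", "June", "July", "October")

#: Instrument channels: dipole orientation x coil spacing (m).
CHANNELS: tuple[str, ...] = ("ec_h05", "ec_h10", "ec_v05", "ec_v10")

_CHANNEL_GEOMETRY: dict[str, tuple[str, float]] = {
    "ec_h05": ("horizontal", 0.5),
    "ec_h10": ("horizontal", 1.0),
    "ec_v05": ("vertical", 0.5),
    "ec_v10": ("vertical", 1.0),
}

SAMPLE_COLUMNS = ["site_id", "period", "layer_top_cm", "layer_bottom_cm", "ece_dsm", "theta"]
SURVEY_COLUMNS = ["x_m", "y_m", "period", "ec_h05", "ec_h10", "ec_v05", "ec_v10"]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass(frozen=True)
class SoilSample:
    """One depth-layer observation at a sampling site."""

    site_id: int
    period: str
    layer: tuple[int, int]
    ece: float
    theta: float
    wet_mass: float | None = None
    dry_mass: float | None = None
    tare_mass: float | None = None


@dataclass(frozen=True)
class EMSurveyPoint:
    """One EM38-MK2 reading: four apparent-conductivity channels at a location."""

    x: float
    y: float
    period: str
    ec_h05: float
    ec_h10: float
    ec_v05: float
    ec_v10: float


@dataclass(frozen=True)
class ProfileConfig:
    """Study-design parameters of the synthetic campaign.

    Defaults emulate the field layout the pipeline targets: 18 fixed sites,
    five 20-cm layers to 1 m, four survey periods, salinity accumulating with
    depth and peaking at 60-80 cm, and a seasonal offset ordering the overall
    salt load July > June > March > October.
    """

    n_sites: int = 18
    layers: tuple[tuple[int, int], ...] = LAYERS
    periods: tuple[str, ...] = PERIODS
    #: per-layer mean ECe, dS/m (shallow -> deep)
    depth_trend: tuple[float, ...] = (0.4, 0.5, 0.6, 0.8, 0.7)
    #: per-period additive ECe shift, dS/m
    seasonal_offset: dict[str, float] = field(
        default_factory=lambda: {"March": 0.0, "June": 0.05, "July": 0.10, "October": -0.05}
    )
    noise_sd: float = 0.05
    moisture_range: tuple[float, float] = (0.05, 0.30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ConfigurationError(f"n_sites must be >= 2, got {self.n_sites}")
        for (t0, b0), (t1, b1) in zip(self.layers, self.layers[1:]):
            if not (t0 < b0 <= t1 < b1):
                raise ConfigurationError(f"layers must be increasing and non-overlapping: {self.layers}")
        last = self.layers[-1]
        if last[0] >= last[1]:
            raise ConfigurationError(f"layers must be increasing and non-overlapping: {self.layers}")
        if len(self.depth_trend) != len(self.layers):
            raise ConfigurationError(
                f"depth_trend has {len(self.depth_trend)} entries for {len(self.layers)} layers"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.moisture_range
        if not (0.0 <= lo <= hi <= 0.6):
            raise ConfigurationError(f"moisture_range must lie within [0, 0.6], got {self.moisture_range}")
        missing = [p for p in self.periods if p not in self.seasonal_offset]
        if missing:
            raise ConfigurationError(f"seasonal_offset missing periods: {missing}")


def generate_profiles(config: ProfileConfig) -> pd.DataFrame:
    """Generate the full layer-sample table of the campaign.

    Returns one row per (site, period, layer) with
    ``ece = depth_trend[layer] + seasonal_offset[period] + N(0, noise_sd^2)``,
    truncated at zero, and θ drawn uniformly from ``moisture_range``.
    Rows are ordered period-major, then site, then shallow-to-deep layer —
    the acquisition order the assimilation stream assumes.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for period in config.periods:
        offset = config.seasonal_offset[period]
        for site in range(1, config.n_sites + 1):
            for (top, bottom), trend in zip(config.layers, config.depth_trend):
                ece = trend + offset + rng.normal(0.0, config.noise_sd)
                theta = rng.uniform(*config.moisture_range)
                rows.append((site, period, top, bottom, max(ece, 0.0), theta))
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def em38_response_weights(
    layer_edges_cm,
    mode: str,
    spacing_m: float,
) -> tuple[np.ndarray, float]:
    """Per-layer sensitivity weights of one EM38 channel.

    Parameters
    ----------
    layer_edges_cm
        Strictly increasing depth edges in cm, starting at the surface,
        e.g. ``[0, 20, 40, 60, 80, 100]``.
    mode
        ``"horizontal"`` or ``"vertical"`` dipole orientation.
    spacing_m
        Transmitter-receiver coil separation (0.5 or 1.0 m for the MK2).

    Returns
    -------
    (weights, residual)
        ``weights[i]`` is the contribution of layer i; ``residual`` is the
        contribution of the halfspace below the last edge.  They sum to 1.
    """
    edges = np.asarray(layer_edges_cm, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError(f"layer edges must be strictly increasing, got {layer_edges_cm}")
    z = edges / 100.0 / spacing_m  # normalized depth
    if mode == "vertical":
        r = 1.0 / np.sqrt(4.0 * z**2 + 1.0)
    elif mode == "horizontal":
        r = np.sqrt(4.0 * z**2 + 1.0) - 2.0 * z
    else:
        raise ValueError(f"mode must be 'horizontal' or 'vertical', got {mode!r}")
    weights = -np.diff(r)
    if z[0] == 0.0:
        # R(0) = 1 for both orientations; residual closes the telescoping sum.
        assert math.isclose(r[0], 1.0)
    return weights, float(r[-1])


def channel_weights(layers=LAYERS) -> dict[str, tuple[np.ndarray, float]]:
    """Response weights of all four channels over the given layers."""
    edges = [layers[0][0]] + [b for _, b in layers]
    return {
        ch: em38_response_weights(edges, mode, spacing)
        for ch, (mode, spacing) in _CHANNEL_GEOMETRY.items()
    }


def simulate_survey(
    profiles: pd.DataFrame,
    below_profile_ec: float = 0.7,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    points_per_site: int = 1,
    jitter_sd_m: float = 1.0,
    site_spacing_m: float = 30.0,
    moisture_noise_factor=None,
) -> pd.DataFrame:
    """Simulate EM38-MK2 readings over the sampled profiles.

    Each channel reading is the response-weighted sum of the site's layer
    conductivities plus ``residual_weight * below_profile_ec`` plus Gaussian
    instrument noise, truncated at zero.  One point per site/period by
    default; ``points_per_site`` densifies by replication with spatial jitter.

    ``moisture_noise_factor``, if given, maps the site's mean θ to a
    multiplicative factor on ``noise_sd`` — EM38 accuracy degrades in dry
    soil, and this knob reproduces that moisture-dependent error.
    Returns a survey table that also carries ``site_id`` for collocation.
    """
    required = {"site_id", "period", "layer_top_cm", "layer_bottom_cm", "ece_dsm"}
    missing_cols = required - set(profiles.columns)
    if missing_cols:
        raise ValueError(f"profiles table missing columns: {sorted(missing_cols)}")

    layers = sorted(
        {(int(t), int(b)) for t, b in zip(profiles["layer_top_cm"], profiles["layer_bottom_cm"])}
    )
    gaps = []
    for (site, period), grp in profiles.groupby(["site_id", "period"], sort=False):
        have = {(int(t), int(b)) for t, b in zip(grp["layer_top_cm"], grp["layer_bottom_cm"])}
        if have != set(layers):
            gaps.append((site, period, sorted(set(layers) - have)))
    if gaps:
        raise ValueError(f"profiles missing layers for site/period: {gaps}")

    weights = channel_weights(tuple(layers))
    rng = np.random.default_rng(seed)
    rows = []
    n_layers = len(layers)
    for (site, period), grp in profiles.groupby(["site_id", "period"], sort=False):
        grp = grp.sort_values("layer_top_cm")
        ece = grp["ece_dsm"].to_numpy()
        assert ece.size == n_layers
        sd = noise_sd
        if moisture_noise_factor is not None and "theta" in grp.columns:
            sd = noise_sd * float(moisture_noise_factor(float(grp["theta"].mean())))
        base_x = float(site - 1) * site_spacing_m
        for rep in range(points_per_site):
            jitter = rng.normal(0.0, jitter_sd_m, size=2) if points_per_site > 1 else np.zeros(2)
            vals = {}
            for ch, (w, resid) in weights.items():
                clean = float(w @ ece) + resid * below_profile_ec
                vals[ch] = max(clean + rng.normal(0.0, sd) if sd > 0 else clean, 0.0)
            rows.append(
                (base_x + jitter[0], jitter[1], period, site,
                 vals["ec_h05"], vals["ec_h10"], vals["ec_v05"], vals["ec_v10"])
            )
    return pd.DataFrame(rows, columns=["x_m", "y_m", "period", "site_id"] + list(CHANNELS))


def dry_soil_noise_factor(theta: float) -> float:
    """Default moisture->noise multiplier: dry soil degrades EM38 accuracy.

    3x noise below 10% moisture, 1.5x between 10 and 20%, nominal above 20%.
    """
    if theta < 0.10:
        return 3.0
    if theta < 0.20:
        return 1.5
    return 1.0


# Yield-model coefficient presets: intercept (kg/hm^2) and per-layer slopes
# (kg/hm^2 per dS/m), keyed by layer index 1..5 where layer 1 is 0-20 cm.
JUNE_YIELD_COEFFICIENTS: tuple[float, dict[int, float]] = (5630.70, {3: -157.7125, 4: -33.93})
JULY_YIELD_COEFFICIENTS: tuple[float, dict[int, float]] = (5280.58, {2: 259.50, 5: -338.78})


def _linear_yield(coeffs: tuple[float, dict[int, float]], layer_ec: dict[int, float]) -> float:
    intercept, slopes = coeffs
    missing = [k for k in slopes if k not in layer_ec]
    if missing:
        raise ValueError(f"layer_ec missing required layer variables: {missing}")
    return intercept + sum(b * layer_ec[k] for k, b in slopes.items())


def simulate_yields(
    layer_ec_june: dict[int, float],
    layer_ec_july: dict[int, float],
    coefficients: dict[str, tuple[float, dict[int, float]]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Seed-cotton yields (kg/hm²) from bud- and boll-stage layer conductivities.

    ``yield = intercept + Σ coef·layer_ec + N(0, noise_sd²)``, floored at 0,
    one value per month.  ``layer_ec_*`` are keyed by layer index (1 = 0-20 cm
    ... 5 = 80-100 cm); defaults are the fitted June/July coefficient presets.
    """
    if coefficients is None:
        coefficients = {"June": JUNE_YIELD_COEFFICIENTS, "July": JULY_YIELD_COEFFICIENTS}
    rng = np.random.default_rng(seed)
    layer_ec = {"June": layer_ec_june, "July": layer_ec_july}
    out = {}
    for month, coeffs in coefficients.items():
        y = _linear_yield(coeffs, layer_ec[month])
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd)
        out[month] = max(y, 0.0)
    return out


def simulate_yield_series(
    layer_ec_by_year: list[dict[int, float]],
    coefficients: tuple[float, dict[int, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Multi-year yield series from one month's coefficients (for model fitting)."""
    rng = np.random.default_rng(seed)
    ys = np.array([_linear_yield(coefficients, ec) for ec in layer_ec_by_year])
    if noise_sd > 0:
        ys = ys + rng.normal(0.0, noise_sd, size=ys.size)
    return np.maximum(ys, 0.0)
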