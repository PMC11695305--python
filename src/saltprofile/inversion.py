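"""Per-depth-layer linear inversion of EM38 apparent conductivity to ECe.

For each survey period and each 20-cm depth layer, a simple linear model
``ECe = a + b * ECa`` is fitted by ordinary least squares for each of the
four instrument channels, and the channel with the highest R² is selected
as the modelling factor for that layer.  The horizontal 0.5-m channel is
most sensitive to shallow soil and the vertical 1.0-m channel to deep soil,
so the selected channel typically deepens with the layer; a fixed preset
encoding that assignment (h0.5 for 0-40 cm, v0.5 for 40-80 cm, v1.0 for
80-100 cm) is also provided.

Model accuracy depends on soil moisture: the instrument senses the free
conductive medium, and inversion quality degrades below ~10% gravimetric
moisture.  ``stratify_by_moisture`` partitions samples into the three
conventional gradients (0-10%, 10-20%, >20%) for that analysis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import FitMetrics, fit_metrics
from .synthetic import CHANNELS, LAYERS

#: Channel preference order for ties: shallow-sensitive first.
CHANNEL_PREFERENCE: tuple[str, ...] = ("ec_h05", "ec_h10", "ec_v05", "ec_v10")

#: Fixed channel-by-depth assignment used when data-driven selection is off.
PRESET_CHANNELS: dict[tuple[int, int], str] = {
    (0, 20): "ec_h05",
    (20, 40): "ec_h05",
    (40, 60): "ec_v05",
    (60, 80): "ec_v05",
    (80, 100): "ec_v10",
}

#: Published-style calibration coefficients (intercept a, slope b) per
#: period and layer for the preset channel of that layer, dS/m — a
#: representative drip-irrigated cotton-field calibration used as the
#: ground truth of synthetic recovery experiments and demo runs.
FIELD_CALIBRATION: dict[tuple[str, tuple[int, int]], tuple[float, float]] = {
    ("March", (0, 20)): (-0.679, 0.907),
    ("March", (20, 40)): (-0.665, 0.834),
    ("March", (40, 60)): (-0.083, 0.503),
    ("March", (60, 80)): (0.274, 0.454),
    ("March", (80, 100)): (0.325, 0.476),
    ("June", (0, 20)): (-0.645, 0.769),
    ("June", (20, 40)): (0.843, 0.694),
    ("June", (40, 60)): (0.264, 0.456),
    ("June", (60, 80)): (0.283, 0.463),
    ("June", (80, 100)): (0.304, 0.473),
    ("July", (0, 20)): (-1.566, 1.566),
    ("July", (20, 40)): (-1.424, 1.011),
    ("July", (40, 60)): (-0.675, 0.785),
    ("July", (60, 80)): (0.301, 0.496),
    ("July", (80, 100)): (-0.079, 0.521),
    ("October", (0, 20)): (-0.671, 0.863),
    ("October", (20, 40)): (-1.347, 1.432),
    ("October", (40, 60)): (-0.372, 0.534),
    ("October", (60, 80)): (-0.405, 0.573),
    ("October", (80, 100)): (0.353, 0.479),
}

#: The three conventional gravimetric-moisture gradients, lower-closed.
MOISTURE_GRADIENTS: tuple[tuple[str, float, float], ...] = (
    ("0-10%", 0.0, 0.10),
    ("10-20%", 0.10, 0.20),
    (">20%", 0.20, float("inf")),
)


@dataclass(frozen=True)
class LayerInversionModel:
    """Fitted linear map ECa -> ECe for one period, layer and channel."""

    period: str
    layer: tuple[int, int]
    channel: str
    intercept: float
    slope: float
    metrics: FitMetrics
    sample_key: str = ""  # fingerprint of the fitting set, for comparability checks

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.metrics.n < 3:
            raise ValueError(f"inversion fit needs n >= 3, got {self.metrics.n}")


def _fingerprint(values: np.ndarray) -> str:
    return hashlib.sha1(np.round(np.sort(values), 9).tobytes()).hexdigest()[:16]


def fit_layer_inversion(
    eca,
    ece,
    period: str,
    layer: tuple[int, int],
    channel: str,
) -> LayerInversionModel:
    """OLS fit of ``ECe = a + b * ECa`` on collocated pairs for one layer."""
    x = np.asarray(eca, dtype=float).ravel()
    y = np.asarray(ece, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("eca and ece must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate predictor: channel {channel} is constant")
    if np.ptp(y) == 0:
        # constant response: slope 0, intercept at the constant
        mets = FitMetrics(r2=0.0, rmse=0.0, n=int(x.size))
        return LayerInversionModel(period, layer, channel, float(y[0]), 0.0, mets, _fingerprint(y))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    pred = res.fittedvalues
    return LayerInversionModel(
        period=period,
        layer=layer,
        channel=channel,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        metrics=fit_metrics(y, pred),
        sample_key=_fingerprint(y),
    )


def select_best_channel(models: list[LayerInversionModel]) -> str:
    """Channel with maximal R² among candidate fits of one layer.

    All candidates must be fitted on the same response sample; ties are
    broken by the shallow-sensitivity preference order.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 candidate models")
    keys = {m.sample_key for m in models}
    ns = {m.metrics.n for m in models}
    if len(keys) > 1 or len(ns) > 1:
        raise ValueError("candidate models were fitted on differing sample sets")
    order = {ch: i for i, ch in enumerate(CHANNEL_PREFERENCE)}
    best = max(models, key=lambda m: (m.metrics.r2, -order[m.channel]))
    return best.channel


def moisture_gradient_label(theta: float) -> str:
    """Gradient label for one θ (lower-closed bins)."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    for label, lo, hi in MOISTURE_GRADIENTS:
        if lo <= theta < hi:
            return label
    raise AssertionError("unreachable: gradients partition [0, inf)")


def stratify_by_moisture(samples: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a sample table into the three moisture gradients by θ."""
    if "theta" not in samples.columns:
        raise ValueError("samples table has no 'theta' column")
    missing = samples.index[samples["theta"].isna()].tolist()
    if missing:
        raise ValueError(f"samples missing theta at rows: {missing}")
    labels = samples["theta"].map(moisture_gradient_label)
    return {label: samples[labels == label] for label, _, _ in MOISTURE_GRADIENTS}


def split_modelling_validation(
    groups,
    modelling_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    *,
    gradient_labels: dict | None = None,
):
    """Random disjoint modelling/validation split of group identifiers.

    Sizes are ``round(f * n)`` and the remainder (18 groups at f=2/3 give the
    conventional 12:6 split).  When ``gradient_labels`` maps each group to a
    moisture gradient, the validation set is re-drawn (deterministically)
    until it spans every occupied gradient, so validation covers the full
    moisture range.
    """
    groups = list(groups)
    n = len(groups)
    if n < 3:
        raise ValueError(f"need at least 3 groups, got {n}")
    if not (0.0 < modelling_fraction < 1.0):
        raise ValueError(f"modelling_fraction must be in (0, 1), got {modelling_fraction}")
    n_model = int(round(modelling_fraction * n))
    n_model = min(max(n_model, 1), n - 1)
    rng = np.random.default_rng(seed)
    occupied = set(gradient_labels.values()) if gradient_labels else None
    for _ in range(1000):
        perm = rng.permutation(n)
        modelling = [groups[i] for i in perm[:n_model]]
        validation = [groups[i] for i in perm[n_model:]]
        if occupied is None:
            return modelling, validation
        if {gradient_labels[g] for g in validation} == occupied:
            return modelling, validation
    raise ValueError("could not draw a validation set spanning all occupied moisture gradients")


def predict_ece(model: LayerInversionModel, eca) -> np.ndarray | float:
    """Apply a fitted inversion: ``ECe = intercept + slope * ECa``."""
    eca_arr = np.asarray(eca, dtype=float)
    out = model.intercept + model.slope * eca_arr
    return float(out) if out.ndim == 0 else out


def fit_all_inversions(
    samples: pd.DataFrame,
    survey: pd.DataFrame,
    *,
    selection: str = "best",
) -> pd.DataFrame:
    """Fit inversions for every period/layer from collocated tables.

    Survey points are matched to sampling sites via ``site_id`` (site means
    when the survey is densified).  ``selection`` is ``"best"`` (data-driven
    channel per layer) or ``"preset"`` (fixed channel-by-depth assignment).
    Returns a tidy model table (period, layer, channel, intercept, slope,
    r2, rmse, n).
    """
    if selection not in ("best", "preset"):
        raise ValueError(f"selection must be 'best' or 'preset', got {selection!r}")
    if "site_id" not in survey.columns:
        raise ValueError("survey table has no 'site_id' column for collocation")
    eca_site = survey.groupby(["period", "site_id"], sort=False)[list(CHANNELS)].mean()
    rows = []
    for (period, top, bottom), grp in samples.groupby(
        ["period", "layer_top_cm", "layer_bottom_cm"], sort=False
    ):
        layer = (int(top), int(bottom))
        grp = grp.sort_values("site_id")
        eca_rows = eca_site.loc[[(period, s) for s in grp["site_id"]]]
        ece = grp["ece_dsm"].to_numpy()
        fits = {
            ch: fit_layer_inversion(eca_rows[ch].to_numpy(), ece, period, layer, ch)
            for ch in CHANNELS
        }
        if selection == "best":
            chosen = select_best_channel(list(fits.values()))
        else:
            chosen = PRESET_CHANNELS.get(layer)
            if chosen is None:
                raise ValueError(f"no preset channel for layer {layer}")
        m = fits[chosen]
        rows.append(
            (period, top, bottom, m.channel, m.intercept, m.slope,
             m.metrics.r2, m.metrics.rmse, m.metrics.n)
        )
    return pd.DataFrame(
        rows,
        columns=["period", "layer_top_cm", "layer_bottom_cm", "channel",
                 "intercept", "slope", "r2", "rmse", "n"],
    )
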