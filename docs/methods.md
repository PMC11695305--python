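# Methods

## Scope and model chain

The package implements a four-stage analysis of profile salinity in
drip-irrigated cotton fields: (1) inversion of EM38-MK2 apparent conductivity
(ECa, dS/m) to layer conductivity (ECe, dS/m) by per-period, per-layer linear
models; (2) a dummy-variable least-squares regression of ECe on depth layer
and sample index; (3) scalar Kalman-filter assimilation that calibrates the
regression predictions against the measured stream; (4) linear yield models on
June/July layer conductivities with a price/cost/area economics layer. A
synthetic-survey generator supplies inputs with the statistical structure the
analysis assumes.

## Synthetic generator

Layer salinity follows an additive decomposition
`ECe(site, period, layer) = T(layer) + S(period) + ε`, ε ~ N(0, σ²) truncated
at 0, with gravimetric moisture θ uniform over a configured range. Defaults
describe the study conditions the pipeline targets:

| parameter | default | rationale |
|---|---|---|
| n_sites | 18 | fixed sampling points per campaign (90-point stream with 5 layers) |
| layers | 0–20 … 80–100 cm | auger strata, five 20-cm layers to 1 m |
| periods | March, June, July, October | pre-sowing, bud, boll, harvest |
| depth trend T | (0.4, 0.5, 0.6, 0.8, 0.7) dS/m | salinity accumulates with depth and peaks at 60–80 cm under mulched drip irrigation |
| seasonal offset S | (0, +0.05, +0.10, −0.05) dS/m | orders overall salt load July > June > March > October |
| noise σ | 0.05 dS/m | replicate-scale ECe measurement error |
| moisture range | 0.05–0.30 | spans the three moisture gradients |
| below-profile ECe | 0.7 dS/m | unobserved halfspace under 1 m, set explicitly rather than extrapolated |
| instrument noise | 0.02 dS/m | EM38 channel repeatability |

The EM38 forward model uses the standard cumulative depth-response functions
for normalized depth z = depth/spacing — R_V(z) = 1/√(4z²+1),
R_H(z) = √(4z²+1) − 2z — with layer weight R(z_top) − R(z_bot) and the
below-profile residual R(z_last); because R(0) = 1 the weights telescope to 1,
which yields the homogeneous-halfspace identity (constant profile in, same
constant out on all four channels) used as an exact invariant. An optional
moisture→noise multiplier (3× below 10% moisture, 1.5× at 10–20%) emulates the
degradation of instrument accuracy in dry soil; with it, inversion R² is worst
in the 0–10% gradient, matching the qualitative field finding.

What the generator does **not** emulate: spatial autocorrelation between
sites, salt-transport physics (irrigation events, evaporation pulses),
non-Gaussian error tails, and any linkage between survey-point density and
site count beyond collocation. Passing tests therefore demonstrate that the
estimators and the filter behave correctly under the assumed additive model,
not that the fitted field coefficients transfer to real campaigns.

## Inversion

Per period and layer, `ECe = a + b·ECa` is fitted by OLS (statsmodels) for
each channel; the modelling channel is the one with maximal R², ties broken by
the shallow-sensitivity preference order (h0.5, h1.0, v0.5, v1.0). A fixed
preset (h0.5 for 0–40 cm, v0.5 for 40–80 cm, v1.0 for 80–100 cm) is available
where the data-driven choice is not wanted. Moisture gradients are
lower-closed bins [0, 0.10), [0.10, 0.20), [0.20, ∞) — conventional half-open
binning; θ is a mass-basis fraction, so "10%" is 0.10. Modelling/validation
splits draw `round(f·n)` groups (12:6 at f = 2/3 with 18 sites); when gradient
labels are supplied the validation draw is repeated (deterministically under
the seed) until it spans every occupied gradient.

## Depth regression

The design matrix is [t, d₂…d₅] plus intercept: t is the 1-based acquisition
index within the period (site-major, depth cycling with period 5) and dᵢ are
indicators against the 0–20 cm baseline — the shallowest layer is the natural
reference. Rank deficiency (e.g. single-layer input) raises an error naming
the collinear columns. The moving-average detrend uses a centred window
(default 5, the depth-cycle length) truncated at the boundaries so that
trend + residual reconstructs the series exactly; outlier screening applies a
z-score (default k = 3) or Tukey-fence rule to the detrended residual, and a
zero-spread residual removes nothing.

## Kalman filter

State, forecast and update are scalar:

    x_f = m·x_a            p_f = m²·p_a + q
    K   = p_f·h / (h²·p_f + r)
    x_a = x_f + K(y − h·x_f)
    p_a = (1 − K·h)·p_f

with h = 1 (observations are direct ECe measurements). The transition m has no
operational physical definition in this setting; the default is the ratio of
consecutive background values (fallback 1 when the previous value is within
1e-6 dS/m of zero), so the forecast follows the regression trajectory; an
identity-transition mode with an additive background increment is the
alternative. Initialisation uses the surface-layer convention: x_a is the mean
of the 0–20 cm samples and p_a the squared difference between the first sample
and that mean — squared because p is an error *variance*, commensurate with
Eqs. above. Defaults for the noise variances in the pipeline: r is the
generator's ECe noise variance and q the squared modelling RMSE of the depth
fit; both are white noise. The stream is assimilated interleaved (all 90
points in acquisition order) rather than per layer.

Pre/post comparison uses R² in the standard form 1 − SS_res/SS_tot throughout:
the explained-variance ratio Σ(ŷ−ȳ)²/Σ(y−ȳ)² coincides with it for OLS fitted
values but can exceed 1 for filter analyses, which would make pre/post deltas
incomparable; the ratio form remains available (`form="explained"`). The
calibration growth rate 100·ΔR²/R²_pre is computed in decimal arithmetic and
rounded half-up to one decimal (float subtraction of quantities quoted at two
decimals otherwise misrounds values landing exactly on .x5). RMSE is reported
in both dS/m and μS/cm (1 dS/m = 1000 μS/cm) since both conventions are common.

## Yield and economics

June and July yield models are linear in the preset layer subsets (June:
layers 3–4, i.e. the 40–80 cm root zone; July: layers 2 and 5); no automated
subset selection is performed, though any subset can be passed. Refitting uses
the first three years as the modelling set and later years for validation.
Predicted yields are floored at 0. Income is reported per hectare
(yield·price − cost) and as total revenue over the area; note the per-ha yield
bounds 5203/5551 kg/hm² propagate to totals of 78,045/83,265 kg and
74,271.75/111,594.75 RMB — quoted reference totals computed from unrounded
yields differ by 0.004–0.03%, a reconciliation gap this package documents
rather than matches digit-for-digit.

## Numerical and design choices

- All randomness flows from one seed; the pipeline spawns per-stage substreams
  via `numpy.random.SeedSequence`, so a config+seed pair pins every output.
- Negative draws of conductivity and yield are truncated at 0 (physical
  constraint).
- Candidate inversion models carry a fingerprint of their fitting response;
  channel selection refuses to compare models fitted on different samples.
- Problem sizes in the test suite and acceptance script follow the study
  design (90-point streams; 100 replicates for the stochastic improvement
  experiment; 200 replicates for coefficient-recovery bias), which keeps the
  whole suite under a few seconds while the Monte-Carlo bounds (3σ) remain
  comfortably wide.

## Known limitations

- The generator's site-to-site ECe variation at default settings is pure
  noise, so inversion R² on default pipeline runs is modest; coefficient
  recovery experiments instead generate pairs directly on a known calibration
  line.
- The linear scalar filter assumes Gaussian errors and a linear state
  relationship; no extended/ensemble variants are provided.
- No geostatistics: survey points are collocated with sites by identifier, and
  no spatial interpolation beyond that is attempted.
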