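# saltprofile

Soil-profile salinity modelling for drip-irrigated cotton fields: layer-wise
inversion of EM38-MK2 apparent conductivity, a dummy-variable regression of
profile salinity on depth, scalar Kalman-filter data assimilation that
calibrates the regression against measured conductivity streams, and seed-cotton
yield / economics prediction from layer conductivities.

## Who this is for

Agro-environmental modellers and precision-agriculture researchers monitoring
salinization in arid irrigated fields (the motivating setting is mulched
drip-irrigated cotton in southern Xinjiang, where salts leach downward and
accumulate at 60–100 cm). Field data of this kind are rarely released, so the
package ships a synthetic-survey generator with the same statistical structure —
every stage runs end to end with no download.

## The models

**EM38 forward model / inversion.** An electromagnetic-induction meter senses a
depth-weighted average of bulk conductivity. Per channel (dipole orientation ×
coil spacing *s*), the cumulative depth response at normalized depth *z = d/s*
is R_V(z) = 1/√(4z²+1) (vertical) and R_H(z) = √(4z²+1) − 2z (horizontal); a
layer [z₁, z₂] carries weight R(z₁) − R(z₂). Inversion fits, per period and
per 20-cm layer, the linear map ECe = a + b·ECa by OLS and selects the channel
with the best R² (or uses the fixed shallow-to-deep preset).

**Depth regression.** Within one period the 90-point sample stream (18 sites ×
5 layers, site-major, depth cycling with period 5) is modelled as

    ECe = β_t·t + Σᵢ βᵢ·dᵢ + C

with *t* the 1-based sample index and dᵢ indicator (dummy) variables for the
four non-baseline layers (baseline 0–20 cm), fitted by least squares on a
random 12:6 site split.

**Kalman calibration.** The regression prediction is the background; measured
ECe are the observations. A scalar filter alternates forecast
x_f = m·x_a, p_f = m²·p_a + q and update K = p_f/(p_f + r),
x_a = x_f + K(y − x_f), p_a = (1 − K)p_f, with the transition *m* taken as the
ratio of consecutive background values so the forecast follows the regression
trajectory. Pre/post accuracy is compared by R² and RMSE.

**Yield and economics.** Bud-stage (June) and boll-stage (July) yield models
are linear in layer conductivities (June: y = 5630.70 − 157.7125·x₃ −
33.93·x₄; July: y = 5280.58 + 259.50·x₂ − 338.78·x₅, xₖ the ECe of layer k in
dS/m), with income = yield·price − cost at 7.15 RMB/kg, 32,250 RMB/hm² and a
15 hm² study area.

## Worked example

```python
import saltprofile as sp

report = sp.run_pipeline(sp.PipelineConfig(seed=1))
july = report["assimilate"]["July"]
print(round(july["rmse_pre_uS_cm"], 2), "->", round(july["rmse_post_uS_cm"], 2))
print(round(report["yield"]["low"]["yield_kg_per_ha"], 1),
      round(report["yield"]["high"]["income_rmb_per_ha"], 1))
```

prints

```
49.23 -> 22.22
5164.0 7084.2
```

i.e. for the boll-stage (July) stream, assimilation reduces the RMSE between
predicted and measured conductivity from 49.23 to 22.22 μS/cm; the assimilated
June/July layer conductivities yield 5164 kg/hm² at the low end and a net
income of 7084 RMB/hm² at the high end. The same pipeline is available from
the shell:

```bash
saltprofile run-all --seed 1 --out pipeline_out
saltprofile yield --model june --ec 3=0.6 --ec 4=0.8
```

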