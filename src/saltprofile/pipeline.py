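"""End-to-end pipeline: simulate -> invert -> fit depth model -> assimilate -> yield.

Stage ordering mirrors the field workflow: an EM38 survey and stratified
augering produce collocated tables; per-layer inversions map apparent
conductivity to ECe; the dummy-variable depth regression gives the
background series; the Kalman filter calibrates it against the measured
stream; assimilated layer conductivities for the bud (June) and boll (July)
stages feed the yield and economics models.

All randomness flows from one global seed through per-stage spawned
substreams, so a config+seed pair pins the whole report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .depth_regression import assign_sample_index, fit_depth_model, predict_depth_frame
from .economics import JULY_MODEL, JUNE_MODEL, EconomicsConfig, income, predict_yield, total_production
from .inversion import fit_all_inversions
from .io import config_hash, write_json, write_samples, write_survey, write_table
from .kalman import assimilate_series, evaluate_calibration, kf_init
from .synthetic import LAYERS, ProfileConfig, generate_profiles, simulate_survey


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-pipeline run."""

    profile: ProfileConfig = field(default_factory=ProfileConfig)
    below_profile_ec: float = 0.7  # halfspace ECe under the deepest layer, dS/m
    survey_noise_sd: float = 0.02  # instrument noise, dS/m
    channel_selection: str = "best"  # best | preset
    kf_q: float | None = None  # None -> modelling-residual variance
    kf_r: float | None = None  # None -> profile noise variance
    m_mode: str = "ratio"
    modelling_fraction: float = 2.0 / 3.0
    economics: EconomicsConfig = field(default_factory=EconomicsConfig)
    seed: int = 0
    out_dir: str | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seeds(seed: int, n: int = 5) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all five stages; return (and optionally write) the report bundle."""
    seeds = _stage_seeds(config.seed)
    meta = {
        "seed": config.seed,
        "config_hash": config_hash(config.as_dict()),
        "version": __version__,
    }
    out = Path(config.out_dir) if config.out_dir else None
    report: dict = {"provenance": dict(meta)}

    # -- simulate ---------------------------------------------------------
    profile_cfg = dataclasses.replace(config.profile, seed=seeds[0])
    samples = generate_profiles(profile_cfg)
    survey = simulate_survey(
        samples,
        below_profile_ec=config.below_profile_ec,
        noise_sd=config.survey_noise_sd,
        seed=seeds[1],
    )
    report["simulate"] = {
        "n_samples": int(len(samples)),
        "n_survey_points": int(len(survey)),
        "periods": list(profile_cfg.periods),
        "n_sites": profile_cfg.n_sites,
    }
    if out:
        write_samples(samples, out / "samples.csv", meta)
        write_survey(survey, out / "survey.csv", meta)

    # -- invert -----------------------------------------------------------
    models = fit_all_inversions(samples, survey, selection=config.channel_selection)
    report["invert"] = {
        "n_models": int(len(models)),
        "mean_r2": float(models["r2"].mean()),
        "channels": {
            f"{int(t)}-{int(b)}cm": str(models[(models.layer_top_cm == t) & (models.layer_bottom_cm == b)]["channel"].iloc[0])
            for t, b in LAYERS
        },
    }
    if out:
        write_table(models, out / "inversion_models.csv", meta)

    # -- fit depth model + assimilate ------------------------------------
    depth_section: dict = {}
    calib_section: dict = {}
    june_july_layer_ec: dict[str, dict[int, float]] = {}
    for i, period in enumerate(profile_cfg.periods):
        per = samples[samples["period"] == period]
        model = fit_depth_model(
            per, split_seed=seeds[2] + i, modelling_fraction=config.modelling_fraction,
            layers=profile_cfg.layers,
        )
        indexed = assign_sample_index(per)
        background = predict_depth_frame(model, indexed)
        observations = indexed["ece_dsm"].to_numpy()

        q = config.kf_q if config.kf_q is not None else model.metrics_modelling.rmse**2
        r = config.kf_r if config.kf_r is not None else profile_cfg.noise_sd**2
        surface = indexed[indexed["layer_top_cm"] == profile_cfg.layers[0][0]]["ece_dsm"].to_numpy()
        state0 = kf_init(surface, q=q, r=r)
        run = assimilate_series(
            background, observations, state0,
            m_mode=config.m_mode, cycle=len(profile_cfg.layers),
        )
        calib = evaluate_calibration(run.metrics_pre, run.metrics_post)

        depth_section[period] = {
            "beta_t": model.beta_t,
            "beta_depth": list(model.beta_depth),
            "intercept": model.intercept,
            "r2_model": model.metrics_modelling.r2,
            "rmse_model": model.metrics_modelling.rmse,
            "r2_valid": model.metrics_validation.r2 if model.metrics_validation else None,
            "rmse_valid": model.metrics_validation.rmse if model.metrics_validation else None,
        }
        calib_section[period] = calib.as_dict()

        if period in ("June", "July"):
            indexed = indexed.assign(analysis=run.analyses)
            layer_means = indexed.groupby("layer_top_cm")["analysis"].mean()
            june_july_layer_ec[period] = {
                k + 1: float(layer_means[top]) for k, (top, _) in enumerate(profile_cfg.layers)
            }
        if out:
            write_table(
                indexed.assign(background=background, analysis=run.analyses),
                out / f"assimilation_{period}.csv",
                meta,
            )
    report["fit_depth"] = depth_section
    report["assimilate"] = calib_section

    # -- yield + economics -------------------------------------------------
    yields = {
        "June": predict_yield(JUNE_MODEL, june_july_layer_ec["June"]),
        "July": predict_yield(JULY_MODEL, june_july_layer_ec["July"]),
    }
    lo, hi = min(yields.values()), max(yields.values())
    econ = config.economics
    yield_section = {"yield_kg_per_ha": yields, "layer_ec": june_july_layer_ec}
    for label, y in (("low", lo), ("high", hi)):
        inc_ha, inc_total = income(y, econ)
        yield_section[label] = {
            "yield_kg_per_ha": y,
            "total_kg": total_production(y, econ),
            "income_rmb_per_ha": inc_ha,
            "total_revenue_rmb": inc_total,
        }
    report["yield"] = yield_section

    if out:
        write_json(report, out / "report.json")
    return report
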