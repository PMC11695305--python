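import numpy as np
import pandas as pd
import pytest

from saltprofile.inversion import (
    FIELD_CALIBRATION,
    LayerInversionModel,
    fit_all_inversions,
    fit_layer_inversion,
    moisture_gradient_label,
    predict_ece,
    select_best_channel,
    split_modelling_validation,
    stratify_by_moisture,
)
from saltprofile.metrics import FitMetrics
from saltprofile.synthetic import (
    ProfileConfig,
    dry_soil_noise_factor,
    generate_profiles,
    simulate_survey,
)


class TestFitLayerInversion:
    def test_recovers_exact_linear_calibration(self):
        a, b = FIELD_CALIBRATION[("March", (0, 20))]
        eca = np.linspace(0.5, 3.0, 20)
        model = fit_layer_inversion(eca, a + b * eca, "March", (0, 20), "ec_h05")
        assert model.intercept == pytest.approx(a, abs=1e-10)
        assert model.slope == pytest.approx(b, abs=1e-10)
        assert model.metrics.r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_gives_zero_slope(self):
        model = fit_layer_inversion([1.0, 2.0, 3.0], [0.4, 0.4, 0.4], "June", (0, 20), "ec_h05")
        assert model.slope == 0.0
        assert model.intercept == pytest.approx(0.4)

    def test_noisy_slope_within_sampling_bound(self, rng):
        eca = rng.uniform(0.0, 3.0, 200)
        ece = eca + rng.normal(0, 0.05, 200)  # slope 1, intercept 0
        model = fit_layer_inversion(eca, ece, "June", (0, 20), "ec_h05")
        assert abs(model.slope - 1.0) < 0.02

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_layer_inversion([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], "June", (0, 20), "ec_h05")

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            fit_layer_inversion([1.0, 2.0], [0.1, 0.2], "June", (0, 20), "ec_h05")


def _model(channel, r2, key="k"):
    return LayerInversionModel(
        "June", (20, 40), channel, 0.0, 1.0, FitMetrics(r2=r2, rmse=0.1, n=18), key
    )


class TestSelectBestChannel:
    def test_picks_maximal_r2(self):
        models = [_model("ec_h05", 0.87), _model("ec_h10", 0.70),
                  _model("ec_v05", 0.65), _model("ec_v10", 0.50)]
        assert select_best_channel(models) == "ec_h05"

    def test_deep_channel_wins_at_depth(self):
        models = [_model("ec_h05", 0.40), _model("ec_v10", 0.76)]
        assert select_best_channel(models) == "ec_v10"

    def test_tie_broken_by_shallow_preference(self):
        models = [_model("ec_v05", 0.8), _model("ec_h10", 0.8)]
        assert select_best_channel(models) == "ec_h10"

    def test_order_invariance(self):
        models = [_model("ec_v10", 0.7), _model("ec_h05", 0.9), _model("ec_v05", 0.8)]
        assert select_best_channel(models) == select_best_channel(models[::-1])

    def test_differing_sample_sets_raise(self):
        with pytest.raises(ValueError, match="differing"):
            select_best_channel([_model("ec_h05", 0.8, "a"), _model("ec_v05", 0.7, "b")])


class TestMoistureStratification:
    @pytest.mark.parametrize(
        "theta, label",
        [(0.05, "0-10%"), (0.10, "10-20%"), (0.1999, "10-20%"), (0.20, ">20%"), (0.5, ">20%")],
    )
    def test_boundaries_lower_closed(self, theta, label):
        assert moisture_gradient_label(theta) == label

    def test_partition_is_exhaustive_and_balanced(self, rng):
        samples = pd.DataFrame({"theta": rng.uniform(0, 0.3, 300), "ece_dsm": 0.5})
        groups = stratify_by_moisture(samples)
        sizes = {k: len(v) for k, v in groups.items()}
        assert sum(sizes.values()) == 300
        for size in sizes.values():
            assert 60 <= size <= 140  # ~100 expected under uniform theta

    def test_missing_theta_raises_with_rows(self):
        samples = pd.DataFrame({"theta": [0.1, np.nan, 0.2]})
        with pytest.raises(ValueError, match="rows"):
            stratify_by_moisture(samples)


class TestSplit:
    def test_conventional_twelve_six(self):
        m, v = split_modelling_validation(list(range(18)), 2 / 3, seed=0)
        assert len(m) == 12 and len(v) == 6
        assert sorted(m + v) == list(range(18))

    def test_three_groups(self):
        m, v = split_modelling_validation([1, 2, 3], 2 / 3, seed=0)
        assert len(m) == 2 and len(v) == 1

    def test_seed_determinism(self):
        assert split_modelling_validation(range(18), seed=5) == split_modelling_validation(
            range(18), seed=5
        )

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            split_modelling_validation(range(18), 1.5)

    def test_validation_spans_occupied_gradients(self):
        labels = {g: ("0-10%" if g < 3 else ">20%") for g in range(18)}
        for seed in range(10):
            _, v = split_modelling_validation(range(18), seed=seed, gradient_labels=labels)
            assert {labels[g] for g in v} == {"0-10%", ">20%"}


class TestPredictEce:
    def test_march_surface_model(self):
        a, b = FIELD_CALIBRATION[("March", (0, 20))]
        model = _model("ec_h05", 0.9)
        model = LayerInversionModel("March", (0, 20), "ec_h05", a, b, FitMetrics(0.9, 0.1, 18))
        assert predict_ece(model, 1.0) == pytest.approx(0.228, abs=1e-12)
        assert predict_ece(model, 0.0) == pytest.approx(a)

    def test_july_surface_model_crosses_zero_at_unit_eca(self):
        a, b = FIELD_CALIBRATION[("July", (0, 20))]
        model = LayerInversionModel("July", (0, 20), "ec_h05", a, b, FitMetrics(0.9, 0.1, 18))
        assert predict_ece(model, 1.0) == pytest.approx(0.0, abs=1e-12)


class TestEndToEndInversion:
    def test_fit_all_inversions_covers_every_period_layer(self, default_samples):
        survey = simulate_survey(default_samples, noise_sd=0.02, seed=1)
        models = fit_all_inversions(default_samples, survey)
        assert len(models) == 4 * 5
        assert set(models.channel).issubset({"ec_h05", "ec_h10", "ec_v05", "ec_v10"})

    def test_preset_selection_uses_depth_assignment(self, default_samples):
        survey = simulate_survey(default_samples, noise_sd=0.02, seed=1)
        models = fit_all_inversions(default_samples, survey, selection="preset")
        by_layer = models.groupby("layer_top_cm")["channel"].unique()
        assert list(by_layer[0]) == ["ec_h05"]
        assert list(by_layer[40]) == ["ec_v05"]
        assert list(by_layer[80]) == ["ec_v10"]

    def test_low_moisture_gradient_has_worst_r2(self):
        """Instrument noise grows in dry soil, so the 0-10% gradient fits worst."""
        r2 = {}
        for label, band in [("0-10%", (0.0, 0.10)), ("10-20%", (0.10, 0.20)), (">20%", (0.20, 0.30))]:
            cfg = ProfileConfig(n_sites=120, noise_sd=0.5, moisture_range=band, seed=7)
            samples = generate_profiles(cfg)
            sub = samples[(samples.period == "June") & (samples.layer_top_cm == 0)]
            survey = simulate_survey(
                samples, noise_sd=0.1, seed=11, moisture_noise_factor=dry_soil_noise_factor
            )
            sj = survey[survey.period == "June"].set_index("site_id")
            sub = sub.sort_values("site_id")
            eca = sj.loc[sub.site_id, "ec_h05"].to_numpy()
            model = fit_layer_inversion(eca, sub.ece_dsm.to_numpy(), "June", (0, 20), "ec_h05")
            r2[label] = model.metrics.r2
        assert r2["0-10%"] < r2["10-20%"] < r2[">20%"]
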