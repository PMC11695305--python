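import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltprofile.kalman import (
    M_RATIO_EPS,
    KFState,
    assimilate_series,
    evaluate_calibration,
    kf_init,
    kf_predict,
    kf_update,
)
from saltprofile.metrics import FitMetrics


def reference_matrix_kf(bg, obs, x0, p0, q, r):
    """Independent textbook Kalman filter in explicit matrix form.

    Uses 1x1 numpy matrices and the canonical forecast/gain/update
    equations; shares only the transition-scalar definition with the
    implementation under test.
    """
    bg = np.asarray(bg, float)
    prev = np.concatenate([[x0], bg[:-1]])
    m = np.where(np.abs(prev) > M_RATIO_EPS, bg / prev, 1.0)
    x = np.array([[x0]])
    P = np.array([[p0]])
    H = np.array([[1.0]])
    R = np.array([[r]])
    Q = np.array([[q]])
    I = np.eye(1)
    out = []
    for k in range(bg.size):
        M = np.array([[m[k]]])
        x = M @ x
        P = M @ P @ M.T + Q
        K = P @ H.T @ np.linalg.inv(H @ P @ H.T + R)
        x = x + K @ (np.array([[obs[k]]]) - H @ x)
        P = (I - K @ H) @ P
        out.append(float(x[0, 0]))
    return np.array(out)


class TestInit:
    @pytest.mark.parametrize(
        "samples, x_a, p_a",
        [
            ([0.5], 0.5, 0.0),
            ([0.4, 0.6], 0.5, 0.01),
            ([0.3, 0.5, 0.7], 0.5, 0.04),
        ],
    )
    def test_surface_layer_initialisation(self, samples, x_a, p_a):
        state = kf_init(samples)
        assert state.x_a == pytest.approx(x_a)
        assert state.p_a == pytest.approx(p_a)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kf_init([])


class TestPredict:
    def test_identity_propagation(self):
        state = KFState(x_a=0.5, p_a=0.02, q=0.0, r=0.01)
        assert kf_predict(state, 1.0) == (0.5, 0.02)

    def test_hand_substitution(self):
        state = KFState(x_a=3.0, p_a=1.0, q=0.5, r=0.01)
        assert kf_predict(state, 2.0) == (6.0, 4.5)

    def test_process_noise_inflates_variance(self):
        state = KFState(x_a=0.5, p_a=0.02, q=1e-3, r=0.01)
        _, p_f = kf_predict(state, 1.0)
        assert p_f > state.p_a


class TestUpdate:
    def test_hand_substitution(self):
        state = kf_update((1.0, 1.0), y_obs=3.0, h=1.0, r=1.0)
        assert state.k_gain == pytest.approx(0.5)
        assert state.x_a == pytest.approx(2.0)
        assert state.p_a == pytest.approx(0.5)

    def test_uninformative_observation(self):
        state = kf_update((1.0, 1.0), y_obs=3.0, h=1.0, r=1e12)
        assert state.k_gain == pytest.approx(0.0, abs=1e-9)
        assert state.x_a == pytest.approx(1.0, abs=1e-9)

    def test_perfect_observation(self):
        state = kf_update((1.0, 1.0), y_obs=3.0, h=1.0, r=0.0)
        assert state.x_a == pytest.approx(3.0)
        assert state.p_a == pytest.approx(0.0)

    def test_singular_update_raises(self):
        with pytest.raises(ZeroDivisionError):
            kf_update((1.0, 0.0), y_obs=3.0, h=1.0, r=0.0)

    def test_analysis_variance_never_exceeds_forecast(self, rng):
        for _ in range(50):
            p_f = rng.uniform(0, 1)
            r = rng.uniform(1e-6, 1)
            state = kf_update((0.5, p_f), y_obs=rng.normal(), h=1.0, r=r)
            assert state.p_a <= p_f + 1e-15
            assert 0.0 <= state.k_gain <= 1.0

    @given(
        p1=st.floats(1e-6, 10), p2=st.floats(1e-6, 10),
        r1=st.floats(1e-6, 10), r2=st.floats(1e-6, 10),
    )
    @settings(deadline=None, max_examples=100)
    def test_gain_monotonicity(self, p1, p2, r1, r2):
        """K grows with forecast variance and shrinks with observation noise."""
        lo_p, hi_p = sorted([p1, p2])
        lo_r, hi_r = sorted([r1, r2])
        k_lo = kf_update((0.0, lo_p), 1.0, 1.0, lo_r).k_gain
        assert kf_update((0.0, hi_p), 1.0, 1.0, lo_r).k_gain >= k_lo - 1e-12
        assert kf_update((0.0, lo_p), 1.0, 1.0, hi_r).k_gain <= k_lo + 1e-12


class TestAssimilateSeries:
    def _stream(self, seed=0, n=90):
        rng = np.random.default_rng(seed)
        true = np.tile([0.4, 0.5, 0.6, 0.8, 0.7], n // 5)
        obs = true + rng.normal(0, 0.05, n)
        bg = true + 0.1
        return bg, obs

    def test_matches_matrix_oracle(self):
        bg, obs = self._stream(3)
        state0 = kf_init(obs[::5], q=1e-4, r=2.5e-3)
        run = assimilate_series(bg, obs, state0)
        ref = reference_matrix_kf(bg, obs, state0.x_a, state0.p_a, state0.q, state0.r)
        assert np.max(np.abs(run.analyses - ref)) < 1e-10

    def test_zero_innovation_returns_background(self):
        bg, _ = self._stream(1)
        state0 = kf_init(bg[::5], q=1e-4, r=2.5e-3)
        run = assimilate_series(bg, bg.copy(), state0)
        assert np.allclose(run.analyses, bg, atol=1e-12)
        assert run.metrics_post.rmse == pytest.approx(run.metrics_pre.rmse, abs=1e-12)

    def test_huge_observation_noise_returns_background(self):
        bg, obs = self._stream(2)
        state0 = kf_init(obs[::5], q=1e-4, r=1e12)
        run = assimilate_series(bg, obs, state0)
        assert np.allclose(run.analyses, bg, atol=1e-6)

    def test_zero_observation_noise_returns_observations(self):
        bg, obs = self._stream(4)
        state0 = kf_init(obs[::5], q=1e-4, r=0.0)
        run = assimilate_series(bg, obs, state0)
        assert np.allclose(run.analyses, obs, atol=1e-12)

    def test_identity_mode_zero_innovation_also_exact(self):
        bg, _ = self._stream(5)
        state0 = kf_init(bg[::5], q=1e-4, r=2.5e-3)
        run = assimilate_series(bg, bg.copy(), state0, m_mode="identity")
        assert np.allclose(run.analyses, bg, atol=1e-12)

    def test_biased_background_improves(self):
        bg, obs = self._stream(6)
        state0 = kf_init(obs[::5], q=1e-4, r=2.5e-3)
        run = assimilate_series(bg, obs, state0)
        assert run.metrics_post.rmse < run.metrics_pre.rmse

    def test_length_mismatch_raises(self):
        state0 = kf_init([0.5])
        with pytest.raises(ValueError, match="length"):
            assimilate_series([1.0, 2.0], [1.0], state0)

    def test_non_finite_input_reports_index(self):
        state0 = kf_init([0.5])
        with pytest.raises(ValueError, match="indices \\[1\\]"):
            assimilate_series([1.0, np.nan, 1.0], [1.0, 1.0, 1.0], state0)


class TestEvaluateCalibration:
    def _metrics(self, r2):
        return FitMetrics(r2=r2, rmse=0.1, n=90)

    def test_boll_stage_worked_example(self):
        report = evaluate_calibration(self._metrics(0.32), self._metrics(0.58))
        assert report.delta_r2 == pytest.approx(0.26)
        assert report.growth_rate_pct == pytest.approx(81.3)

    def test_pre_sowing_worked_example(self):
        report = evaluate_calibration(self._metrics(0.78), self._metrics(0.79))
        assert report.delta_r2 == pytest.approx(0.01)

    def test_no_change(self):
        report = evaluate_calibration(self._metrics(0.5), self._metrics(0.5))
        assert report.delta_r2 == 0.0
        assert report.growth_rate_pct == 0.0

    def test_zero_pre_r2_growth_undefined(self):
        report = evaluate_calibration(self._metrics(0.0), self._metrics(0.5))
        assert report.growth_rate_pct is None

    def test_microsiemens_conversion_in_report(self):
        pre = FitMetrics(r2=0.5, rmse=0.09617, n=90)
        report = evaluate_calibration(pre, self._metrics(0.6)).as_dict()
        assert report["rmse_pre_uS_cm"] == pytest.approx(96.17)
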