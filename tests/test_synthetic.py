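"""Generator building blocks: BG profiles, kinetics, calibration, AR noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmdissect import (
    ARModel,
    GlucoseSeries,
    MealTestConfig,
    PopulationConfig,
    SessionConfig,
    apply_calibration,
    bg_to_ig,
    generate_bg_profile,
    generate_dataset,
    generate_session,
    simulate_ar,
)
from cgmdissect.noise import NonStationaryError, stationary_variance
from cgmdissect.synthetic import GenerationError, draw_session_truth

from conftest import CC_COEFFS, CC_STAT_VAR, CC_VAR, yule_walker_variance


class TestBGProfile:
    def test_zero_excursion_is_constant_basal(self):
        cfg = MealTestConfig(basal_mean=120.0, basal_sd=0.0, meal_amp_mean=0.0,
                             meal_amp_sd=0.0, dip_amp_mean=0.0, dip_amp_sd=0.0,
                             slow_var_amp=0.0, fast_var_amp=0.0)
        bg = generate_bg_profile(cfg, seed=0)
        np.testing.assert_allclose(bg.values, 120.0)
        assert bg.values.size == 481

    def test_deterministic_in_seed(self):
        cfg = MealTestConfig()
        a = generate_bg_profile(cfg, seed=5)
        b = generate_bg_profile(cfg, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nadir_floor_respected(self):
        cfg = MealTestConfig()
        for seed in range(50):
            assert generate_bg_profile(cfg, seed).values.min() >= cfg.floor

    def test_rejects_impossible_config(self):
        with pytest.raises(GenerationError):
            MealTestConfig(basal_mean=30.0)
        with pytest.raises(GenerationError):
            MealTestConfig(duration=-1.0)


class TestBGToIG:
    def test_tau_zero_is_identity(self):
        bg = GlucoseSeries(0.0, 1.0, 100 + 50 * np.sin(np.linspace(0, 6, 200)))
        np.testing.assert_array_equal(bg_to_ig(bg, 0.0).values, bg.values)

    @given(
        tau=st.floats(0.0, 100.0),
        dt=st.floats(0.1, 10.0),
        level=st.floats(40.0, 400.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_unit_steady_state_gain(self, tau, dt, level):
        """Constant input passes through unchanged for any tau and dt."""
        bg = GlucoseSeries(0.0, dt, np.full(50, level))
        np.testing.assert_allclose(bg_to_ig(bg, tau).values, level, rtol=1e-12)

    def test_step_response_closed_form(self):
        # step 100 -> 200 at t=0 with IG(0)=100: IG(tau) = 100 + 100(1 - 1/e)
        tau, dt = 20.0, 0.01
        values = np.full(int(3 * tau / dt), 200.0)
        values[0] = 100.0
        ig = bg_to_ig(GlucoseSeries(0.0, dt, values), tau)
        k = int(round(tau / dt))
        expected = 100.0 + 100.0 * (1 - np.exp(-1))
        assert ig.values[k] == pytest.approx(expected, abs=0.05)

    def test_negative_tau_rejected(self):
        bg = GlucoseSeries(0.0, 1.0, np.full(10, 100.0))
        with pytest.raises(GenerationError):
            bg_to_ig(bg, -1.0)


class TestApplyCalibration:
    def test_identity(self):
        ig = GlucoseSeries(0.0, 1.0, np.linspace(80, 200, 100))
        out = apply_calibration(ig, [1.0], [0.0])
        np.testing.assert_array_equal(out.values, ig.values)

    def test_constant_gain_offset_hand_value(self):
        # published mean a0/b0: 1.1 * 100 - 11.2 = 98.8
        ig = GlucoseSeries(0.0, 1.0, np.full(10, 100.0))
        out = apply_calibration(ig, [1.1], [-11.2])
        np.testing.assert_allclose(out.values, 98.8)

    def test_linear_gain_hand_value(self):
        # a(t) = 1 + 0.001 t at t = 100 -> gain 1.1 -> IGS = 110
        ig = GlucoseSeries(0.0, 1.0, np.full(200, 100.0))
        out = apply_calibration(ig, [1.0, 0.001], [0.0])
        assert out.values[100] == pytest.approx(110.0)

    def test_nonpositive_gain_rejected(self):
        ig = GlucoseSeries(0.0, 1.0, np.full(500, 100.0))
        with pytest.raises(GenerationError):
            apply_calibration(ig, [1.0, -0.01], [0.0])


class TestSimulateAR:
    def test_white_noise_variance(self):
        model = ARModel([0.0], 4.0)
        x = simulate_ar(model, 100_000, seed=3)
        assert np.var(x) == pytest.approx(4.0, rel=0.03)
        assert np.mean(x) == pytest.approx(0.0, abs=0.05)

    def test_ar3_matches_yule_walker_variance(self):
        model = ARModel(CC_COEFFS, CC_VAR)
        x = simulate_ar(model, 100_000, seed=4)
        gamma0 = yule_walker_variance(CC_COEFFS, CC_VAR)
        assert gamma0 == pytest.approx(CC_STAT_VAR, rel=1e-12)
        assert np.var(x) == pytest.approx(gamma0, rel=0.1)

    def test_sample_autocorrelations_match_yule_walker(self):
        model = ARModel(CC_COEFFS, CC_VAR)
        x = simulate_ar(model, 100_000, seed=5)
        c = CC_COEFFS
        A = np.eye(3)
        b = np.zeros(3)
        for k in range(1, 4):
            for j in range(1, 4):
                m = abs(k - j)
                if m == 0:
                    b[k - 1] += c[j - 1]
                else:
                    A[k - 1, m - 1] -= c[j - 1]
        rho = np.linalg.solve(A, b)
        x0 = x - x.mean()
        for lag in (1, 2, 3):
            r = np.dot(x0[:-lag], x0[lag:]) / (x.size * x0.var())
            # 3 asymptotic standard errors at N = 1e5
            assert abs(r - rho[lag - 1]) < 3 * 5 / np.sqrt(x.size)

    def test_unit_root_rejected(self):
        with pytest.raises(NonStationaryError):
            simulate_ar(ARModel([1.0], 1.0), 100, seed=0)

    def test_deterministic(self):
        model = ARModel(CC_COEFFS, CC_VAR)
        np.testing.assert_array_equal(
            simulate_ar(model, 500, seed=9), simulate_ar(model, 500, seed=9)
        )

    def test_stationary_variance_helper_agrees_with_oracle(self):
        model = ARModel(CC_COEFFS, CC_VAR)
        assert stationary_variance(model) == pytest.approx(CC_STAT_VAR, rel=1e-12)


class TestGenerateSession:
    def test_all_error_sources_off_reproduces_bg(self, quiet_truth):
        cfg = SessionConfig()
        sess = generate_session(quiet_truth, cfg, seed=21)
        # regenerate the BG profile from the same substream to compare
        rng = np.random.default_rng(21)
        bg = generate_bg_profile(cfg.meal, rng)
        idx = np.arange(0, bg.values.size, int(cfg.cgm_dt / bg.dt))
        for trace in sess.cgm:
            np.testing.assert_allclose(trace.values, bg.values[idx], atol=1e-8)

    def test_composition_identity_with_zero_noise(self, quiet_truth):
        """CGM_i - [a_i(t) IG(t) + b_i(t)] = 0 when noise is off."""
        from cgmdissect.synthetic import SensorTruth, SessionTruth

        tiny = ARModel([0.0], 1e-20)
        truth = SessionTruth(
            9.4, [SensorTruth([1.1, -0.0009], [-11.2, 0.09], tiny) for _ in range(2)], tiny
        )
        cfg = SessionConfig()
        sess = generate_session(truth, cfg, seed=22)
        rng = np.random.default_rng(22)
        bg = generate_bg_profile(cfg.meal, rng)
        ig = bg_to_ig(bg, truth.tau)
        idx = np.arange(0, bg.values.size, int(cfg.cgm_dt / bg.dt))
        t = ig.times[idx]
        for trace, sensor in zip(sess.cgm, truth.sensors):
            pred = (
                np.polynomial.polynomial.polyval(t, sensor.gain_coeffs) * ig.values[idx]
                + np.polynomial.polynomial.polyval(t, sensor.offset_coeffs)
            )
            np.testing.assert_allclose(trace.values, pred, atol=1e-7)

    def test_same_seed_identical(self, mean_truth):
        a = generate_session(mean_truth, SessionConfig(), seed=7)
        b = generate_session(mean_truth, SessionConfig(), seed=7)
        for x, y in zip(a.cgm, b.cgm):
            np.testing.assert_array_equal(x.values, y.values)
        np.testing.assert_array_equal(a.reference.values, b.reference.values)

    def test_reference_gap_window(self, noisy_session):
        gaps = np.diff(noisy_session.reference.times)
        assert gaps.min() >= 9.0  # 10 +/- rounding to whole minutes
        assert gaps.max() <= 21.0

    def test_single_sensor_rejected(self):
        from cgmdissect.synthetic import SensorTruth, SessionTruth

        truth = SessionTruth(9.4, [SensorTruth([1.0], [0.0])])
        with pytest.raises(GenerationError):
            generate_session(truth, SessionConfig(), seed=0)


class TestGenerateDataset:
    def test_empty(self):
        assert generate_dataset(PopulationConfig(), 0, seed=0) == []

    def test_degenerate_population_shares_truth(self, fixed_population):
        sessions = generate_dataset(fixed_population, 3, seed=5)
        taus = {s.truth.tau for s in sessions}
        assert taus == {9.4}
        for s in sessions:
            np.testing.assert_array_equal(s.truth.sensors[0].gain_coeffs, [1.1, -0.0009])

    def test_population_means_recovered(self):
        """Law of large numbers on the drawn truths."""
        pop = PopulationConfig()
        rng = np.random.default_rng(17)
        draws = [draw_session_truth(pop, rng) for _ in range(10_000)]
        taus = np.array([d.tau for d in draws])
        a0 = np.array([s.gain_coeffs[0] for d in draws for s in d.sensors])
        b0 = np.array([s.offset_coeffs[0] for d in draws for s in d.sensors])
        # tau is resampled-to-positive: the oracle is the zero-truncated
        # normal mean mu + sigma phi(a)/(1 - Phi(a)), a = -mu/sigma
        from scipy.stats import norm

        a = -9.4 / 6.5
        trunc_mean = 9.4 + 6.5 * norm.pdf(a) / (1 - norm.cdf(a))
        assert taus.mean() == pytest.approx(trunc_mean, abs=0.3)
        assert taus.min() > 0
        # gain draws are rejection-sampled to keep a(t) positive over the
        # horizon; reproduce that truncation independently as the oracle
        rng2 = np.random.default_rng(99)
        acc = []
        grid = np.linspace(0, 480.0, 50)
        while len(acc) < 20_000:
            g0 = rng2.normal(1.1, 0.4)
            g1 = rng2.normal(-0.0009, 0.0016)
            if np.all(g0 + g1 * grid > 0.05):
                acc.append(g0)
        assert a0.mean() == pytest.approx(np.mean(acc), abs=0.02)
        assert b0.mean() == pytest.approx(-11.2, abs=1.5)  # offsets untruncated

    def test_invalid_population_rejected(self):
        with pytest.raises(GenerationError):
            PopulationConfig(tau_sd=-1.0)
        with pytest.raises(GenerationError):
            PopulationConfig(n_sensors=1)
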