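"""Noise decomposition and AR process estimation."""

import numpy as np
import pytest

from cgmdissect import (
    ARModel,
    decompose_noise,
    fit_ar,
    fit_population_ar,
    select_ar_order,
    simulate_ar,
    stationary_variance,
    validate_ar,
    variance_summary,
)
from cgmdissect.noise import ARError, prediction_errors

from conftest import (
    CC_COEFFS,
    CC_STAT_VAR,
    CC_VAR,
    SSC_COEFFS,
    SSC_STAT_VAR,
    SSC_VAR,
    yule_walker_variance,
)

CC = ARModel(CC_COEFFS, CC_VAR)
SSC = ARModel(SSC_COEFFS, SSC_VAR)


class TestDecompose:
    def test_identical_series_gives_zero_ssc(self):
        x = np.sin(np.linspace(0, 10, 100))
        d = decompose_noise([x, x.copy()])
        np.testing.assert_array_equal(d.cc, x)
        for s in d.ssc:
            np.testing.assert_allclose(s, 0.0)

    def test_antisymmetric_series(self):
        x = np.sin(np.linspace(0, 10, 100))
        d = decompose_noise([x, -x])
        np.testing.assert_allclose(d.cc, 0.0, atol=1e-15)
        np.testing.assert_allclose(d.ssc[0], x)
        np.testing.assert_allclose(d.ssc[1], -x)

    def test_exact_reconstruction_and_zero_sum(self):
        rng = np.random.default_rng(7)
        res = [rng.normal(0, 5, 500) for _ in range(3)]
        d = decompose_noise(res)
        for r, s in zip(res, d.ssc):
            np.testing.assert_allclose(d.cc + s, r, rtol=0, atol=1e-12)
        np.testing.assert_allclose(np.sum(d.ssc, axis=0), 0.0, atol=1e-12)

    def test_recovers_generative_components(self):
        """With n=2, cc_hat = cc + (ssc1+ssc2)/2; correlation with the true
        cc follows from the variance ratio."""
        n = 20_000
        cc = simulate_ar(CC, n, seed=8)
        ssc = [simulate_ar(SSC, n, seed=9), simulate_ar(SSC, n, seed=10)]
        res = [cc + s for s in ssc]
        d = decompose_noise(res)
        rho = np.corrcoef(d.cc, cc)[0, 1]
        # variance arithmetic: rho = sqrt(var_cc / (var_cc + var_ssc/2))
        # = 0.881 at the long-run Yule-Walker variances of the two processes
        expected = np.sqrt(CC_STAT_VAR / (CC_STAT_VAR + SSC_STAT_VAR / 2))
        assert rho == pytest.approx(expected, abs=0.03)
        assert rho > 0.85

    def test_misaligned_rejected(self):
        with pytest.raises(ARError):
            decompose_noise([np.zeros(10), np.zeros(11)])
        with pytest.raises(ARError):
            decompose_noise([np.zeros(10)])


class TestFitAR:
    def test_population_cc_coefficients_recovered(self):
        x = simulate_ar(CC, 100_000, seed=11)
        model = fit_ar(x, 3)
        se = 1.0 / np.sqrt(x.size)  # coefficient SEs are O(1/sqrt(N))
        assert abs(model.coeffs[0] - 1.584) < 3 * 5 * se
        assert model.innovation_var == pytest.approx(3.98, rel=0.03)

    def test_white_noise_null_recovery(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 50_000)
        model = fit_ar(x, 2)
        assert np.all(np.abs(model.coeffs) < 3 / np.sqrt(x.size))

    def test_consistency_error_shrinks_as_sqrt_n(self):
        errs = []
        for n in (1_000, 10_000, 100_000):
            x = simulate_ar(SSC, n, seed=13)
            model = fit_ar(x, 2)
            errs.append(np.linalg.norm(model.coeffs - SSC_COEFFS))
        assert errs[0] > errs[2]
        # roughly 1/sqrt(N): two decades of N give about one decade of error
        assert errs[2] < errs[0] / 3

    def test_simulate_fit_simulate_spectral_closure(self):
        """Spectra of the original and refitted processes agree."""
        from scipy.signal import welch

        x = simulate_ar(CC, 60_000, seed=14)
        refit = fit_ar(x, 3)
        y = simulate_ar(refit, 60_000, seed=15)
        f1, p1 = welch(x, nperseg=1024)
        f2, p2 = welch(y, nperseg=1024)
        ratio = p2 / p1
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)
        assert np.all((ratio > 0.5) & (ratio < 2.0))

    def test_short_series_rejected(self):
        with pytest.raises(ARError):
            fit_ar(np.arange(25.0), 3)


class TestSelectOrder:
    def test_modal_order_three_for_cc_process(self):
        series = [simulate_ar(CC, 5_000, seed=100 + i) for i in range(12)]
        sel = select_ar_order(series, k_max=15)
        assert sel.modal_order == 3

    def test_modal_order_two_for_ssc_process(self):
        series = [simulate_ar(SSC, 5_000, seed=200 + i) for i in range(12)]
        sel = select_ar_order(series, k_max=15)
        assert sel.modal_order == 2

    def test_white_noise_selects_smallest_order(self):
        rng = np.random.default_rng(16)
        series = [rng.normal(0, 1, 3_000) for _ in range(10)]
        sel = select_ar_order(series, k_max=15)
        assert sel.modal_order == 1

    def test_empty_rejected(self):
        with pytest.raises(ARError):
            select_ar_order([])


class TestValidateAR:
    def test_nominal_pass_rate_on_gaussian_innovations(self):
        passed = 0
        n_series = 100
        for i in range(n_series):
            x = simulate_ar(CC, 600, seed=300 + i)
            model = fit_ar(x, 3)
            passed += validate_ar(model, x).passed
        # 5% test size: ~95% pass, binomial 3 sigma ~ 6.5 points
        assert 88 <= passed <= 100

    def test_heavy_tailed_innovations_fail_more(self):
        rng = np.random.default_rng(17)
        failed = 0
        n_series = 50
        for i in range(n_series):
            w = rng.standard_t(3, size=1_100) * np.sqrt(SSC_VAR)
            x = np.zeros(1_100)
            for t in range(2, 1_100):
                x[t] = SSC_COEFFS @ x[t - 2 : t][::-1] + w[t]
            x = x[100:]
            model = fit_ar(x, 2)
            failed += not validate_ar(model, x).passed
        assert failed / n_series > 0.5

    def test_too_short_rejected(self):
        with pytest.raises(ARError):
            validate_ar(ARModel([0.5], 1.0), np.arange(5.0))


class TestPopulationAR:
    def test_single_series_equals_fit_ar(self):
        x = simulate_ar(SSC, 3_000, seed=18)
        single = fit_ar(x, 2)
        pooled = fit_population_ar([x], 2)
        np.testing.assert_allclose(pooled.coeffs, single.coeffs)
        assert pooled.innovation_var == pytest.approx(single.innovation_var)

    def test_pooled_recovery_from_session_scale_series(self):
        """37 short cc series pooled: coefficients within 3 SE of truth."""
        series = [simulate_ar(CC, 97, seed=400 + i) for i in range(37)]
        pooled = fit_population_ar(series, 3)
        n_rows = pooled.fitted_on
        se = 5 / np.sqrt(n_rows)
        for est, true in zip(pooled.coeffs, CC_COEFFS):
            assert abs(est - true) < 3 * se

    def test_two_different_models_pool_between(self):
        a = ARModel([0.8], 1.0)
        b = ARModel([0.2], 1.0)
        xs = [simulate_ar(a, 20_000, seed=19), simulate_ar(b, 20_000, seed=20)]
        pooled = fit_population_ar(xs, 1)
        assert 0.2 < pooled.coeffs[0] < 0.8

    def test_boundary_rows_excluded(self):
        """Pooling must not create regression rows across series."""
        x1 = np.concatenate([np.zeros(40), [100.0]])  # big jump at the end
        rng = np.random.default_rng(21)
        x2 = rng.normal(0, 1, 41)
        pooled = fit_population_ar([x1 + rng.normal(0, 1, 41), x2], 2)
        # rows used: (41-2) per series
        assert pooled.fitted_on == 2 * 39


class TestVarianceSummary:
    def test_all_zero_decomposition_medians(self):
        from cgmdissect.noise import NoiseDecomposition

        d = NoiseDecomposition(np.zeros(50), [np.zeros(50), np.zeros(50)], "s1")
        table = variance_summary([d])
        assert table.attrs["median_cc_variance"] == 0.0
        assert table.attrs["median_ssc_variance"] == 0.0

    def test_cc_variance_exceeds_ssc_variance_at_population_truth(self):
        decomps = []
        for i in range(20):
            cc = simulate_ar(CC, 97, seed=500 + i)
            ssc = [simulate_ar(SSC, 97, seed=600 + i), simulate_ar(SSC, 97, seed=700 + i)]
            decomps.append(decompose_noise([cc + s for s in ssc], f"s{i}"))
        table = variance_summary(decomps)
        assert table.attrs["median_cc_variance"] > table.attrs["median_ssc_variance"]
        assert table.attrs["ranksum_p"] < 0.05


class TestStationaryVariance:
    def test_matches_hand_solved_yule_walker(self):
        assert stationary_variance(CC) == pytest.approx(
            yule_walker_variance(CC_COEFFS, CC_VAR), rel=1e-12
        )
        assert stationary_variance(SSC) == pytest.approx(SSC_STAT_VAR, rel=1e-12)

    def test_prediction_errors_of_true_model_are_innovations(self):
        x = simulate_ar(SSC, 50_000, seed=22)
        e = prediction_errors(SSC, x)
        assert np.var(e) == pytest.approx(SSC_VAR, rel=0.05)
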