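"""Coding efficiency, prediction, correlation summaries, AIC comparison."""

import numpy as np
import pytest
from scipy.stats import kurtosis

from argsm.ar import ARParams, yule_walker_autocov
from argsm.dynamic import (
    ARGSMParams,
    constant_z_loglik,
    fit_variant,
    simulate_argsm,
)
from argsm.analytics import (
    aic_dynamic,
    argsm_marginal_loglik,
    channel_capacity,
    correlation_time,
    efficiency_curve,
    forecast,
    gsm_channel_mutual_info,
    lagged_magnitude_correlation,
    pooled_kurtosis,
    prediction_r2,
)


def ar1_params(phi_y, sd_y, phi_z, noise_z, k=1):
    pad = lambda p: np.array([p] + [0.0] * (k - 1))
    return ARGSMParams(
        y1=ARParams(k, pad(phi_y), sd_y**2 * (1 - phi_y**2)),
        y2=ARParams(k, pad(phi_y), sd_y**2 * (1 - phi_y**2)),
        z=ARParams(k, pad(phi_z), noise_z),
    )


class TestCapacity:
    @pytest.mark.parametrize(
        "snr, expected", [(0.0, 0.0), (np.e - 1, 0.5), (1.0, 0.5 * np.log(2))]
    )
    def test_values(self, snr, expected):
        assert np.isclose(channel_capacity(snr), expected)

    def test_negative_snr_rejected(self):
        with pytest.raises(ValueError):
            channel_capacity(-0.1)


class TestMutualInfo:
    def test_gaussian_signal_achieves_capacity(self):
        for snr in (0.1, 1.0, 10.0):
            I = gsm_channel_mutual_info(np.sqrt(snr), 0.0, 1.0)
            assert abs(I - channel_capacity(snr)) < 1e-6

    def test_vanishes_at_high_noise(self):
        assert gsm_channel_mutual_info(1.0, 0.5, 1e6) < 1e-5

    def test_matches_monte_carlo_entropy(self):
        """Brute-force oracle: fine-histogram entropy of simulated channel
        outputs."""
        sy, sz, nv = 1.0, 0.5, 1.0
        rng = np.random.default_rng(0)
        n = 4 * 10**6
        x = rng.standard_normal(n) * np.exp(rng.normal(scale=sz, size=n)) * sy
        xh = x + rng.normal(scale=np.sqrt(nv), size=n)
        lim = 40 * np.std(xh)
        h, edges = np.histogram(xh, bins=np.linspace(-lim, lim, 4001), density=True)
        w = np.diff(edges)
        mask = h > 0
        H_mc = -np.sum(h[mask] * np.log(h[mask]) * w[mask])
        I_mc = H_mc - 0.5 * np.log(2 * np.pi * np.e * nv)
        I = gsm_channel_mutual_info(sy, sz, nv)
        assert abs(I - I_mc) < 0.01

    def test_nondecreasing_in_snr(self):
        grid = np.linspace(-4, 6, 21)
        c = efficiency_curve(0.5, grid)
        assert np.all(np.diff(c.mutual_info) > -1e-9)


class TestEfficiency:
    def test_unity_without_scale_fluctuations(self):
        c = efficiency_curve(0.0, np.linspace(-4, 6, 11))
        assert np.allclose(c.efficiency, 1.0, atol=1e-6)

    def test_approaches_unity_at_extremes(self):
        for sz in (0.3, 0.6):
            c = efficiency_curve(sz, np.array([-4.0, 6.0]))
            assert np.all(c.efficiency > 0.95)

    def test_monotone_decreasing_in_sigma_z(self):
        es = [efficiency_curve(s, [1.5]).efficiency[0] for s in (0.0, 0.2, 0.4, 0.6)]
        assert np.all(np.diff(es) < 0)

    def test_capacity_column_exact(self):
        grid = np.linspace(-2, 2, 5)
        c = efficiency_curve(0.3, grid)
        assert np.allclose(c.capacity, 0.5 * np.log1p(np.exp(grid)))

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            efficiency_curve(0.3, [0.0], mode="bogus")


class TestPredictionR2:
    def test_closed_form_no_scale_noise(self):
        p = ar1_params(0.9, 1.0, 0.0, 1e-12)
        r = prediction_r2(p)
        assert np.isclose(r.r2_y, 0.81, atol=1e-6)
        assert np.isclose(r.r2_x_given_z, 0.81, atol=1e-4)

    def test_closed_form_bracket(self):
        p = ar1_params(0.9487, 1.0, 0.8, 0.02)  # r2_y ~ 0.9
        r = prediction_r2(p)
        expected = r.r2_y * (2 * np.exp(0.01) - np.exp(0.04))
        assert np.isclose(r.r2_x_given_z, expected)

    @staticmethod
    def one_step_r2(params, N=20_000, T=32, seed=0):
        """Monte-Carlo plug-in forecast xhat = yhat exp(zhat) from the true
        latent histories, pooled over both components."""
        ens, lat = simulate_argsm(params, N=N, T=T, seed=seed)
        k = params.order
        y = ens.velocities / lat.s_hat[:, :, None]
        num = 0.0
        den = 0.0
        for c, py in ((0, params.y1), (1, params.y2)):
            yh = sum(
                py.phi[i] * y[:, k - 1 - i : T - 1 - i, c] for i in range(k)
            )
            zh = sum(
                params.z.phi[i] * lat.z_hat[:, k - 1 - i : T - 1 - i]
                for i in range(k)
            )
            xh = yh * np.exp(zh)
            x = ens.velocities[:, k:, c]
            num += np.mean((x - xh) ** 2)
            den += np.mean(x**2)
        return 1.0 - num / den

    def test_monte_carlo_matches_formula(self):
        p = ar1_params(0.9, 1.0, 0.9, 0.02)
        r = prediction_r2(p)
        mc = self.one_step_r2(p)
        assert abs(mc - r.r2_x_given_z) < 0.02

    def test_independent_of_sigma_z(self):
        """Same innovation variance, different stationary scale variance."""
        p_hi = ar1_params(0.9, 1.0, 0.9, 0.02)  # var_Z = 0.105
        p_lo = ar1_params(0.9, 1.0, 0.3, 0.02)  # var_Z = 0.022
        r_hi = prediction_r2(p_hi)
        r_lo = prediction_r2(p_lo)
        assert np.isclose(r_hi.r2_x_given_z, r_lo.r2_x_given_z)
        assert abs(self.one_step_r2(p_hi, seed=1) - self.one_step_r2(p_lo, seed=2)) < 0.02

    def test_naive_r2_from_ensemble(self):
        p = ar1_params(0.9, 1.0, 0.8, 0.02)
        ens, _ = simulate_argsm(p, N=2000, T=32, seed=3)
        r = prediction_r2(p, ensemble=ens)
        assert r.r2_x_naive is not None
        assert 0 < r.r2_x_naive <= r.r2_x_given_z + 0.05


class TestForecast:
    def test_zero_history_gives_zero_forecast(self):
        p = ar1_params(0.8, 1.0, 0.5, 0.01)
        f = forecast(p, np.zeros((4, 2)), np.zeros(4), 5)
        assert np.all(f["velocity"] == 0) and np.all(f["displacement"] == 0)

    def test_ar1_recursion(self):
        p = ar1_params(0.8, 1.0, 0.0, 1e-12)
        f = forecast(p, np.array([[1.0, 0.0]]), np.array([0.0]), 3)
        assert np.allclose(f["velocity"][:, 0], [0.8, 0.64, 0.512])
        assert np.isclose(f["displacement"][0], 1.952)

    def test_history_too_short_rejected(self):
        p = ar1_params(0.8, 1.0, 0.5, 0.01, k=3)
        with pytest.raises(ValueError):
            forecast(p, np.zeros((2, 2)), np.zeros(2), 1)

    def test_one_step_interval_coverage(self):
        """±1.96 predictive sd intervals from the scale-aware predictive
        variance must cover ~95% of one-step outcomes."""
        p = ar1_params(0.9, 1.0, 0.9, 0.005)
        ens, lat = simulate_argsm(p, N=40_000, T=8, seed=4)
        y = ens.velocities / lat.s_hat[:, :, None]
        phi = p.y1.phi[0]
        phiz = p.z.phi[0]
        yh = phi * y[:, -2, 0]
        zh = phiz * lat.z_hat[:, -2]
        xh = yh * np.exp(zh)
        sd = np.sqrt(p.y1.noise_var) * np.exp(zh)
        x = ens.velocities[:, -1, 0]
        cover = np.mean(np.abs(x - xh) < 1.96 * sd)
        assert abs(cover - 0.95) < 0.01

    def test_forecast_consistent_with_manual_recursion(self):
        p = ar1_params(0.9, 1.0, 0.8, 0.02, k=2)
        rng = np.random.default_rng(5)
        xh = rng.standard_normal((6, 2))
        zh = 0.1 * rng.standard_normal(6)
        f = forecast(p, xh, zh, 2)
        y = xh / np.exp(zh)[:, None]
        z1 = p.z.phi @ zh[::-1][:2]
        y1 = p.y1.phi @ y[::-1][:2, 0]
        assert np.isclose(f["z"][0], z1)
        assert np.isclose(f["velocity"][0, 0], y1 * np.exp(z1))
        assert np.allclose(f["predictive_var"][0, 0], p.y1.noise_var * np.exp(2 * z1))


class TestCorrelationTime:
    @pytest.mark.parametrize(
        "acf, expected",
        [
            (ARParams(1, np.array([0.5]), 1.0).autocorr(10), 1.0),
            (np.array([1.0, 0.0, 0.0]), 0.5),
            (ARParams(1, np.array([0.9]), 1.0).autocorr(30), 6.5916),
        ],
    )
    def test_values(self, acf, expected):
        t, crossed = correlation_time(acf)
        assert crossed
        assert abs(t - expected) < 1e-3

    def test_dt_and_rescale_invariance(self):
        g = yule_walker_autocov(ARParams(1, np.array([0.8]), 2.0), 20)
        t1, _ = correlation_time(g, dt=1 / 60)
        t2, _ = correlation_time(5.0 * g, dt=1 / 60)
        assert np.isclose(t1, t2)
        t3, _ = correlation_time(g, dt=1.0)
        assert np.isclose(t3, t1 * 60)

    def test_flagged_when_never_crossing(self):
        t, crossed = correlation_time(np.array([1.0, 0.95, 0.9]))
        assert not crossed and t == 2.0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_time(np.array([0.0, 0.0]))


class TestLaggedMagnitudeCorrelation:
    def test_white_independent_components_near_zero(self):
        from argsm.dynamic import TrajectoryEnsemble

        vel = np.random.default_rng(6).standard_normal((2000, 32, 2))
        c = lagged_magnitude_correlation(TrajectoryEnsemble(vel), 8)
        assert np.abs(c).max() < 0.02

    def test_constant_scale_gives_flat_positive_curve(self):
        p = ar1_params(0.0, 1.0, 0.999, 0.25 * (1 - 0.999**2))
        ens, _ = simulate_argsm(p, N=4000, T=32, seed=7)
        c = lagged_magnitude_correlation(ens, 8)
        assert np.all(c > 0.1)
        assert c.max() - c.min() < 0.05

    def test_dynamic_scale_gives_decreasing_curve(self):
        p = ar1_params(0.0, 1.0, 0.9, 0.36 * (1 - 0.81))
        ens, _ = simulate_argsm(p, N=8000, T=64, seed=8)
        c = lagged_magnitude_correlation(ens, 8)
        assert np.all(np.diff(c) < 0)

    def test_max_lag_validated(self):
        from argsm.dynamic import TrajectoryEnsemble

        with pytest.raises(ValueError):
            lagged_magnitude_correlation(
                TrajectoryEnsemble(np.ones((2, 8, 2))), 8
            )


class TestPooledKurtosis:
    def test_gaussian(self):
        x = np.random.default_rng(9).standard_normal((10**6, 2))
        assert abs(pooled_kurtosis(x) - 3.0) < 0.05

    def test_laplace(self):
        x = np.random.default_rng(10).laplace(size=(10**6, 2))
        assert abs(pooled_kurtosis(x) - 6.0) < 0.15

    def test_gsm(self):
        from argsm.gsm import GSMParams, sample_gsm

        x = sample_gsm(GSMParams(1.0, 0.3, 0.5), 10**6, seed=11)
        assert abs(pooled_kurtosis(x) - 3 * np.exp(0.36)) < 0.1

    def test_anisotropy_does_not_inflate(self):
        x = np.random.default_rng(12).standard_normal((10**5, 2)) * [1.0, 10.0]
        assert abs(pooled_kurtosis(x) - 3.0) < 0.1


class TestAICDynamic:
    @pytest.fixture(scope="class")
    def heavy_fits(self):
        p = ar1_params(0.9, 1.0, 0.85, 0.25 * (1 - 0.85**2))
        ens, _ = simulate_argsm(p, N=256, T=32, seed=13)
        return ens, {
            "full": fit_variant(ens, "full", k=1, alpha=100, iterations=200, seed=14),
            "constant_z": fit_variant(ens, "constant_z", k=1),
            "ar_only": fit_variant(ens, "ar_only", k=1),
        }

    def test_full_model_wins_on_heavy_tailed_data(self, heavy_fits):
        ens, fits = heavy_fits
        table = aic_dynamic(ens, fits, seed=15).set_index("model")
        assert table["aic"].idxmin() == "full"
        assert table.loc["full", "aic"] < table.loc["constant_z", "aic"]
        assert table.loc["constant_z", "aic"] < table.loc["ar_only", "aic"]

    def test_ar_only_wins_on_gaussian_data(self):
        p = ar1_params(0.8, 1.0, 0.0, 1e-8)
        ens, _ = simulate_argsm(p, N=256, T=32, seed=16)
        fits = {
            "full": fit_variant(ens, "full", k=1, alpha=50, iterations=100, seed=17),
            "ar_only": fit_variant(ens, "ar_only", k=1),
        }
        table = aic_dynamic(ens, fits, seed=18).set_index("model")
        se = max(table.loc["full", "loglik_se"], 1.0)
        assert table.loc["ar_only", "aic"] <= table.loc["full", "aic"] + 3 * se + 5

    def test_constant_z_likelihood_degenerates_to_ar(self):
        p = ar1_params(0.8, 1.0, 0.0, 1e-8)
        ens, _ = simulate_argsm(p, N=128, T=32, seed=19)
        ar_fit = fit_variant(ens, "ar_only", k=1)
        ll = constant_z_loglik(
            ens, ar_fit.params["y1"], ar_fit.params["y2"], 1e-8
        )
        assert abs(ll - ar_fit.loglik) < 1e-3

    def test_importance_sampler_tracks_tractable_limit(self):
        """On (nearly) degenerate-scale data with a tiny-scale model, the
        IS marginal likelihood must agree with the exact AR likelihood."""
        p = ar1_params(0.8, 1.0, 0.0, 1e-6)
        ens, _ = simulate_argsm(p, N=64, T=16, seed=20)
        ar_fit = fit_variant(ens, "ar_only", k=1)
        model = ARGSMParams(
            y1=ar_fit.params["y1"], y2=ar_fit.params["y2"],
            z=ARParams(1, np.array([0.0]), 1e-6),
        )
        ll, se, ess = argsm_marginal_loglik(ens, model, n_samples=256, seed=21)
        assert abs(ll - ar_fit.loglik) < max(3 * se, 1.0)
        assert ess > 50
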