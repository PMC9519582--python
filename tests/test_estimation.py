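"""UKF estimation, Morris screening, and agreement statistics."""

import numpy as np
import pandas as pd
import pytest

from stromasim.cell_models import CellModelSpec
from stromasim.estimation import (
    FilterConfig,
    bland_altman,
    goodness_of_fit,
    hukf_estimate,
    morris_screening,
    sigma_points,
)
from stromasim.reaction_network import (
    RateLaw,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
)
from stromasim.synthetic_data import generate_timecourse, perturbed_truth


def linear_decay_spec(a=0.3, x0=2.0):
    net = ReactionNetwork(
        [SpeciesSpec("x", "internal", x0)],
        [Reaction("deg", RateLaw("mass_action", "a", {"x": 1}), {"x": -1})],
        {"a": a},
    )
    return CellModelSpec("lin", net, {"X": "x"}, [], {})


class TestSigmaPoints:
    def test_scalar_closed_form(self):
        cfg = FilterConfig(alpha=0.5, kappa=0.0)
        pts, wm, wc = sigma_points(np.array([0.0]), np.array([[1.0]]), cfg)
        lam = 0.5**2 * 1 - 1
        spread = np.sqrt(1 + lam)
        np.testing.assert_allclose(sorted(pts[:, 0]), [-spread, 0.0, spread])
        assert wm.sum() == pytest.approx(1.0)

    def test_moments_reconstructed_exactly(self, rng):
        A = rng.normal(size=(5, 5))
        P = A @ A.T + 0.5 * np.eye(5)
        m = rng.normal(size=5)
        pts, wm, wc = sigma_points(m, P, FilterConfig())
        np.testing.assert_allclose(wm @ pts, m, atol=1e-10)
        d = pts - m
        np.testing.assert_allclose((d.T * wc) @ d, P, atol=1e-10)

    def test_non_psd_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            sigma_points(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]),
                         FilterConfig())


class TestHUKF:
    def test_matches_discrete_kalman_filter_on_linear_system(self):
        """On a 1-D linear-Gaussian system the continuous-discrete UKF must
        coincide with the exactly discretized Kalman filter."""
        a, x0 = 0.3, 2.0
        spec = linear_decay_spec(a, x0)
        times = [0.0, 1.0, 2.0, 3.0, 4.0]
        rng = np.random.default_rng(42)
        y = x0 * np.exp(-a * np.array(times)) + rng.normal(0, 0.05, len(times))
        obs = pd.DataFrame([y], index=["X"], columns=times)
        q, r, p0 = 1e-4, 0.05**2, 0.1
        cfg = FilterConfig(free_parameters=[], fold_change=False, n_passes=1,
                           process_noise_state=q, measurement_noise=r,
                           init_state_var=p0)
        res = hukf_estimate(spec, obs, cfg)

        F = np.exp(-a)
        m, P = x0, p0
        kf = [m]
        for k in range(1, len(times)):
            m, P = F * m, F * P * F + q
            K = P / (P + r)
            m, P = m + K * (y[k] - m), (1 - K) * P
            kf.append(m)
        np.testing.assert_allclose(res.filtered_means[:, 0], kf, atol=1e-6)

    def test_truth_is_a_fixed_point_of_the_correction(self, cancer_spec):
        """Noise-free self-generated data with the filter initialized at the
        true parameters leaves the parameters essentially unchanged."""
        free = ["k8p", "k9p"]
        obs = generate_timecourse(cancer_spec, noise_sd=0.0)
        cfg = FilterConfig(free_parameters=free, n_passes=3,
                           measurement_noise=1e-12,
                           process_noise_state=1e-12, process_noise_param=1e-12,
                           init_state_var=1e-6,
                           ode_rtol=1e-10, ode_atol=1e-12)
        res = hukf_estimate(cancer_spec, obs.values, cfg)
        for p in free:
            truth = cancer_spec.network.parameters[p]
            assert abs(res.estimated_parameters[p] - truth) / truth <= 1e-6

    def test_estimates_are_strictly_positive(self, cancer_spec):
        free = ["k8p", "k8m", "k9p"]
        obs = generate_timecourse(cancer_spec, noise_sd=0.05, seed=3)
        start = perturbed_truth(cancer_spec, free, (0.5, 2.0), seed=4)
        cfg = FilterConfig(free_parameters=free, n_passes=2,
                           measurement_noise=0.05**2,
                           ode_rtol=1e-6, ode_atol=1e-9)
        res = hukf_estimate(cancer_spec, obs.values, cfg,
                            initial_parameters=start)
        assert all(v > 0 for v in res.estimated_parameters.values())

    def test_recovery_improves_as_noise_vanishes(self, cancer_spec):
        """Median parameter recovery error shrinks (in expectation) as
        observation noise goes from 5% to 0, with paired seeds."""
        free = ["k8p", "k9p", "k10p"]
        errors = {}
        for noise in (0.0, 0.02, 0.05):
            errs = []
            for seed in (1, 2):
                obs = generate_timecourse(cancer_spec, noise_sd=noise, seed=seed)
                start = perturbed_truth(cancer_spec, free, (0.7, 1.4),
                                        seed=100 + seed)
                cfg = FilterConfig(free_parameters=free, n_passes=4,
                                   measurement_noise=max(noise, 0.01)**2,
                                   ode_rtol=1e-6, ode_atol=1e-9)
                res = hukf_estimate(cancer_spec, obs.values, cfg,
                                    initial_parameters=start)
                rel = [abs(res.estimated_parameters[p]
                           - cancer_spec.network.parameters[p])
                       / cancer_spec.network.parameters[p] for p in free]
                errs.append(np.median(rel))
            errors[noise] = np.mean(errs)
        assert errors[0.0] <= errors[0.05] + 1e-3

    def test_rejects_observations_without_t0(self, cancer_spec):
        obs = pd.DataFrame(np.ones((4, 2)),
                           index=["SMAD7", "TGFb", "LIF", "CXCL12"],
                           columns=[24.0, 48.0])
        with pytest.raises(ValueError, match="t=0"):
            hukf_estimate(cancer_spec, obs, FilterConfig())


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        out = goodness_of_fit([1, 2, 3], [1, 2, 3])
        assert out["R2"] == pytest.approx(1.0)
        assert out["RMSE"] == 0.0 and out["MAE"] == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0])
        out = goodness_of_fit(np.full(3, obs.mean()), obs)
        assert out["R2"] == pytest.approx(0.0)

    def test_hand_computed_rmse(self):
        out = goodness_of_fit([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        assert out["RMSE"] == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_zero_variance_observed_raises(self):
        with pytest.raises(ZeroDivisionError):
            goodness_of_fit([1.0, 2.0], [3.0, 3.0])


class TestBlandAltman:
    def test_identical_sets(self):
        out = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out == {"bias": 0.0, "loa_low": 0.0, "loa_high": 0.0}

    def test_constant_offset(self):
        out = bland_altman(np.array([1.0, 2.0]), np.array([1.0, 2.0]) + 0.5)
        assert out["bias"] == pytest.approx(-0.5)
        assert out["loa_high"] - out["loa_low"] == pytest.approx(0.0)

    def test_hand_computed_limits(self):
        out = bland_altman([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert out["bias"] == pytest.approx(0.0)
        assert out["loa_low"] == pytest.approx(-1.96)
        assert out["loa_high"] == pytest.approx(1.96)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestMorris:
    def test_linear_model_is_exact(self):
        a = {"p1": 1.0, "p2": 2.0, "p3": -0.5}
        fn = lambda t: sum(a[k] * t[k] for k in a)
        # a 2-level grid with delta = 1/2 keeps every float operation exact
        res = morris_screening(fn, {k: (0.0, 1.0) for k in a}, r=6, seed=0,
                               delta=0.5, levels=2)
        for i, name in enumerate(res.parameters):
            assert res.mu[i] == a[name]
            assert res.sigma[i] == 0.0
            assert res.mu_star[i] == abs(a[name])

    def test_interaction_produces_dispersion(self):
        fn = lambda t: t["p1"] * t["p2"]
        res = morris_screening(fn, {"p1": (0.0, 1.0), "p2": (0.0, 1.0)},
                               r=50, seed=1)
        assert res.sigma[0] > 0

    def test_seed_reproducibility(self):
        fn = lambda t: t["a"] ** 2 + np.sin(t["b"])
        r1 = morris_screening(fn, {"a": (0, 2), "b": (0, 3)}, r=8, seed=7)
        r2 = morris_screening(fn, {"a": (0, 2), "b": (0, 3)}, r=8, seed=7)
        np.testing.assert_array_equal(r1.mu, r2.mu)
        np.testing.assert_array_equal(r1.sigma, r2.sigma)

    def test_mu_star_bounds_mu(self, rng):
        fn = lambda t: np.tanh(t["a"]) - t["b"] ** 2
        res = morris_screening(fn, {"a": (0, 1), "b": (0, 1)}, r=12, seed=3)
        assert np.all(res.mu_star >= np.abs(res.mu) - 1e-15)

    def test_nonfinite_trajectories_dropped_with_warning(self):
        calls = {"n": 0}

        def fn(t):
            calls["n"] += 1
            return np.nan if calls["n"] <= 3 else t["a"]

        with pytest.warns(UserWarning, match="dropped"):
            res = morris_screening(fn, {"a": (0.0, 1.0)}, r=5, seed=0)
        assert np.isfinite(res.mu).all()
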