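import math

import numpy as np
import pytest

import koalastpp as k
from conftest import make_square_study, simulate_study
from reference_impl import naive_log_partial_likelihood


def _tiny_instance(seed, side=4, n_events=5, T=3):
    """Small random study with events scattered over a few periods."""
    rng = np.random.default_rng(seed)
    _, grid, stack, _ = make_square_study(side=side, resolution=1.0,
                                          seed=seed, n_density=2, n_roads=2)
    patterns = []
    counts = rng.multinomial(n_events, np.ones(T) / T)
    for t in range(T):
        pts = rng.uniform(0.01, side - 0.01, size=(counts[t], 2))
        patterns.append(k.MonthlyPattern(t, pts, [f"e{t}-{i}" for i in range(counts[t])]))
    return grid, stack, patterns


def _naive_lp(params, patterns, stack, grid, season=None, cfg=None):
    season = season or k.SeasonCalendar()
    cfg = cfg or k.InteractionConfig()
    return naive_log_partial_likelihood(
        params.gamma, params.beta, params.theta1, params.theta2, params.phi,
        cfg.u, set(season.mating_months),
        [p.points for p in patterns], grid.masked_centers(),
        stack.e, stack.d, grid.cell_area,
    )


class TestLogPartialLikelihood:
    def test_uniform_null_closed_form(self, small_study):
        _, grid, stack, _ = small_study
        rng = np.random.default_rng(0)
        patterns = [
            k.MonthlyPattern(t, rng.uniform(0.1, 11.9, size=(4, 2)), list("abcd"))
            for t in range(3)
        ]
        params = k.ModelParams(gamma=[0.0, 0.0], beta=[0.0], theta1=1.0,
                               theta2=1.0, phi=1.0)
        lp = k.log_partial_likelihood(params, patterns, stack, grid)
        area = grid.n_in * grid.cell_area
        assert lp == pytest.approx(-12 * math.log(area), rel=1e-12)

    def test_global_rescaling_of_q_cancels(self, small_study):
        # adding a constant to a covariate layer multiplies q by a constant
        # factor everywhere, which cancels in the intensity ratio
        _, grid, stack, _ = small_study
        rng = np.random.default_rng(1)
        patterns = [
            k.MonthlyPattern(t, rng.uniform(0.1, 11.9, size=(5, 2)), [str(i) for i in range(5)])
            for t in range(4)
        ]
        params = k.ModelParams(gamma=[0.5, -0.3], beta=[-0.4], theta1=1.8,
                               theta2=2.2, phi=0.4)
        lp = k.log_partial_likelihood(params, patterns, stack, grid)
        shifted = k.CovariateStack(
            grid=stack.grid, e_names=stack.e_names,
            e=stack.e + np.array([math.log(7.3) / 0.5, 0.0]),  # q scaled by 7.3
            d_names=stack.d_names, d=stack.d,
        )
        lp2 = k.log_partial_likelihood(params, patterns, shifted, grid)
        assert lp2 == pytest.approx(lp, rel=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_double_loop(self, seed):
        grid, stack, patterns = _tiny_instance(seed)
        rng = np.random.default_rng(seed + 1000)
        params = k.ModelParams(
            gamma=rng.normal(0, 0.5, 2), beta=rng.normal(0, 0.5, 1),
            theta1=rng.uniform(0.5, 3), theta2=rng.uniform(0.5, 3),
            phi=rng.uniform(0.1, 1.0),
        )
        lp = k.log_partial_likelihood(params, patterns, stack, grid)
        assert lp == pytest.approx(_naive_lp(params, patterns, stack, grid), rel=1e-10)

    def test_gradient_matches_naive_finite_differences(self):
        grid, stack, patterns = _tiny_instance(3)
        psi0 = np.array([0.3, -0.2, -0.1, math.log(1.5), math.log(2.0), math.log(0.5)])

        def lp_vec(psi):
            params = k.ModelParams(gamma=psi[:2], beta=psi[2:3],
                                   theta1=math.exp(psi[3]), theta2=math.exp(psi[4]),
                                   phi=math.exp(psi[5]))
            return k.log_partial_likelihood(params, patterns, stack, grid)

        def lp_naive(psi):
            params = k.ModelParams(gamma=psi[:2], beta=psi[2:3],
                                   theta1=math.exp(psi[3]), theta2=math.exp(psi[4]),
                                   phi=math.exp(psi[5]))
            return _naive_lp(params, patterns, stack, grid)

        h = 1e-6
        for i in range(6):
            ei = np.zeros(6)
            ei[i] = h
            g_vec = (lp_vec(psi0 + ei) - lp_vec(psi0 - ei)) / (2 * h)
            g_naive = (lp_naive(psi0 + ei) - lp_naive(psi0 - ei)) / (2 * h)
            assert g_vec == pytest.approx(g_naive, rel=1e-5, abs=1e-8)

    def test_event_outside_region_rejected(self, small_study):
        _, grid, stack, _ = small_study
        patterns = [k.MonthlyPattern(0, np.array([[50.0, 50.0]]), ["x"])]
        params = k.ModelParams(gamma=[0.0, 0.0], beta=[0.0], theta1=1.0,
                               theta2=1.0, phi=1.0)
        with pytest.raises(ValueError, match="outside grid"):
            k.log_partial_likelihood(params, patterns, stack, grid)


@pytest.fixture(scope="module")
def null_fit():
    _, grid, stack, _ = make_square_study(side=15, seed=11)
    true = k.ModelParams(gamma=[0.0, 0.0], beta=[0.0], theta1=1.0,
                         theta2=1.0, phi=k.InteractionConfig().u)
    patterns, _ = simulate_study(stack, grid, true, T=24, seed=11,
                                 target_total=900)
    result = k.fit(patterns, stack, grid)
    return result, patterns, stack, grid


class TestFit:
    def test_null_simulation_estimates_near_null(self, null_fit):
        result, *_ = null_fit
        assert result.converged
        psi = np.asarray(result.trace["psi_hat"])
        # γ, β near 0 and log θ near 0, each within 3 SE.  log φ is left
        # out: with θ = 1 the kernel scale has no true value (r ≡ 1).
        for i, name in enumerate(result.param_names):
            if name == "log_phi":
                continue
            assert abs(psi[i]) <= 3 * result.stderr[i] + 1e-6, name

    def test_refit_from_optimum_is_a_fixed_point(self, null_fit):
        result, patterns, stack, grid = null_fit
        again = k.fit(patterns, stack, grid,
                      opts=k.FitOptions(start=np.asarray(result.trace["psi_hat"])))
        assert again.logpl == pytest.approx(result.logpl, abs=1e-6)

    def test_deterministic_given_data_and_start(self, null_fit):
        _, patterns, stack, grid = null_fit
        a = k.fit(patterns, stack, grid)
        b = k.fit(patterns, stack, grid)
        np.testing.assert_array_equal(a.trace["psi_hat"], b.trace["psi_hat"])


class TestLambda0:
    def test_uniform_null_closed_form(self, small_study):
        _, grid, stack, _ = small_study
        rng = np.random.default_rng(5)
        T = 6
        patterns = [
            k.MonthlyPattern(t, rng.uniform(0.1, 11.9, size=(3, 2)), list("abc"))
            for t in range(T)
        ]
        params = k.ModelParams(gamma=[0.0, 0.0], beta=[0.0], theta1=1.0,
                               theta2=1.0, phi=1.0)
        result = k.FitResult(params=params, logpl=0.0, stderr=np.full(5, np.nan),
                             param_names=[], converged=True, n_events=3 * T,
                             trace={"psi_hat": [0.0] * 5})
        lam0 = k.estimate_lambda0(result, patterns, stack, grid)
        area = grid.n_in * grid.cell_area
        assert lam0 == pytest.approx(3 * T / (area * T), rel=1e-12)

    def test_roundtrip_expected_count_equals_n(self):
        _, grid, stack, _ = make_square_study(side=10, seed=21)
        true = k.ModelParams(gamma=[0.5, -0.5], beta=[-0.6], theta1=2.0,
                             theta2=2.5, phi=0.4)
        patterns, _ = simulate_study(stack, grid, true, T=12, seed=21,
                                     target_total=100)
        result = k.fit(patterns, stack, grid)
        k.estimate_lambda0(result, patterns, stack, grid)
        n = sum(len(p) for p in patterns)
        total = k.expected_total(result.params, patterns, stack, grid)
        assert total == pytest.approx(n, rel=1e-9)

    def test_quadrature_consistency_across_resolutions(self):
        # same point data, coarser quadrature: λ0 agrees to quadrature error
        region, grid_f, stack_f, roads = make_square_study(side=10, resolution=0.5,
                                                           seed=33)
        true = k.ModelParams(gamma=[0.4, -0.4], beta=[-0.5], theta1=1.0,
                             theta2=1.0, phi=0.4)
        patterns, _ = simulate_study(stack_f, grid_f, true, T=8, seed=33,
                                     target_total=300)
        grid_c = k.build_grid(region, 1.0)
        rasters = k.generate_covariate_fields(grid_c, 2, seed=33)
        stack_c = k.assemble_stack(grid_c, rasters, roads=roads)

        def lam0_on(stack, grid):
            params = k.ModelParams(gamma=[0.4, -0.4], beta=[-0.5], theta1=1.0,
                                   theta2=1.0, phi=0.4)
            result = k.FitResult(params=params, logpl=0.0, stderr=np.full(5, np.nan),
                                 param_names=[], converged=True,
                                 n_events=sum(len(p) for p in patterns),
                                 trace={"psi_hat": [0.0] * 5})
            return k.estimate_lambda0(result, patterns, stack, grid)

        fine, coarse = lam0_on(stack_f, grid_f), lam0_on(stack_c, grid_c)
        assert coarse == pytest.approx(fine, rel=0.15)


class TestWaldCI:
    def test_normal_quantile(self):
        from scipy.stats import norm

        assert norm.ppf(0.975) == pytest.approx(1.959964, abs=1e-6)

    def test_log_scale_intervals_are_positive_and_contain_estimate(self):
        params = k.ModelParams(gamma=[0.2], beta=[-0.1], theta1=1.5, theta2=2.0,
                               phi=0.5)
        psi = [0.2, -0.1, math.log(1.5), math.log(2.0), math.log(0.5)]
        result = k.FitResult(params=params, logpl=0.0,
                             stderr=np.array([0.1, 0.1, 0.2, 0.2, 0.5]),
                             param_names=["gamma_1", "beta_1", "log_theta1",
                                          "log_theta2", "log_phi"],
                             converged=True, n_events=10, trace={"psi_hat": psi})
        ci = k.wald_ci(result, 0.95)
        for name, est in [("theta1", 1.5), ("theta2", 2.0), ("phi", 0.5)]:
            lo, hi = ci[name]
            assert 0 < lo < est < hi
            # asymmetric around the estimate on the natural scale
            assert (hi - est) > (est - lo)
        lo, hi = ci["gamma_1"]
        assert lo == pytest.approx(0.2 - 1.959964 * 0.1, abs=1e-5)
        assert hi == pytest.approx(0.2 + 1.959964 * 0.1, abs=1e-5)

    def test_unavailable_stderr_maps_to_nan_interval(self):
        params = k.ModelParams(gamma=[0.0], beta=[], theta1=1.0, theta2=1.0, phi=1.0)
        result = k.FitResult(params=params, logpl=0.0,
                             stderr=np.array([np.nan, 0.1, 0.1, 0.1]),
                             param_names=["gamma_1", "log_theta1", "log_theta2",
                                          "log_phi"],
                             converged=True, n_events=5,
                             trace={"psi_hat": [0.0, 0.0, 0.0, 0.0]})
        ci = k.wald_ci(result)
        assert all(math.isnan(v) for v in ci["gamma_1"])
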