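"""Dipolar kernel, forward signal model, and trace inversion."""

import numpy as np
import pytest

import ddrensemble as dd
from ddrensemble.deer import dipolar_frequency, elementary_kernel, pathway_kernel
from ddrensemble.distributions import DistanceDistribution


class TestElementaryKernel:
    def test_unity_at_zero_time(self):
        k = elementary_kernel(np.array([0.0]), dd.default_grid(15, 80, 1.0))
        np.testing.assert_allclose(k[0], 1.0)

    def test_dipolar_frequency_constant(self):
        # nu_dd(30 A) = 52.04 MHz / 3^3
        assert dipolar_frequency(np.array([30.0]))[0] == pytest.approx(52.04 / 27.0)

    def test_matches_monte_carlo_powder_average(self):
        # stratified MC over 1e6 orientations as the independent oracle
        rng = np.random.default_rng(7)
        n = 1_000_000
        z = (np.arange(n) + rng.random(n)) / n
        t_axis = np.array([0.2, 0.5, 1.0, 1.7, 2.5])
        r_axis = np.array([20.0, 30.0, 45.0, 60.0])
        k = elementary_kernel(t_axis, r_axis)
        w = 2 * np.pi * dipolar_frequency(r_axis)
        mc = np.array(
            [[np.cos((1 - 3 * z**2) * wi * ti).mean() for wi in w] for ti in t_axis]
        )
        assert np.max(np.abs(k - mc)) < 1e-3

    def test_values_bounded_in_theoretical_range(self):
        t = np.linspace(0, 6, 400)
        k = elementary_kernel(t, dd.default_grid(15, 80, 0.5))
        assert k.max() <= 1.0 + 1e-9
        assert k.min() >= -0.5


class TestMultipathwaySignal:
    def test_unmodulated_only_gives_flat_signal(self, grid):
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=30, sigma=5))
        model = dd.PathwayModel(lambda0=1.0, lambda1=0.0, lambda2=0.0)
        tr = dd.multipathway_signal(d, model, np.linspace(0, 3, 100))
        np.testing.assert_allclose(tr.v, 1.0)

    def test_delta_distribution_reduces_to_elementary_kernel(self):
        r = dd.default_grid(10, 60, 0.5)
        p = np.zeros(r.size)
        p[r == 30.0] = 1.0
        d = DistanceDistribution(r, p)
        t = np.linspace(0, 3, 120)
        model = dd.PathwayModel(lambda0=0.6, lambda1=0.4, k_bg=0.0)
        tr = dd.multipathway_signal(d, model, t)
        expected = 0.6 + 0.4 * elementary_kernel(t, np.array([30.0]))[:, 0]
        np.testing.assert_allclose(tr.v, expected, atol=1e-12)

    def test_full_model_matches_term_by_term_brute_force(self):
        rng = np.random.default_rng(3)
        r = dd.default_grid(15, 60, 2.5)
        p = rng.random(r.size)
        d = DistanceDistribution(r, p).normalize()
        t = np.sort(rng.uniform(-0.2, 3.0, 20))
        model = dd.PathwayModel(lambda0=0.55, lambda1=0.3, lambda2=0.1, t02=2.6, k_bg=0.08)
        tr = dd.multipathway_signal(d, model, t)
        # brute-force double loop over (t, r)
        brute = np.zeros(t.size)
        for it, ti in enumerate(t):
            acc = 0.0
            for ir, ri in enumerate(r):
                k0a = elementary_kernel(np.array([ti]), np.array([ri]))[0, 0]
                k0b = elementary_kernel(np.array([ti - 2.6]), np.array([ri]))[0, 0]
                kern = (0.55 + 0.3 * k0a + 0.1 * k0b) * np.exp(
                    -0.08 * (0.3 * abs(ti) + 0.1 * abs(ti - 2.6))
                )
                acc += d.p[ir] * kern
            brute[it] = acc
        np.testing.assert_allclose(tr.v, brute, atol=1e-10)

    def test_unit_signal_at_zero_time(self, grid):
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=35, sigma=8))
        model = dd.PathwayModel(lambda0=0.7, lambda1=0.3, lambda2=0.0, k_bg=0.0)
        tr = dd.multipathway_signal(d, model, np.array([0.0, 1.0]))
        assert tr.v[0] == pytest.approx(1.0)

    def test_amplitude_sum_validated(self):
        with pytest.raises(ValueError):
            dd.PathwayModel(lambda0=0.8, lambda1=0.5)


class TestParametricFit:
    def test_noiseless_gaussian_recovery(self):
        grid = dd.default_grid(10, 70, 0.5)
        truth = dd.gaussian_pdf(grid, dd.GaussianParams(mean=35, sigma=9))
        model = dd.PathwayModel(lambda0=0.7, lambda1=0.3, k_bg=0.05)
        tr = dd.simulate_trace(truth, model, t_max=3.0, dt=0.012)
        fit = dd.fit_parametric(tr, "gaussian", r_axis=grid)
        assert fit.dist_params.mean == pytest.approx(35.0, rel=0.01)
        assert fit.dist_params.sigma == pytest.approx(9.0, rel=0.01)
        assert fit.pathway.lambda0 == pytest.approx(0.7, rel=0.01)
        assert fit.pathway.k_bg == pytest.approx(0.05, rel=0.01)
        assert fit.converged

    def test_noisy_mean_recovery_across_seeds(self):
        grid = dd.default_grid(10, 70, 1.0)
        truth = dd.gaussian_pdf(grid, dd.GaussianParams(mean=35, sigma=9))
        model = dd.PathwayModel(lambda0=0.7, lambda1=0.3, k_bg=0.05)
        means = []
        for seed in range(10):
            tr = dd.simulate_trace(truth, model, t_max=3.0, dt=0.012, noise_sigma=0.002, seed=seed)
            fit = dd.fit_parametric(tr, "gaussian", r_axis=grid, n_starts=2, seed=seed)
            means.append(fit.dist_params.mean)
        assert abs(np.mean(means) - 35.0) < 0.5

    def test_multi_gaussian_bic_selects_two_components(self):
        grid = dd.default_grid(10, 90, 1.0)
        model = dd.PathwayModel(lambda0=0.7, lambda1=0.3, k_bg=0.05)
        p2 = DistanceDistribution(
            grid,
            0.6 * dd.gaussian_pdf(grid, dd.GaussianParams(mean=28, sigma=4)).p
            + 0.4 * dd.gaussian_pdf(grid, dd.GaussianParams(mean=48, sigma=5)).p,
        ).normalize()
        hits = 0
        n_rep = 6
        for seed in range(n_rep):
            tr = dd.simulate_trace(p2, model, t_max=4.0, dt=0.016, noise_sigma=0.002, seed=seed)
            fit = dd.fit_parametric(
                tr, "multi_gaussian", r_axis=grid, n_max=3, criterion="bic",
                n_starts=2, seed=seed,
            )
            hits += fit.n_components == 2
        assert hits >= n_rep - 1  # component count picked in nearly all replicates


class TestTikhonov:
    def test_narrow_distribution_mode_recovered(self):
        grid = dd.default_grid(10, 60, 1.0)
        r0 = 35.0
        p = np.exp(-0.5 * ((grid - r0) / 1.0) ** 2)
        truth = DistanceDistribution(grid, p).normalize()
        model = dd.PathwayModel(lambda0=0.6, lambda1=0.4, k_bg=0.0)
        tr = dd.multipathway_signal(truth, model, np.linspace(0, 4, 300))
        dist, _, _ = dd.tikhonov(tr, alpha=0.01, model=model, r_axis=grid)
        assert grid[dist.p.argmax()] == pytest.approx(r0, abs=1.0)

    def test_large_alpha_drives_smoothness(self):
        grid = dd.default_grid(10, 60, 1.0)
        truth = dd.gaussian_pdf(grid, dd.GaussianParams(mean=35, sigma=6))
        model = dd.PathwayModel(lambda0=0.6, lambda1=0.4, k_bg=0.0)
        tr = dd.multipathway_signal(truth, model, np.linspace(0, 4, 300))
        small, _, _ = dd.tikhonov(tr, alpha=0.1, model=model, r_axis=grid)
        large, _, _ = dd.tikhonov(tr, alpha=1e4, model=model, r_axis=grid)

        def curvature(p):
            return float(np.sum(np.diff(p, 2) ** 2))

        assert curvature(large.p) < 1e-3 * curvature(small.p)

    def test_criterion_selection_recovers_broad_gaussian(self):
        grid = dd.default_grid(10, 90, 1.0)
        truth = dd.gaussian_pdf(grid, dd.GaussianParams(mean=40, sigma=15))
        model = dd.PathwayModel(lambda0=0.7, lambda1=0.3, k_bg=0.05)
        tr = dd.simulate_trace(truth, model, t_max=4.0, dt=0.016, noise_sigma=0.002, seed=3)
        for criterion in ("aic", "bic", "residual"):
            dist, alpha_used, _ = dd.tikhonov(tr, alpha=criterion, model=model, r_axis=grid)
            assert dd.overlap(dist, truth) >= 0.9, criterion
            assert alpha_used > 0

    def test_forward_inverse_consistency(self):
        # noiseless narrow distribution round-trips with overlap >= 0.98
        grid = dd.default_grid(10, 70, 0.5)
        truth = dd.gaussian_pdf(grid, dd.GaussianParams(mean=32, sigma=3))
        model = dd.PathwayModel(lambda0=0.65, lambda1=0.35, k_bg=0.02)
        tr = dd.multipathway_signal(truth, model, np.linspace(0, 4, 350))
        dist, _, _ = dd.tikhonov(tr, alpha=0.05, model=model, r_axis=grid)
        assert dd.overlap(dist, truth) >= 0.98


class TestTrace:
    def test_noise_estimate_from_second_difference(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 3, 400)
        v = np.exp(-t) + 0.01 * rng.standard_normal(t.size)
        tr = dd.DeerTrace(t, v)
        assert tr.estimate_noise() == pytest.approx(0.01, rel=0.25)

    def test_rejects_nonincreasing_time(self):
        with pytest.raises(ValueError):
            dd.DeerTrace(np.array([0.0, 0.0, 1.0]), np.ones(3))
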