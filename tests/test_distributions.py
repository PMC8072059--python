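"""Distance-distribution container, parametric models, overlap, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import ddrensemble as dd
from ddrensemble.distributions import FWHM_PER_SIGMA, DistanceDistribution


class TestGaussianParams:
    def test_fwhm_sigma_identity(self):
        p = dd.GaussianParams(mean=30.0, fwhm=2.3548)
        assert p.sigma == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 8.2, 25.0])
    def test_conversion_is_involution(self, sigma):
        p = dd.GaussianParams(mean=30.0, sigma=sigma)
        q = dd.GaussianParams(mean=30.0, fwhm=p.fwhm)
        assert q.sigma == pytest.approx(sigma, rel=1e-12)
        assert p.fwhm == pytest.approx(sigma * FWHM_PER_SIGMA)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            dd.GaussianParams(mean=30.0, sigma=-1.0)


class TestGaussianPdf:
    def test_normalized_with_mode_at_mean(self, grid):
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=30.0, sigma=5.0))
        assert d.p.sum() == pytest.approx(1.0)
        assert d.r_axis[d.p.argmax()] == pytest.approx(30.0)

    def test_tail_mass_matches_cdf_oracle(self):
        # fraction of mass below 15 A vs the analytic normal CDF,
        # with the same truncation window as the grid
        grid = dd.default_grid(10.0, 60.0, 0.5)
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=27.0, sigma=8.2))
        got = d.p[grid < 15.0].sum()
        cdf = norm(27.0, 8.2).cdf
        expected = (cdf(14.75) - cdf(9.75)) / (cdf(60.25) - cdf(9.75))
        assert got == pytest.approx(expected, abs=2e-3)

    def test_rejects_nonuniform_axis(self):
        with pytest.raises(ValueError):
            dd.gaussian_pdf(np.array([1.0, 2.0, 4.0]), dd.GaussianParams(mean=2, sigma=1))


class TestSawNuPdf:
    @pytest.mark.parametrize("nu", [0.35, 0.5, 0.6, 0.75])
    def test_second_moment_equals_R_squared(self, nu):
        grid = dd.default_grid(0.5, 150.0, 0.5)
        d = dd.saw_nu_pdf(grid, dd.SawNuParams(R=30.0, nu=nu))
        assert d.rms() == pytest.approx(30.0, rel=5e-3)

    def test_good_solvent_shape_is_mildly_skewed(self):
        grid = dd.default_grid(0.5, 120.0, 0.5)
        d = dd.saw_nu_pdf(grid, dd.SawNuParams(R=30.0, nu=0.6))
        assert d.skewness() > 0.0
        _, rmsd = dd.fit_gaussian(d)
        assert 0.0 < rmsd < 0.05  # deviations from a Gaussian are minor

    def test_poor_solvent_more_skewed_than_good_solvent(self):
        grid = dd.default_grid(0.25, 120.0, 0.25)
        poor = dd.saw_nu_pdf(grid, dd.SawNuParams(R=30.0, nu=1.0 / 3.0))
        good = dd.saw_nu_pdf(grid, dd.SawNuParams(R=30.0, nu=0.6))
        assert poor.skewness() > good.skewness()

    @pytest.mark.parametrize("nu", [0.0, 1.0, 1.2])
    def test_rejects_nu_outside_unit_interval(self, nu):
        with pytest.raises(ValueError):
            dd.SawNuParams(R=30.0, nu=nu)


class TestOverlap:
    def test_identical_distributions(self, grid):
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=30, sigma=5))
        assert dd.overlap(d, d) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        r = dd.default_grid(10, 20, 1.0)
        a = np.zeros(r.size)
        b = np.zeros(r.size)
        a[:3] = 1 / 3
        b[-3:] = 1 / 3
        assert dd.overlap(DistanceDistribution(r, a), DistanceDistribution(r, b)) == 0.0

    def test_shifted_uniform_blocks(self):
        # uniform over bins 1-4 vs bins 3-6: two shared bins of 0.25 each
        r = dd.default_grid(10, 16, 1.0)
        a = np.zeros(r.size)
        b = np.zeros(r.size)
        a[0:4] = 0.25
        b[2:6] = 0.25
        assert dd.overlap(DistanceDistribution(r, a), DistanceDistribution(r, b)) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_one_minus_total_variation(self, seed):
        rng = np.random.default_rng(seed)
        r = dd.default_grid(10, 40, 1.0)
        a = DistanceDistribution(r, rng.random(r.size)).normalize()
        b = DistanceDistribution(r, rng.random(r.size)).normalize()
        o = dd.overlap(a, b)
        tv = 0.5 * np.abs(a.p - b.p).sum()  # brute-force TV oracle
        assert o == pytest.approx(1.0 - tv, abs=1e-12)
        assert dd.overlap(b, a) == pytest.approx(o)  # symmetry
        assert 0.0 <= o <= 1.0


class TestGeometricMeanOverlap:
    @pytest.mark.parametrize(
        "values, expected",
        [([0.9, 0.9], 0.9), ([1.0, 0.25], 0.5), ([0.8, 0.9, 0.7], 0.7958)],
    )
    def test_known_values(self, values, expected):
        assert dd.geometric_mean_overlap(values) == pytest.approx(expected, abs=1e-4)

    def test_zero_overlap_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert dd.geometric_mean_overlap([0.9, 0.0]) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=10))
    def test_never_exceeds_arithmetic_mean(self, values):
        assert dd.geometric_mean_overlap(values) <= np.mean(values) + 1e-12


class TestFitting:
    def test_gaussian_self_fit(self, grid):
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=30, sigma=5))
        params, rmsd = dd.fit_gaussian(d)
        assert params.mean == pytest.approx(30.0, abs=1e-6)
        assert params.sigma == pytest.approx(5.0, abs=1e-6)
        assert rmsd < 1e-9

    def test_gaussian_fit_of_skewed_density_sits_below_rms(self):
        grid = dd.default_grid(0.5, 120.0, 0.5)
        d = dd.saw_nu_pdf(grid, dd.SawNuParams(R=30.0, nu=0.6))
        params, _ = dd.fit_gaussian(d)
        assert params.mean < d.rms()  # skew pushes RMS above the fitted mean
        assert params.mean < 30.0

    @pytest.mark.parametrize("nu", [0.35, 0.5, 0.6, 0.75])
    def test_saw_nu_round_trip(self, nu):
        grid = dd.default_grid(0.5, 150.0, 0.5)
        d = dd.saw_nu_pdf(grid, dd.SawNuParams(R=30.0, nu=nu))
        params, rmsd = dd.fit_saw_nu(d)
        assert params.R == pytest.approx(30.0, rel=0.01)
        assert params.nu == pytest.approx(nu, rel=0.01)
        assert rmsd < 1e-6

    def test_saw_fit_of_pure_gaussian_runs_to_upper_nu(self, grid):
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=30, sigma=5))
        params, rmsd = dd.fit_saw_nu(d)
        assert rmsd > 0.0
        assert params.nu > 0.7  # symmetric target drives nu to the stiff end

    def test_degenerate_distribution_rejected(self):
        r = dd.default_grid(10, 20, 1.0)
        p = np.zeros(r.size)
        p[3] = 1.0
        with pytest.raises(ValueError):
            dd.fit_gaussian(DistanceDistribution(r, p))


class TestResample:
    def test_identity_axis(self, grid):
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=30, sigma=5))
        r = dd.resample(d, grid)
        np.testing.assert_allclose(r.p, d.p)

    def test_halve_then_restore_round_trip(self):
        coarse = dd.default_grid(10, 60, 1.0)
        fine = dd.default_grid(10, 60, 0.5)
        d = dd.gaussian_pdf(coarse, dd.GaussianParams(mean=30, sigma=6))
        back = dd.resample(dd.resample(d, fine), coarse)
        assert 1.0 - dd.overlap(back, d) < 1e-6

    def test_moments_preserved_across_bin_width(self):
        fine = dd.default_grid(10, 60, 0.5)
        coarse = dd.default_grid(10, 60, 1.0)
        d = dd.gaussian_pdf(fine, dd.GaussianParams(mean=30, sigma=6))
        r = dd.resample(d, coarse)
        assert r.mean() == pytest.approx(d.mean(), rel=1e-3)
        assert r.std() == pytest.approx(d.std(), rel=1e-3)

    def test_rejects_decreasing_axis(self, grid):
        d = dd.gaussian_pdf(grid, dd.GaussianParams(mean=30, sigma=5))
        with pytest.raises(ValueError):
            dd.resample(d, grid[::-1])


class TestBands:
    def test_band_shape_validation(self):
        r = dd.default_grid(10, 20, 1.0)
        with pytest.raises(ValueError):
            DistanceDistribution(r, np.ones(r.size), band_lo=np.ones(3))
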