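"""Seawater optics: phase functions, backscatter fraction, PSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from oceanhsrl import optics as O


class TestPowerLawPSD:
    @pytest.mark.parametrize(
        "D, expected",
        [(1.0, 1e10), (2.0, 6.25e8)],
    )
    def test_number_density_values(self, D, expected):
        psd = O.PowerLawPSD(N0=1e10, D0=1.0, xi=4.0)
        assert psd.number_density(D) == pytest.approx(expected, rel=1e-12)

    def test_loglog_slope_recovers_exponent(self):
        psd = O.PowerLawPSD(N0=1e10, D0=1.0, xi=3.7)
        D = np.logspace(-1, 2, 50)
        slope = np.polyfit(np.log(D), np.log(psd.number_density(D)), 1)[0]
        assert slope == pytest.approx(-3.7, abs=1e-10)

    def test_nonpositive_diameter_rejected(self):
        psd = O.PowerLawPSD(N0=1e10, D0=1.0, xi=4.0)
        with pytest.raises(ValueError):
            psd.number_density(0.0)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            O.PowerLawPSD(N0=1.0, D0=1.0, xi=3.0)


class TestRefractiveIndex:
    @pytest.mark.parametrize(
        "xi, expected",
        [(3.0001, 1.01), (4.0, 1.1642), (3.38, 1.068596)],
    )
    def test_values(self, xi, expected):
        assert O.relative_refractive_index(xi) == pytest.approx(expected, abs=2e-5)

    def test_monotone(self):
        xi = np.linspace(3.05, 5.0, 40)
        m = O.relative_refractive_index(xi)
        assert np.all(np.diff(m) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            O.relative_refractive_index(3.0)


class TestFournierForand:
    @pytest.mark.parametrize("xi", [3.2, 3.5, 4.0])
    def test_normalization(self, xi):
        total, _ = quad(
            lambda t: O.fournier_forand_phase(xi, t) * 2 * np.pi * np.sin(t),
            1e-12,
            np.pi,
            limit=400,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_forward_peak(self):
        ratio = O.fournier_forand_phase(3.5, np.radians(1.0)) / O.fournier_forand_phase(
            3.5, np.pi / 2
        )
        assert ratio > 1e3

    @pytest.mark.parametrize("xi", [3.15, 3.42, 4.5])
    def test_cumulative_matches_density(self, xi):
        # dF/dtheta = p(theta) 2 pi sin(theta) at interior angles
        for th in (0.01, 0.3, 1.5, 2.8):
            eps = 1e-6
            dF = (
                O.fournier_forand_cumulative(xi, th + eps)
                - O.fournier_forand_cumulative(xi, th - eps)
            ) / (2 * eps)
            pd = O.fournier_forand_phase(xi, th) * 2 * np.pi * np.sin(th)
            assert dF == pytest.approx(pd, rel=2e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            O.fournier_forand_phase(3.5, 0.0)
        with pytest.raises(ValueError):
            O.fournier_forand_phase(3.0, 0.5)

    def test_nonnegative(self):
        th = np.linspace(1e-5, np.pi, 500)
        assert np.all(O.fournier_forand_phase(3.3, th) >= 0)


class TestBackscatterFraction:
    @pytest.mark.parametrize("xi", [3.2, 3.5, 4.0])
    def test_matches_backward_quadrature(self, xi):
        back, _ = quad(
            lambda t: O.fournier_forand_phase(xi, t) * 2 * np.pi * np.sin(t),
            np.pi / 2,
            np.pi,
            limit=200,
        )
        assert O.backscatter_fraction(xi) == pytest.approx(back, rel=0.01)

    def test_monotone_in_slope(self):
        bf = [O.backscatter_fraction(x) for x in (3.2, 3.6, 4.0)]
        assert bf[0] < bf[1] < bf[2]

    def test_bounds(self):
        # BF reaches exactly 1/2 at the upper domain edge xi = 5
        xi = np.linspace(3.05, 4.99, 30)
        bf = O.backscatter_fraction(xi)
        assert np.all(bf > 0) and np.all(bf < 0.5)

    def test_degenerate_slope_rejected(self):
        with pytest.raises(ValueError):
            O.backscatter_fraction(3.0)

    def test_round_trip_inversion(self):
        for xi in (3.15, 3.38, 4.2):
            bf = O.backscatter_fraction(xi)
            assert O.xi_from_backscatter_fraction(bf) == pytest.approx(xi, abs=1e-6)


class TestPhaseInvariants:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(xi=st.floats(3.05, 5.0))
    def test_cumulative_monotone_and_bounded(self, xi):
        th = np.linspace(1e-5, np.pi, 200)
        cdf = O.fournier_forand_cumulative(xi, th)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert 0.0 <= cdf[0] and cdf[-1] == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(xi=st.floats(3.05, 5.0), theta=st.floats(1e-5, np.pi))
    def test_density_nonnegative(self, xi, theta):
        assert O.fournier_forand_phase(xi, theta) >= 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(xi=st.floats(3.05, 4.99))
    def test_bf_round_trip(self, xi):
        bf = O.backscatter_fraction(xi)
        assert 0.0 < bf < 0.5
        assert O.xi_from_backscatter_fraction(bf) == pytest.approx(xi, abs=1e-6)


class TestMolecularPhase:
    def test_normalized_and_symmetric(self):
        p = O.MolecularPhase()
        total, _ = quad(lambda t: p(t) * 2 * np.pi * np.sin(t), 0, np.pi)
        assert total == pytest.approx(1.0, abs=1e-9)
        th = np.linspace(0.01, np.pi / 2 - 0.01, 50)
        assert np.allclose(p(th), p(np.pi - th), rtol=1e-12)


class TestAngleSampling:
    def test_deterministic_for_fixed_seed(self):
        phase = O.FournierForandPhase(3.5)
        a = O.sample_scattering_angle(phase, 100, np.random.default_rng(3))
        b = O.sample_scattering_angle(phase, 100, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_requires_seeded_generator(self):
        with pytest.raises(TypeError):
            O.sample_scattering_angle(O.FournierForandPhase(3.5), 10, rng=None)

    def test_empirical_cdf_matches_analytic(self):
        phase = O.FournierForandPhase(3.5)
        draws = O.sample_scattering_angle(phase, 200_000, np.random.default_rng(5))
        grid = np.sort(draws)
        emp = np.arange(1, grid.size + 1) / grid.size
        ana = O.fournier_forand_cumulative(3.5, grid)
        assert np.max(np.abs(emp - ana)) < 0.005

    def test_backward_draw_fraction_matches_bf(self):
        phase = O.FournierForandPhase(3.5)
        n = 500_000
        draws = O.sample_scattering_angle(phase, n, np.random.default_rng(9))
        frac = np.mean(draws > np.pi / 2)
        bf = phase.backscatter_fraction
        se = np.sqrt(bf * (1 - bf) / n)
        assert abs(frac - bf) < 3 * se + 1e-4
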