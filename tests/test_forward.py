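"""Forward models: analytic surrogate, semianalytic Monte Carlo, noise."""

import numpy as np
import pytest

from oceanhsrl import (
    IOPProfile,
    LidarConfig,
    add_noise,
    forward_analytic,
    simulate_mc,
)


def single_scatter_reference(iop, config):
    """Bin-integrated single-scattering lidar equation (molecular return).

    Independent closed form for the particulate-free limit: two-way
    attenuation 2(a + b_m), exact range-gate integration, bin-averaged
    geometry factor.
    """
    z = iop.depths
    dz = iop.dz
    h = config.lidar_height
    geom = config.system_constant * config.receiver_area / (
        (h + z - dz / 2) * (h + z + dz / 2)
    )
    g = 2.0 * (iop.a + iop.water.b_w)
    tau_edge = np.concatenate([[0.0], np.cumsum(g * dz)])[:-1]
    gate = -np.expm1(-g * dz) / g
    return geom * config.beta_m_pi * np.exp(-tau_edge) * gate / dz


class TestAnalyticForward:
    def test_single_scattering_limit_exact(self, config):
        iop = IOPProfile.homogeneous(0.05, 0.0022, 3.4, max_depth=30)
        sig = forward_analytic(iop, config)
        ref = single_scatter_reference(iop, config)
        for ch in range(3):
            assert np.allclose(sig.mol[ch], ref, rtol=1e-10)

    def test_channel_ordering_nested_apertures(self, l3_signals):
        assert np.all(l3_signals.mol_wide >= l3_signals.mol_mid)
        assert np.all(l3_signals.mol_mid >= l3_signals.mol_narrow)
        assert np.all(l3_signals.comb_wide >= l3_signals.mol_wide)

    def test_monotone_decay_with_depth(self, l3_signals):
        for ch in range(3):
            assert np.all(np.diff(l3_signals.mol[ch]) < 0)

    def test_narrow_fov_limit_is_beam_attenuation(self, config):
        # the Fournier-Forand forward spike concentrates percent-level
        # scattering below 1e-4 rad, so the 2c limit is approached slowly
        iop = IOPProfile.homogeneous(0.08, 0.45, 3.3, max_depth=30)

        def slope(fov):
            cfg = config.replace(fovs=(fov, 2 * fov, 0.2))
            sig = forward_analytic(iop, cfg)
            z = sig.depths
            rc = np.log(sig.mol_narrow * (config.lidar_height + z) ** 2)
            return -np.polyfit(z[2:20], rc[2:20], 1)[0]

        two_c = 2 * (0.08 + 0.45)
        s_tiny, s_mid, s_nominal = slope(1e-6), slope(1e-3), slope(0.04)
        assert s_nominal < s_mid < s_tiny <= two_c
        assert s_tiny == pytest.approx(two_c, rel=0.06)

    def test_wide_fov_slope_in_diffuse_regime(self, config):
        iop = IOPProfile.homogeneous(0.08, 0.45, 3.3, max_depth=30)
        sig = forward_analytic(iop, config)
        z = sig.depths
        rc = np.log(sig.mol_wide * (config.lidar_height + z) ** 2)
        slope = -np.polyfit(z[2:20], rc[2:20], 1)[0]
        assert 2 * 0.08 <= slope < 2 * (0.08 + 0.45)

    def test_multiple_scattering_signature(self, config):
        # (wide - narrow)/narrow grows with optical depth, vanishes as b_p -> 0
        turbid = forward_analytic(
            IOPProfile.homogeneous(0.08, 0.45, 3.3, max_depth=30), config
        )
        ratio = (turbid.mol_wide - turbid.mol_narrow) / turbid.mol_narrow
        assert np.all(np.diff(ratio[:20]) > 0)
        clear = forward_analytic(
            IOPProfile.homogeneous(0.08, 0.0023, 3.3, max_depth=30), config
        )
        ratio_clear = (clear.mol_wide - clear.mol_narrow) / clear.mol_narrow
        assert np.max(np.abs(ratio_clear)) < 2e-3


class TestMonteCarlo:
    def test_deterministic_for_fixed_seed(self, l5_profile, config):
        s1 = simulate_mc(l5_profile, config, n_photons=50_000, seed=123)
        s2 = simulate_mc(l5_profile, config, n_photons=50_000, seed=123)
        assert np.array_equal(s1.mol, s2.mol)
        assert np.array_equal(s1.comb_wide, s2.comb_wide)

    def test_seed_changes_draws(self, l5_profile, config):
        s1 = simulate_mc(l5_profile, config, n_photons=50_000, seed=1)
        s2 = simulate_mc(l5_profile, config, n_photons=50_000, seed=2)
        assert not np.array_equal(s1.mol, s2.mol)

    def test_rejects_tiny_photon_budget(self, l5_profile, config):
        with pytest.raises(ValueError):
            simulate_mc(l5_profile, config, n_photons=100, seed=0)

    def test_clear_water_matches_single_scattering(self, clear_profile, clear_mc, config):
        ref = single_scatter_reference(clear_profile, config)
        sel = clear_mc.mol_se[2] > 0
        resid = (clear_mc.mol_wide[sel] - ref[sel]) / np.maximum(
            clear_mc.mol_se[2][sel], 1e-300
        )
        # bin-wise agreement within Monte Carlo error bars
        assert np.mean(np.abs(resid) < 4) > 0.9

    def test_standard_error_scaling_with_photons(self, l5_profile, config):
        lo = simulate_mc(l5_profile, config, n_photons=100_000, seed=31)
        hi = simulate_mc(l5_profile, config, n_photons=900_000, seed=32)
        # pooled relative SE over the upper bins should fall roughly as n^-1/2
        r_lo = np.median((lo.mol_se / lo.mol)[:, :8])
        r_hi = np.median((hi.mol_se / hi.mol)[:, :8])
        assert 1.5 < r_lo / r_hi < 6.0

    def test_channel_consistency(self, l5_mc):
        assert np.all(l5_mc.comb_wide >= l5_mc.mol_wide * 0.98)


class TestPoissonNoise:
    def test_large_scale_limit_recovers_signal(self, l3_signals):
        noisy = add_noise(l3_signals, scale=1e9 / l3_signals.mol.max(), seed=4)
        assert np.allclose(noisy.mol, l3_signals.mol, rtol=1e-3)

    def test_variance_matches_poisson(self, l3_signals):
        scale = 5e4 / l3_signals.mol.max()
        draws = np.array(
            [add_noise(l3_signals, scale=scale, seed=s).mol[2, 5] for s in range(800)]
        )
        expected_var = l3_signals.mol[2, 5] / scale
        assert np.var(draws) == pytest.approx(expected_var, rel=0.25)

    def test_seed_reproducibility(self, l3_signals):
        a = add_noise(l3_signals, scale=100.0, seed=7)
        b = add_noise(l3_signals, scale=100.0, seed=7)
        assert np.array_equal(a.mol, b.mol)

    def test_negative_background_rejected(self, l3_signals):
        with pytest.raises(ValueError):
            add_noise(l3_signals, scale=1.0, background=-1.0)
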