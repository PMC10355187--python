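"""Iterative triple-FOV inversion: metric, initialization, solver."""

import numpy as np
import pytest

from oceanhsrl import (
    IOPProfile,
    LidarConfig,
    forward_analytic,
    initialize_state,
    iterate_retrieval,
    rmsrd,
)
from oceanhsrl.retrieval import compute_sensitivity, usable_depth_mask


class TestRmsrd:
    def test_identity_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rmsrd(x, x) == 0.0

    def test_constant_ratio(self):
        ref = np.array([1.0, 2.0, 4.0])
        assert rmsrd(1.1 * ref, ref) == pytest.approx(10.0, abs=1e-12)

    def test_symmetric_deviation(self):
        ref = np.array([1.0, 1.0])
        x = np.array([0.9, 1.1])
        assert rmsrd(x, ref) == pytest.approx(10.0, abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            rmsrd(np.array([1.0]), np.array([0.0]))


class TestInitialization:
    def test_xi_seeded_constant(self, l3_signals, config):
        init = initialize_state(l3_signals, config, xi0=3.5)
        assert np.all(init.xi == 3.5)

    def test_b_floor_clipped_in_clear_water(self, config):
        clear = IOPProfile.homogeneous(0.042, 0.0022, 3.5, max_depth=30)
        sig = forward_analytic(clear, config)
        init = initialize_state(sig, config)
        assert np.all(init.b >= config.water.b_w)

    def test_a0_matches_wide_channel_slope(self, l3_signals, config):
        # a0 is by construction half the negative log-slope of the
        # range-corrected wide molecular channel
        init = initialize_state(l3_signals, config)
        z = l3_signals.depths
        rc = np.log(l3_signals.mol_wide * (config.lidar_height + z) ** 2)
        k_mid = -0.5 * np.polyfit(z[8:13], rc[8:13], 1)[0]
        assert init.a[10] == pytest.approx(k_mid, rel=0.05)

    def test_too_few_bins_rejected(self, config):
        iop = IOPProfile.homogeneous(0.08, 0.4, 3.3, max_depth=3)
        sig = forward_analytic(iop, config)
        with pytest.raises(ValueError):
            initialize_state(sig, config)


@pytest.fixture(scope="module")
def sens(config):
    iop = IOPProfile.homogeneous(0.08, 0.45, 3.3, max_depth=6)
    return compute_sensitivity(forward_analytic, iop, config, step=0.02)


class TestSensitivity:
    def test_surface_absorption_darkens_deeper_bins(self, sens):
        block = sens.block(channel=2, param="a")
        assert np.all(block[1:, 0] < 0)

    def test_deepest_bin_cannot_affect_shallower_signals(self, sens):
        for p in ("a", "b", "xi"):
            block = sens.block(channel=0, param=p)
            assert np.all(block[:-1, -1] == 0.0)

    def test_step_halving_stability(self, config):
        iop = IOPProfile.homogeneous(0.08, 0.45, 3.3, max_depth=6)
        s1 = compute_sensitivity(forward_analytic, iop, config, step=0.02).entries
        s2 = compute_sensitivity(forward_analytic, iop, config, step=0.01).entries
        big = np.abs(s1) > 0.05
        assert np.max(np.abs((s1[big] - s2[big]) / s1[big])) < 0.01

    def test_invalid_step_rejected(self, config):
        iop = IOPProfile.homogeneous(0.08, 0.45, 3.3, max_depth=6)
        with pytest.raises(ValueError):
            compute_sensitivity(forward_analytic, iop, config, step=0.5)


class TestIterateRetrieval:
    def test_fixed_point_at_truth(self, l3_profile, l3_signals, config):
        res = iterate_retrieval(
            l3_signals, config, init=l3_profile, prefit=False, tol=1.0
        )
        assert res.converged
        assert res.n_iterations == 0
        assert res.rmsrd_final < 1e-8

    def test_noiseless_self_inversion(self, config):
        truth = IOPProfile.homogeneous(0.085, 0.55, 3.25, max_depth=30)
        sig = forward_analytic(truth, config)
        res = iterate_retrieval(sig, config, tol=0.01)
        m = len(res.iop)
        for p in ("a", "b", "xi"):
            assert rmsrd(getattr(res.iop, p), getattr(truth, p)[:m]) < 0.5

    def test_stratified_self_inversion_recovers_layers(self, config):
        spec_layers = IOPProfile.homogeneous(0.08, 0.45, 3.3, max_depth=30)
        spec_layers.b[:5] = 0.30  # clearer 5 m surface layer
        spec_layers.a[:5] = 0.06
        sig = forward_analytic(spec_layers, config)
        # light regularization: the noiseless case tolerates sharp steps
        res = iterate_retrieval(
            sig, config, tol=0.02, max_iter=40, smooth=0.05, ridge=0.005
        )
        m = len(res.iop)
        assert rmsrd(res.iop.a, spec_layers.a[:m]) < 8.0
        assert rmsrd(res.iop.b, spec_layers.b[:m]) < 12.0
        # the two-layer structure emerges: deep b exceeds surface b
        assert res.iop.b[:3].mean() < res.iop.b[10:13].mean()

    def test_monotone_progress_over_accepted_steps(self, config):
        truth = IOPProfile.homogeneous(0.09, 0.6, 3.2, max_depth=20)
        sig = forward_analytic(truth, config)
        bad_init = IOPProfile.homogeneous(0.06, 0.3, 3.5, max_depth=20)
        res = iterate_retrieval(
            sig, config, init=bad_init, prefit=False, tol=0.01, max_iter=10
        )
        vals = [t["rmsrd"] for t in res.trajectory]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_bounds_respected(self, l5_mc, config):
        res = iterate_retrieval(l5_mc, config)
        w = config.water
        assert np.all(res.iop.a >= w.a_w) and np.all(res.iop.a <= 2.0)
        assert np.all(res.iop.b >= w.b_w) and np.all(res.iop.b <= 5.0)
        assert np.all(res.iop.xi > 3.0) and np.all(res.iop.xi <= 5.0)

    def test_usable_depth_cut_three_decades(self, config):
        truth = IOPProfile.homogeneous(0.11, 0.75, 3.15, max_depth=30)
        sig = forward_analytic(truth, config)
        mask = usable_depth_mask(sig)
        narrow = sig.mol_narrow
        assert np.all(narrow[mask] > 1e-3 * narrow[:3].max())
        if (~mask).any():
            assert narrow[~mask].max() <= 1e-3 * narrow[:3].max()
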