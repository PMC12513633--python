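"""NFkB SDE core: drift identities, noise antisymmetry, dispersion ordering."""

import numpy as np
import pytest

from endnsde import nfkb


class TestDriftCore:
    def test_hill_vanishes_at_zero(self):
        p = nfkb.NFkBParams()
        u = np.zeros(nfkb.STATE_DIM)
        u[nfkb.IDX_U6] = 0.3
        du6, _, _ = nfkb.sde_drift_core(u, p)
        assert du6[0] == pytest.approx(p.kbasal - p.kdeg * 0.3)

    def test_hill_saturates(self):
        p = nfkb.NFkBParams()
        u = np.zeros(nfkb.STATE_DIM)
        u[nfkb.IDX_U52] = 1e9
        du6, _, _ = nfkb.sde_drift_core(u, p)
        assert du6[0] == pytest.approx(p.kbasal + p.kmax, rel=1e-6)

    @pytest.mark.parametrize("n_hill", [1.0, 2.0, 4.0])
    def test_half_saturation_at_K(self, n_hill):
        p = nfkb.NFkBParams(n_NFkB=n_hill)
        u = np.zeros(nfkb.STATE_DIM)
        u[nfkb.IDX_U52] = p.K_NFkB
        du6, _, _ = nfkb.sde_drift_core(u, p)
        assert du6[0] == pytest.approx(p.kbasal + p.kmax / 2)

    def test_negative_hill_argument_rejected(self):
        u = np.zeros(nfkb.STATE_DIM)
        u[nfkb.IDX_U52] = -0.1
        with pytest.raises(ValueError):
            nfkb.sde_drift_core(u, nfkb.NFkBParams())


class TestSimulate:
    def test_zero_noise_deterministic_and_seed_independent(self):
        p = nfkb.NFkBParams(sigma1=0.0, sigma2=0.0)
        times = nfkb.default_times(11)
        a = nfkb.simulate(p, None, nfkb.default_u0(), times, 3, seed=1)
        b = nfkb.simulate(p, None, nfkb.default_u0(), times, 5, seed=99)
        assert np.allclose(a.values[0], a.values[1])
        assert np.allclose(a.values[0], b.values[0])

    def test_translocation_noise_cancels_in_u9_plus_u10(self):
        """One Euler step: the +/- sigma2 dB2 pair leaves u9 + u10 exactly
        as in the noise-free step (shared Wiener increment, opposite signs)."""
        u0 = nfkb.default_u0()
        times = np.array([0.0, 0.2])
        noisy = nfkb.simulate(nfkb.NFkBParams(sigma1=0.0, sigma2=0.3), None,
                              u0, times, 200, seed=7, clamp=False, substeps=1)
        quiet = nfkb.simulate(nfkb.NFkBParams(sigma1=0.0, sigma2=0.0), None,
                              u0, times, 200, seed=7, clamp=False, substeps=1)
        s_noisy = noisy.values[:, 1, nfkb.IDX_U9] + noisy.values[:, 1, nfkb.IDX_U10]
        s_quiet = quiet.values[:, 1, nfkb.IDX_U9] + quiet.values[:, 1, nfkb.IDX_U10]
        assert np.allclose(s_noisy, s_quiet, atol=1e-14)
        # while the individual components do fluctuate
        assert noisy.values[:, 1, nfkb.IDX_U10].std() > 0.01

    def test_dispersion_increases_with_noise_intensity(self):
        """Fig-7-style regimes: readout dispersion strictly larger at
        (10^-2.2, 10^-1.5) than at (10^-3.2, 10^-2.5)."""
        times = nfkb.default_times(31)
        lo = nfkb.simulate(nfkb.NFkBParams(sigma1=10**-3.2, sigma2=10**-2.5),
                           None, nfkb.default_u0(), times, 60, seed=3)
        hi = nfkb.simulate(nfkb.NFkBParams(sigma1=10**-2.2, sigma2=10**-1.5),
                           None, nfkb.default_u0(), times, 60, seed=3)
        disp_lo = nfkb.readout(lo).std(axis=0).mean()
        disp_hi = nfkb.readout(hi).std(axis=0).mean()
        assert disp_hi > disp_lo

    def test_mean_converges_to_deterministic_as_noise_vanishes(self):
        times = nfkb.default_times(16)
        det = nfkb.readout(nfkb.representative_trajectory(times=times))[0]
        small = nfkb.simulate(nfkb.NFkBParams(sigma1=1e-5, sigma2=1e-5), None,
                              nfkb.default_u0(), times, 100, seed=11)
        assert np.abs(nfkb.readout(small).mean(axis=0) - det).max() < 1e-3


class TestNoiseGrid:
    def test_default_grid_121_and_contains_corners(self):
        lg1, lg2 = nfkb.default_noise_axes()
        assert len(lg1) == len(lg2) == 11
        grid = nfkb.make_noise_grid(ranges=(lg1[:2], lg2[:2]), seed=0, n_traj=2,
                                    times=nfkb.default_times(4))
        assert len(grid.entries) == 4
        keys = {tuple(np.round(np.log10(k), 6)) for k in
                (np.array(o) for o in nfkb.make_noise_grid(
                    ranges=(lg1, lg2), seed=0, n_traj=1,
                    times=nfkb.default_times(2)).omegas())}
        assert (-3.2, -2.5) in keys and (-2.2, -1.5) in keys
        assert len(keys) == 121

    def test_degenerate_single_point(self):
        grid = nfkb.make_noise_grid(ranges=([-3.0], [-2.0]), seed=0, n_traj=2,
                                    times=nfkb.default_times(3))
        assert len(grid.entries) == 1


class TestExperimentalStandin:
    def test_grid_is_31_points_at_5_minutes(self):
        ens = nfkb.make_experimental_standin(8, [(1e-3, 1e-2)], seed=0)
        assert np.array_equal(ens.times, np.arange(0, 151, 5))
        assert ens.values.shape == (8, 31, 1)
        assert ens.metadata["synthetic_standin"] is True

    def test_mixture_labels_recorded(self):
        levels = [(1e-3, 1e-2), (1e-2, 1e-1)]
        ens = nfkb.make_experimental_standin(32, levels, seed=1,
                                             times=nfkb.default_times(5))
        truth = np.asarray(ens.metadata["true_noise_per_cell"])
        assert truth.shape == (32, 2)
        assert {tuple(r) for r in truth} <= set(levels)
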