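"""Variational Bayes engine tests: conjugate oracle, free energy, spatial
regularization."""

import numpy as np
import pytest

from qbold.models import BloodCompartment, TissuePhysiology
from qbold.simulate import ASESignal, add_noise, build_phantom, simulate_signal
from qbold.infer_ls import forward_model_1c
from qbold.infer_vb import (GaussianPrior, NoisePrior, default_priors,
                            derived_oef_map, vb_fit, vb_fit_spatial)

TRUTH = (4.2595, 0.03, 1.0)


@pytest.fixture(scope="module")
def linear_problem():
    """Affine model y = X theta + e with known noise precision."""
    rng = np.random.default_rng(5)
    x = np.linspace(0.0, 1.0, 30)
    design = np.column_stack([np.ones_like(x), x, x ** 2])
    beta = np.array([1.0, -2.0, 0.5])
    sigma = 0.05
    y = design @ beta + rng.normal(0.0, sigma, x.size)
    return design, y, 1.0 / sigma ** 2


class TestConjugateOracle:
    def test_matches_closed_form_linear_gaussian_posterior(self,
                                                           linear_problem):
        design, y, phi = linear_problem
        prior = GaussianPrior((0.0, 0.0, 0.0), (5.0, 5.0, 5.0))
        # effectively fixed noise precision via a very tight Gamma prior
        tight = NoisePrior(shape=1e8, scale=phi / 1e8)
        fit = vb_fit((np.linspace(-0.01, 0.01, y.size), y),
                     model=lambda th: design @ np.asarray(th),
                     priors=prior, init=prior, noise_prior=tight,
                     init_s0_from_data=False, tol=1e-12, max_iter=100)
        lam = prior.precision + phi * design.T @ design
        cov = np.linalg.inv(lam)
        mean = cov @ (phi * design.T @ y)
        np.testing.assert_allclose(fit.mean, mean, atol=1e-6)
        np.testing.assert_allclose(fit.covariance, cov, atol=1e-6)

    def test_free_energy_monotone_on_linear_model(self, linear_problem):
        design, y, phi = linear_problem
        prior = GaussianPrior((0.0, 0.0, 0.0), (5.0, 5.0, 5.0))
        fit = vb_fit((np.linspace(-0.01, 0.01, y.size), y),
                     model=lambda th: design @ np.asarray(th),
                     priors=prior, init=prior, init_s0_from_data=False,
                     tol=1e-10, max_iter=100)
        diffs = np.diff(fit.free_energy_trace)
        assert np.all(diffs >= -1e-8)

    def test_tight_prior_pins_posterior_to_prior_mean(self, proto):
        y = forward_model_1c(TRUTH, proto.tau, proto)
        sig = ASESignal(tau=proto.tau, amplitude=y)
        prior = GaussianPrior((9.0, 0.08, 1.0), (1e-7, 1e-7, 1e3))
        fit = vb_fit(sig, model="1c", priors=prior, proto=proto)
        assert fit["r2p"] == pytest.approx(9.0, abs=1e-4)
        assert fit["dbv"] == pytest.approx(0.08, abs=1e-6)


class TestRecovery:
    def test_noise_free_recovery_within_tolerance(self, proto):
        y = forward_model_1c(TRUTH, proto.tau, proto)
        sig = ASESignal(tau=proto.tau, amplitude=y)
        fit = vb_fit(sig, model="1c", proto=proto, tol=1e-9, max_iter=300)
        assert fit["r2p"] == pytest.approx(TRUTH[0], rel=1e-6)
        assert fit["dbv"] == pytest.approx(TRUTH[1], rel=1e-6)

    def test_noisy_recovery_reasonable(self, proto, blood, phys,
                                       clean_signal):
        # median behaviour over a handful of noise draws at SNR 100
        r2ps, dbvs = [], []
        for seed in range(5):
            noisy = add_noise(clean_signal, 100, seed)
            fit = vb_fit(noisy, model="2c", blood=blood, proto=proto)
            r2ps.append(fit["r2p"])
            dbvs.append(fit["dbv"])
        assert np.median(r2ps) == pytest.approx(4.26, rel=0.15)
        assert np.median(dbvs) == pytest.approx(0.03, abs=0.015)

    def test_deterministic(self, proto, clean_signal):
        noisy = add_noise(clean_signal, 50, 4)
        f1 = vb_fit(noisy, model="1c", proto=proto)
        f2 = vb_fit(noisy, model="1c", proto=proto)
        np.testing.assert_array_equal(f1.mean, f2.mean)
        assert f1.free_energy == f2.free_energy

    def test_median_dbv_error_below_loglinear(self, proto, blood):
        # qualitative engine ordering at SNR 100 across a spread of truths
        from qbold.infer_ls import fit_loglinear
        rng = np.random.default_rng(17)
        errs_vb, errs_ll = [], []
        for k in range(60):
            oef = rng.uniform(0.25, 0.65)
            dbv = rng.uniform(0.01, 0.12)
            phys = TissuePhysiology(oef=oef, dbv=dbv)
            noisy = add_noise(simulate_signal(phys, blood, proto), 100, rng)
            fit = vb_fit(noisy, model="1c", proto=proto)
            ll = fit_loglinear(noisy, proto)
            errs_vb.append(abs(fit["dbv"] - dbv))
            if np.isfinite(ll.dbv):
                errs_ll.append(abs(ll.dbv - dbv))
        assert np.median(errs_vb) < np.median(errs_ll)


class TestFreeEnergy:
    def test_corrupted_data_lowers_free_energy(self, proto, clean_signal):
        rng = np.random.default_rng(21)
        noisy = add_noise(clean_signal, 100, 1)
        f_clean = vb_fit(noisy, model="1c", proto=proto).free_energy
        bad = noisy.amplitude.copy()
        bad[::2] = rng.normal(0.2, 0.2, bad[::2].size)  # structureless half
        f_bad = vb_fit(ASESignal(tau=proto.tau, amplitude=bad), model="1c",
                       proto=proto).free_energy
        assert f_bad < f_clean

    def test_accepted_iterations_never_drop_free_energy(self, proto,
                                                        clean_signal):
        noisy = add_noise(clean_signal, 20, 9)
        fit = vb_fit(noisy, model="2c", proto=proto, tol=1e-6,
                     max_iter=100)
        diffs = np.diff(fit.free_energy_trace)
        assert np.all(diffs >= -1e-6)


@pytest.fixture(scope="module")
def homogeneous_phantom():
    return build_phantom((4, 4, 2), 0.4, 0.03, snr=25, seed=8)


class TestSpatial:

    def test_zero_iterations_reproduces_voxelwise_fit(self,
                                                      homogeneous_phantom,
                                                      proto):
        ph = homogeneous_phantom
        maps0 = vb_fit_spatial(ph["data"], ph["mask"], proto, n_iter=0)
        sig = ASESignal(tau=proto.tau, amplitude=ph["data"][0, 0, 0])
        single = vb_fit(sig, model="1c", proto=proto)
        assert maps0["r2p"][0, 0, 0] == pytest.approx(single["r2p"],
                                                      rel=1e-12)
        assert maps0["free_energy"][0, 0, 0] == pytest.approx(
            single.free_energy, rel=1e-12)

    def test_spatial_prior_shrinks_across_voxel_sd(self,
                                                   homogeneous_phantom,
                                                   proto):
        ph = homogeneous_phantom
        maps0 = vb_fit_spatial(ph["data"], ph["mask"], proto, n_iter=0)
        maps = vb_fit_spatial(ph["data"], ph["mask"], proto, n_iter=5)
        sd0 = np.nanstd(maps0["r2p"])
        sd = np.nanstd(maps["r2p"])
        assert sd < sd0
        # regularization must not shift the region mean appreciably
        assert np.nanmean(maps["r2p"]) == pytest.approx(
            np.nanmean(maps0["r2p"]), rel=0.05)

    def test_two_region_means_preserved(self, proto):
        # regularization must smooth within regions without dragging the
        # two region means toward each other by more than 5%
        oef_field = np.full((16, 3, 1), 0.30)
        oef_field[8:] = 0.60
        ph = build_phantom((16, 3, 1), oef_field, 0.05, snr=50, seed=12)
        maps0 = vb_fit_spatial(ph["data"], ph["mask"], proto, n_iter=0)
        maps = vb_fit_spatial(ph["data"], ph["mask"], proto, n_iter=5)
        for sl in (slice(None, 8), slice(8, None)):
            assert np.nanmean(maps["r2p"][sl]) == pytest.approx(
                np.nanmean(maps0["r2p"][sl]), rel=0.05)

    def test_isolated_voxel_keeps_global_prior(self, proto):
        mask = np.zeros((3, 3, 1), dtype=bool)
        mask[0, 0, 0] = True  # no neighbours
        ph = build_phantom((3, 3, 1), 0.4, 0.03, snr=50, seed=3, mask=mask)
        maps = vb_fit_spatial(ph["data"], mask, proto, n_iter=2)
        assert np.isfinite(maps["r2p"][0, 0, 0])
        assert np.isnan(maps["r2p"][1, 1, 0])


class TestDerivedOEFMap:
    def test_uniform_maps_give_scalar_value(self, proto):
        from qbold.models import oef_from_r2p
        r2p = np.full((2, 2, 1), 3.0)
        dbv = np.full((2, 2, 1), 0.04)
        oef_map, qc = derived_oef_map(r2p, dbv, 0.40, proto)
        np.testing.assert_allclose(oef_map,
                                   oef_from_r2p(3.0, 0.04, 0.40, proto),
                                   rtol=1e-12)
        assert qc == 0.0

    def test_masked_and_nonpositive_dbv_are_missing(self, proto):
        r2p = np.full((2, 2, 1), 3.0)
        dbv = np.array([[[0.04], [0.0]], [[0.04], [0.04]]])
        mask = np.ones((2, 2, 1), dtype=bool)
        mask[1, 1, 0] = False
        oef_map, _ = derived_oef_map(r2p, dbv, 0.40, proto, mask=mask)
        assert np.isnan(oef_map[0, 1, 0])   # DBV <= 0
        assert np.isnan(oef_map[1, 1, 0])   # outside mask
        assert np.isfinite(oef_map[0, 0, 0])

    def test_qc_fraction_counts_unphysical_voxels(self, proto):
        r2p = np.full((4, 1, 1), 3.0)
        dbv = np.array([0.04, 0.04, 0.001, 0.002]).reshape(4, 1, 1)
        _, qc = derived_oef_map(r2p, dbv, 0.40, proto)
        # DBV 0.001, 0.002 imply OEF far above 100%
        assert qc == pytest.approx(0.5)
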