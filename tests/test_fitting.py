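"""Parameter estimation: per-q and global fits, scans, calibration."""

import numpy as np
import pytest

import vesiclense as v
from vesiclense.errors import ConfigurationError


def _simulate(kappa_kT, radius=60e-9, poly=0.25, sigma=0.0, noise=0.02,
              seed=0, diffusion=None, grid=None):
    p = v.MembraneParams.from_kT(kappa_kT, sigma=sigma)
    pop = v.VesiclePopulation(mean_radius=radius, polydispersity=poly)
    diff = diffusion if diffusion is not None else v.DiffusionSpec()
    grid = grid or v.make_grid("standard")
    ds = v.simulate_dataset(p, pop, diff, grid, noise_level=noise, seed=seed)
    return ds, p, pop, diff


class TestPerQ:
    def test_noiseless_recovery_at_every_q(self):
        ds, p, pop, diff = _simulate(140.0, noise=0.0)
        res = v.fit_kappa_per_q(ds, p.replace(kappa_tilde=50 * p.kT), pop, diff)
        assert np.allclose(res.frame["kappa_kT"], 140.0, rtol=1e-3)
        assert (res.frame["flag"] == "ok").all()

    def test_noisy_recovery_at_high_q(self):
        """2% noise, fixed seed: every high-q estimate agrees with truth
        within 3 reported sigma, and their inverse-variance weighted mean
        is within 5%."""
        ds, p, pop, diff = _simulate(140.0, noise=0.02, seed=1)
        res = v.fit_kappa_per_q(ds, p.replace(kappa_tilde=50 * p.kT), pop, diff)
        high = res.frame[res.frame["q_invA"] >= 0.05]
        dev = np.abs(high["kappa_kT"] - 140.0)
        assert np.all(dev <= 3.0 * high["kappa_err_kT"])
        w = 1.0 / high["kappa_err_kT"] ** 2
        mean = np.sum(w * high["kappa_kT"]) / np.sum(w)
        assert mean == pytest.approx(140.0, rel=0.05)

    def test_pure_diffusion_drives_rigidity_to_upper_bound(self, grid_standard):
        """Data with no undulation signal: the rigidity runs into its upper
        bound and is flagged."""
        p = v.MembraneParams.from_kT(100.0)
        pop = v.VesiclePopulation(mean_radius=60e-9)
        D = v.stokes_einstein(60e-9, p.eta_out, p.temperature)
        q_col, t_col, s_col, e_col = [], [], [], []
        for i, q in enumerate(grid_standard.q_values):
            t = grid_standard.t_values[i]
            q_col.append(np.full_like(t, q)); t_col.append(t)
            s_col.append(np.exp(-D * q**2 * t)); e_col.append(np.full_like(t, 0.01))
        ds = v.RelaxationDataset.from_arrays(
            np.concatenate(q_col), np.concatenate(t_col),
            np.concatenate(s_col), np.concatenate(e_col))
        res = v.fit_kappa_per_q(ds, p, pop,
                                v.DiffusionSpec(mode="fixed", fixed_D=D))
        assert (res.frame["flag"] == "at_bound").all()
        assert np.all(res.frame["kappa_kT"] > 0.9e5)

    def test_summary_lists_fixed_parameters(self):
        ds, p, pop, diff = _simulate(140.0, noise=0.0)
        res = v.fit_kappa_per_q(ds, p, pop, diff)
        text = res.summary()
        assert "sigma_N_per_m (fixed)" in text
        assert "eta_m_Pa_s_m (fixed)" in text


class TestGlobal:
    def test_chi2_vanishes_on_noiseless_data(self):
        ds, p, pop, diff = _simulate(140.0, noise=0.0)
        res = v.fit_global(ds, ("kappa_tilde",),
                           p.replace(kappa_tilde=50 * p.kT), pop, diff)
        assert res.chi2 < 1e-10
        assert res.kappa_tilde_kT == pytest.approx(140.0, rel=1e-6)

    def test_isosmotic_tension_consistent_with_zero(self):
        ds, p, pop, diff = _simulate(140.0, sigma=0.0, noise=0.02, seed=4)
        res = v.fit_global(ds, ("kappa_tilde", "sigma"),
                           p.replace(kappa_tilde=50 * p.kT), pop, diff)
        assert res.bse is not None
        assert abs(res.params["sigma"]) <= 2.0 * res.bse["sigma"]

    def test_laplace_consistent_tension_recovered(self):
        sigma_truth = v.laplace_tension(v.vant_hoff_pressure(40.0, 298.15),
                                        60e-9)
        ds, p, pop, diff = _simulate(140.0, sigma=sigma_truth, noise=0.02,
                                     seed=3)
        res = v.fit_global(ds, ("kappa_tilde", "sigma"),
                           p.replace(sigma=0.0, kappa_tilde=50 * p.kT),
                           pop, diff)
        assert res.params["sigma"] == pytest.approx(sigma_truth, rel=0.10)

    def test_rigidity_viscosity_degeneracy_warns(self):
        ds, p, pop, diff = _simulate(140.0, noise=0.02, seed=5)
        model = v.SphericalVesicleModel(ds, p.replace(kappa_tilde=50 * p.kT),
                                        pop, diff)
        with pytest.warns(UserWarning, match="degenerate"):
            res = model.fit(free=("kappa_tilde", "eta_m"))
        assert any("degenerate" in m for m in res.messages)
        assert res.correlation is not None

    def test_at_most_two_free_parameters(self):
        ds, p, pop, diff = _simulate(140.0, noise=0.0)
        model = v.SphericalVesicleModel(ds, p, pop, diff)
        with pytest.raises(ConfigurationError):
            model.fit(free=("kappa_tilde", "sigma", "eta_m"))

    def test_one_sigma_coverage_calibrated(self):
        """Reported 1-sigma intervals cover the truth in roughly 68% of 20
        noise replicates (binomial tolerance: 9 to 18 hits)."""
        hits = 0
        for seed in range(20):
            ds, p, pop, diff = _simulate(140.0, noise=0.02, seed=100 + seed)
            res = v.fit_global(ds, ("kappa_tilde",),
                               p.replace(kappa_tilde=50 * p.kT), pop, diff)
            err = res.bse_kT()
            assert err is not None and err > 0
            if abs(res.kappa_tilde_kT - 140.0) <= err:
                hits += 1
        assert 9 <= hits <= 18


class TestViscosityScan:
    def test_zero_grid_matches_plain_fit(self):
        ds, p, pop, diff = _simulate(140.0, noise=0.02, seed=6)
        start = p.replace(kappa_tilde=50 * p.kT)
        table = v.viscosity_scan(ds, [0.0], start, pop, diff)
        res = v.fit_global(ds, ("kappa_tilde",), start, pop, diff)
        assert table["kappa_kT"].iloc[0] == pytest.approx(
            res.kappa_tilde_kT, rel=1e-6)

    def test_fitted_rigidity_decreases_with_imposed_viscosity(self):
        ds, p, pop, diff = _simulate(140.0, noise=0.02, seed=6)
        table = v.viscosity_scan(ds, [0.0, 1e-11, 1e-10, 1e-9],
                                 p.replace(kappa_tilde=50 * p.kT), pop, diff)
        kap = table["kappa_kT"].to_numpy()
        assert np.all(np.diff(kap) < 0)

    def test_sizes_diverge_under_imposed_viscosity(self):
        """With eta_m = 0 truth, imposing a membrane viscosity biases small
        vesicles much more than large ones, so rigidity estimates split
        between sizes as the imposed value grows."""
        grid = v.make_grid("standard")
        estimates = {}
        for radius in (30e-9, 100e-9):
            ds, p, pop, diff = _simulate(140.0, radius=radius, noise=0.02,
                                         seed=7, grid=grid)
            table = v.viscosity_scan(ds, [0.0, 1e-9],
                                     p.replace(kappa_tilde=50 * p.kT),
                                     pop, diff)
            estimates[radius] = table["kappa_kT"].to_numpy()
        gap_zero = abs(estimates[30e-9][0] - estimates[100e-9][0])
        gap_imposed = abs(estimates[30e-9][1] - estimates[100e-9][1])
        assert gap_imposed > 4 * gap_zero
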