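"""Free-energy profiles, WHAM, error estimators, and basin analytics."""

import numpy as np
import pytest

import dimerbend as db
from dimerbend import free_energy as fe
from dimerbend.exceptions import (
    ConnectivityError,
    DegeneracyError,
    InputError,
    InsufficientDataError,
    NoBarrierError,
    OutOfRangeError,
)


class TestPmfFromProjection:
    def test_single_occupied_bin(self):
        prof = fe.pmf_from_projection(np.full(100, 0.5), bins=10, range_=(0, 1))
        assert prof.occupied.sum() == 1
        assert prof.G[prof.occupied][0] == 0.0
        assert np.isnan(prof.G[~prof.occupied]).all()

    def test_gaussian_boltzmann_inversion(self):
        z = np.random.default_rng(0).standard_normal(1_000_000)
        prof = fe.pmf_from_projection(z, bins=100)
        sel = prof.occupied & (np.abs(prof.axis) <= 2)
        expected = prof.axis[sel] ** 2 / 2
        np.testing.assert_allclose(prof.G[sel], expected, atol=0.05)

    def test_count_doubling_invariance(self):
        z = np.random.default_rng(1).standard_normal(2000)
        edges = np.histogram_bin_edges(z, bins=30)
        p1 = fe.pmf_from_projection(z, bins=edges)
        p2 = fe.pmf_from_projection(np.concatenate([z, z]), bins=edges)
        np.testing.assert_allclose(p1.G, p2.G, equal_nan=True)

    def test_empty_projection_raises(self):
        with pytest.raises(InputError):
            fe.pmf_from_projection(np.array([]))

    def test_two_dimensional_surface(self):
        rng = np.random.default_rng(2)
        xy = rng.standard_normal((50_000, 2))
        prof = fe.pmf_from_projection(xy, bins=20)
        assert prof.G.shape == (20, 20)
        assert np.nanmin(prof.G) == 0.0


class TestBiasEnergy:
    def test_arithmetic(self):
        w = fe.UmbrellaWindow(center=1.0, spring_k=100.0, series=np.zeros(10))
        assert fe.bias_energy(1.0, w) == 0.0
        assert fe.bias_energy(1.1, w) == pytest.approx(0.5)
        assert fe.bias_energy(0.9, w) == pytest.approx(0.5)


class TestWham:
    def test_single_unbiased_window_flat_potential(self):
        z = np.random.default_rng(3).uniform(0, 1, 100_000)
        w = fe.UmbrellaWindow(center=0.5, spring_k=0.0, series=z)
        prof = fe.wham([w], bins=20)
        assert np.nanmax(np.abs(prof.G[prof.occupied])) < 0.2

    def test_single_window_equals_boltzmann_inversion(self):
        z = np.random.default_rng(4).standard_normal(50_000)
        edges = np.histogram_bin_edges(z, bins=50)
        w = fe.UmbrellaWindow(center=0.0, spring_k=0.0, series=z)
        p_wham = fe.wham([w], bins=edges)
        p_inv = fe.pmf_from_projection(z, bins=edges)
        np.testing.assert_allclose(p_wham.G, p_inv.G, atol=1e-10, equal_nan=True)

    def test_harmonic_oracle(self):
        # true potential 1 kT/nm^2 (2.494 kJ/mol/nm^2 at 300 K)
        pot = db.ToyPotential(form="harmonic", stiffness=1.0)
        centers = np.linspace(-2.4, 2.4, 7)
        windows = db.gen_umbrella_windows(pot, centers, spring_k=50.0,
                                          n_steps=20_000, step_size=0.3,
                                          discard=1_000, seed=5)
        prof = fe.wham(windows, bins=60)
        truth = db.analytic_pmf(pot, prof.axis)
        occ = prof.occupied
        rms = np.sqrt(np.mean((prof.G[occ] - truth.G[occ]) ** 2))
        assert rms < 0.2

    def test_double_well_barrier(self, double_well, double_well_windows):
        prof = fe.wham(double_well_windows, bins=100)
        occ = prof.occupied
        center_bin = np.argmin(np.abs(prof.axis[occ]))
        barrier = prof.G[occ][center_bin]
        assert barrier == pytest.approx(5.0, abs=0.3)

    def test_bias_constant_invariance(self, double_well_windows):
        prof0 = fe.wham(double_well_windows, bins=40)
        offsets = np.zeros(len(double_well_windows))
        offsets[3] = 7.5  # kJ/mol added to one window's bias
        prof1 = fe.wham(double_well_windows, bins=40, bias_offsets=offsets)
        np.testing.assert_allclose(prof0.G, prof1.G, atol=1e-5, equal_nan=True)

    def test_more_sampling_reduces_oracle_error(self, double_well):
        centers = np.linspace(-1.6, 1.6, 11)

        def rms_error(n_steps, seed):
            ws = db.gen_umbrella_windows(double_well, centers, spring_k=100.0,
                                         n_steps=n_steps, step_size=0.25,
                                         discard=500, seed=seed)
            prof = fe.wham(ws, bins=60)
            occ = prof.occupied
            truth = db.analytic_pmf(double_well, prof.axis)
            return np.sqrt(np.mean((prof.G[occ] - truth.G[occ]) ** 2))

        small = np.mean([rms_error(3_000, s) for s in (11, 12)])
        large = np.mean([rms_error(12_000, s) for s in (11, 12)])
        assert large < small

    def test_disconnected_windows_raise(self):
        rng = np.random.default_rng(6)
        w1 = fe.UmbrellaWindow(center=0.0, spring_k=500.0,
                               series=rng.normal(0, 0.02, 2000))
        w2 = fe.UmbrellaWindow(center=5.0, spring_k=500.0,
                               series=rng.normal(5, 0.02, 2000))
        with pytest.raises(ConnectivityError):
            fe.wham([w1, w2], bins=100)


class TestAutocorrTime:
    def test_white_noise_half(self):
        z = np.random.default_rng(7).standard_normal(50_000)
        assert fe.autocorr_time(z) == pytest.approx(0.5, abs=0.1)

    def test_ar1_closed_form(self):
        phi = 0.9
        rng = np.random.default_rng(8)
        e = rng.standard_normal(200_000)
        z = np.empty_like(e)
        z[0] = 0.0
        for t in range(1, z.size):
            z[t] = phi * z[t - 1] + e[t]
        expected = (1 + phi) / (2 * (1 - phi))
        assert fe.autocorr_time(z) == pytest.approx(expected, rel=0.15)

    def test_constant_shift_invariance(self):
        z = np.random.default_rng(9).standard_normal(5_000)
        assert fe.autocorr_time(z) == pytest.approx(fe.autocorr_time(z + 100.0),
                                                    abs=1e-8)

    def test_constant_series_raises(self):
        with pytest.raises(DegeneracyError):
            fe.autocorr_time(np.ones(500))


class TestBlockSize:
    def test_formula(self):
        assert fe.block_size(10_000, 4.5) == 1000

    def test_iid_limit(self):
        assert fe.block_size(1000, 0.0) == 1000

    def test_monotone_decreasing_in_tau(self):
        sizes = [fe.block_size(10_000, tau) for tau in (0.0, 1.0, 5.0, 20.0)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestMeanForceError:
    def _iid_windows(self, seeds, sigma=0.1, T=10_000):
        return [
            fe.UmbrellaWindow(center=float(i), spring_k=100.0,
                              series=np.random.default_rng(s).normal(i, sigma, T))
            for i, s in enumerate(seeds)
        ]

    def test_iid_matches_sigma_over_sqrt_T(self):
        df = fe.mean_force_error(self._iid_windows(range(5)))
        target = 0.1 / np.sqrt(10_000)
        assert np.mean(df["se_mean_z"]) == pytest.approx(target, rel=0.2)

    def test_correlation_inflates_error(self):
        phi = 0.9
        rng = np.random.default_rng(20)
        e = rng.standard_normal(20_000)
        z = np.empty_like(e)
        z[0] = 0.0
        for t in range(1, z.size):
            z[t] = phi * z[t - 1] + e[t]
        w = fe.UmbrellaWindow(center=0.0, spring_k=100.0, series=z)
        df = fe.mean_force_error([w])
        naive = z.std() / np.sqrt(z.size)
        assert df["se_mean_z"].iloc[0] > naive

    def test_identical_windows_identical_errors(self):
        z = np.random.default_rng(21).standard_normal(5_000)
        ws = [fe.UmbrellaWindow(center=0.0, spring_k=50.0, series=z.copy()),
              fe.UmbrellaWindow(center=0.0, spring_k=50.0, series=z.copy())]
        df = fe.mean_force_error(ws)
        assert df["se_mean_z"].iloc[0] == df["se_mean_z"].iloc[1]

    def test_too_few_samples_raise(self):
        w = fe.UmbrellaWindow(center=0.0, spring_k=50.0,
                              series=np.random.default_rng(0).standard_normal(120),
                              tau=0.0)  # block size = T leaves a single block
        with pytest.raises(InsufficientDataError):
            fe.mean_force_error([w], min_blocks=1)


class TestBootstrapProfileError:
    def test_degenerate_weights_zero_error(self, double_well_windows):
        prof = fe.wham(double_well_windows, bins=40)
        err = fe.bootstrap_profile_error(double_well_windows, bins=40,
                                         n_boot=3, seed=0, equal_weights=True)
        assert np.nanmax(err[prof.occupied]) < 1e-12

    def test_barrier_error_exceeds_minima_error(self, double_well_windows):
        prof = fe.wham(double_well_windows, bins=40)
        err = fe.bootstrap_profile_error(double_well_windows, bins=40,
                                         n_boot=50, seed=1)
        occ = prof.occupied
        axis = prof.axis[occ]
        e = err[occ]
        barrier_err = e[np.argmin(np.abs(axis))]
        minima_err = 0.5 * (e[np.argmin(np.abs(axis + 1))] +
                            e[np.argmin(np.abs(axis - 1))])
        assert barrier_err > minima_err

    def test_error_shrinks_with_more_sampling(self, double_well):
        centers = np.linspace(-1.6, 1.6, 11)

        def mean_err(n_steps, seed):
            ws = db.gen_umbrella_windows(double_well, centers, spring_k=100.0,
                                         n_steps=n_steps, step_size=0.25,
                                         discard=500, seed=seed)
            err = fe.bootstrap_profile_error(ws, bins=30, n_boot=25, seed=seed)
            return np.nanmean(err)

        small = np.mean([mean_err(2_000, s) for s in (30, 31)])
        large = np.mean([mean_err(8_000, s) for s in (30, 31)])
        assert large < small


class TestBasins:
    def _tilted_double_well(self, tilt):
        grid = np.linspace(-1.6, 1.6, 400)
        G = 5 * (grid**2 - 1) ** 2 + tilt * grid
        return grid, G

    def test_symmetric_well_equal_depths(self):
        grid, G = self._tilted_double_well(0.0)
        prof = fe.FreeEnergyProfile(grid, G - G.min(), np.zeros_like(G),
                                    np.ones_like(G, bool))
        res = db.basin_analysis(prof)
        assert res.ddg == pytest.approx(0.0, abs=0.05)
        assert res.dg_basin_1 == pytest.approx(res.dg_basin_2, abs=0.05)
        assert res.dg_basin_1 < 0

    def test_planted_depth_difference(self):
        # analytic depth difference: minimize the tilted quartic on each side
        from scipy.optimize import minimize_scalar

        tilt = 1.5
        grid, G = self._tilted_double_well(tilt)
        fn = lambda z: 5 * (z**2 - 1) ** 2 + tilt * z
        m1 = minimize_scalar(fn, bounds=(-1.5, 0), method="bounded").fun
        m2 = minimize_scalar(fn, bounds=(0, 1.5), method="bounded").fun
        analytic_ddg = m1 - m2
        prof = fe.FreeEnergyProfile(grid, G - G.min(), np.zeros_like(G),
                                    np.ones_like(G, bool))
        res = db.basin_analysis(prof)
        assert res.ddg == pytest.approx(analytic_ddg, abs=0.3)

    def test_mirror_flips_sign(self):
        grid, G = self._tilted_double_well(1.5)
        prof = fe.FreeEnergyProfile(grid, G - G.min(), np.zeros_like(G),
                                    np.ones_like(G, bool))
        mirrored = fe.FreeEnergyProfile(grid, (G - G.min())[::-1].copy(),
                                        np.zeros_like(G), np.ones_like(G, bool))
        r1 = db.basin_analysis(prof)
        r2 = db.basin_analysis(mirrored)
        assert r1.ddg == pytest.approx(-r2.ddg, abs=1e-9)

    def test_single_basin_raises(self):
        grid = np.linspace(-1, 1, 100)
        G = grid**2
        prof = fe.FreeEnergyProfile(grid, G, np.zeros_like(G),
                                    np.ones_like(G, bool))
        with pytest.raises(NoBarrierError):
            db.basin_analysis(prof)

    def test_explicit_split_matches_auto_on_clean_profile(self):
        grid, G = self._tilted_double_well(1.5)
        prof = fe.FreeEnergyProfile(grid, G - G.min(), np.zeros_like(G),
                                    np.ones_like(G, bool))
        auto = db.basin_analysis(prof, split="auto")
        manual = db.basin_analysis(prof, split=auto.barrier_position)
        assert manual.ddg == pytest.approx(auto.ddg, abs=0.05)


class TestPopulations:
    def test_printed_basin_arithmetic(self):
        # depths relative to the transition state, as reported: -11.5, -20.1
        ddg = -11.5 - (-20.1)
        assert ddg == pytest.approx(8.6)
        assert db.population_fraction(ddg) == pytest.approx(0.9998, abs=5e-5)

    def test_zero_and_unit_ddg(self):
        assert db.population_fraction(0.0) == 0.5
        assert db.population_fraction(1.0) == pytest.approx(1 / (1 + np.exp(-1)))

    def test_two_state_fractions_sum_to_one(self):
        for ddg in (-3.2, 0.0, 1.0, 8.6):
            p1, p2 = db.population_fractions(ddg)
            assert p1 + p2 == pytest.approx(1.0, abs=1e-15)
            assert max(p1, p2) == db.population_fraction(ddg)


class TestKinkEnergy:
    def test_global_minimum_is_zero(self, double_well_windows):
        prof = fe.wham(double_well_windows, bins=60)
        occ = prof.occupied
        pos = prof.axis[occ][np.nanargmin(prof.G[occ])]
        assert db.kink_energy(prof, pos) == 0.0

    def test_harmonic_two_sigma(self):
        # harmonic profile, position at 2 sigma -> 2 kT
        pot = db.ToyPotential(form="harmonic", stiffness=1.0)
        centers = np.linspace(-2.6, 2.6, 9)
        windows = db.gen_umbrella_windows(pot, centers, spring_k=50.0,
                                          n_steps=15_000, step_size=0.3,
                                          discard=1_000, seed=40)
        prof = fe.wham(windows, bins=60)
        assert db.kink_energy(prof, 2.0) == pytest.approx(2.0, abs=0.2)

    def test_out_of_range_raises(self, double_well_windows):
        prof = fe.wham(double_well_windows, bins=60)
        with pytest.raises(OutOfRangeError):
            db.kink_energy(prof, 50.0)


class TestBondEnergyBudget:
    def test_printed_sum(self):
        assert db.bond_energy_budget(-16.8, -3.6) == pytest.approx(-20.4)

    def test_zero_and_commutativity(self):
        assert db.bond_energy_budget(0.0, 0.0) == 0.0
        assert db.bond_energy_budget(-2.0, -5.0) == db.bond_energy_budget(-5.0, -2.0)
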