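"""Ensemble-separation search: densities, overlap, scans, full search."""

import numpy as np
import pytest
from scipy.integrate import quad

import dimerbend as db
from dimerbend import rc_search as rcs
from dimerbend.ensemble_io import FlatEnsemble
from dimerbend.exceptions import ConfigurationError, DegeneracyError


def _flat(X):
    X = np.asarray(X, dtype=float)
    return FlatEnsemble(X=X, mean=X.mean(axis=0))


class TestProjectedDensity:
    def test_two_point_population_moments(self):
        mu, sigma = rcs.projected_density([-1.0, 1.0], "gaussian")
        assert (mu, sigma) == (0.0, 1.0)

    def test_large_sample_moments(self):
        z = np.random.default_rng(0).standard_normal(100_000)
        mu, sigma = rcs.projected_density(z, "gaussian")
        assert abs(mu) < 0.02 and abs(sigma - 1) < 0.02

    def test_constant_samples_degenerate_gaussian(self):
        with pytest.raises(DegeneracyError):
            rcs.projected_density(np.ones(10), "gaussian")

    def test_histogram_constant_single_occupied_bin(self):
        edges, dens = rcs.projected_density(np.full(50, 2.0), "histogram")
        occupied = dens > 0
        assert occupied.sum() == 1
        width = np.diff(edges)[occupied][0]
        assert dens[occupied][0] == pytest.approx(1.0 / width)

    def test_histogram_integrates_to_one(self):
        z = np.random.default_rng(1).standard_normal(5000)
        edges, dens = rcs.projected_density(z, "histogram")
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)


class TestOverlap:
    def test_identical_standard_normals_closed_form(self):
        assert rcs.gaussian_overlap(0, 1, 0, 1) == pytest.approx(
            1 / (2 * np.sqrt(np.pi)), abs=1e-12)

    def test_separated_gaussians_closed_form(self):
        assert rcs.gaussian_overlap(0, 1, 4, 1) == pytest.approx(
            np.exp(-4) / np.sqrt(4 * np.pi), abs=1e-12)

    def test_closed_form_matches_quadrature_20_random_sets(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            mu1, mu2 = rng.uniform(-3, 3, 2)
            s1, s2 = rng.uniform(0.2, 2.5, 2)

            def integrand(z):
                g1 = np.exp(-((z - mu1) ** 2) / (2 * s1**2)) / (s1 * np.sqrt(2 * np.pi))
                g2 = np.exp(-((z - mu2) ** 2) / (2 * s2**2)) / (s2 * np.sqrt(2 * np.pi))
                return g1 * g2

            numeric, _ = quad(integrand, -30, 30, limit=200)
            assert rcs.gaussian_overlap(mu1, s1, mu2, s2) == pytest.approx(
                numeric, abs=1e-8)

    def test_closed_form_properties_hypothesis(self):
        from hypothesis import given, settings, strategies as st

        params = st.floats(-10, 10), st.floats(0.05, 5), st.floats(-10, 10), st.floats(0.05, 5)

        @settings(derandomize=True, max_examples=100)
        @given(*params)
        def check(mu1, s1, mu2, s2):
            o = rcs.gaussian_overlap(mu1, s1, mu2, s2)
            # nonnegative (0 reachable by underflow at huge separations),
            # bounded by the identical-narrow-gaussian self-overlap
            assert 0 <= o <= 1 / (2 * np.sqrt(np.pi) * min(s1, s2)) + 1e-12
            assert o == rcs.gaussian_overlap(mu2, s2, mu1, s1)  # symmetric
            # shifting both means together changes nothing
            assert o == pytest.approx(
                rcs.gaussian_overlap(mu1 + 3, s1, mu2 + 3, s2), rel=1e-12)

        check()

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        z1 = rng.standard_normal(500)
        z2 = rng.standard_normal(500) + 1.0
        for model in ("gaussian", "histogram"):
            assert rcs.overlap(z1, z2, model) == rcs.overlap(z2, z1, model)

    def test_invariant_under_sign_flip_and_shift(self):
        # O depends on n only through the projections; flipping n or rigidly
        # shifting both ensembles must not change it
        rng = np.random.default_rng(3)
        X1 = rng.standard_normal((400, 5))
        X2 = rng.standard_normal((400, 5)) + 0.5
        n = rng.standard_normal(5)
        n /= np.linalg.norm(n)
        o1 = rcs.overlap(X1 @ n, X2 @ n)
        o2 = rcs.overlap(X1 @ -n, X2 @ -n)
        shift = rng.standard_normal(5)
        o3 = rcs.overlap((X1 + shift) @ n, (X2 + shift) @ n)
        assert o1 == pytest.approx(o2, abs=1e-12)
        assert o1 == pytest.approx(o3, abs=1e-9)


class TestRandomUnitVectors:
    def test_unit_norm(self):
        v = rcs.random_unit_vectors(7, 100, seed=0)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_seed_determinism(self):
        np.testing.assert_array_equal(rcs.random_unit_vectors(4, 10, seed=5),
                                      rcs.random_unit_vectors(4, 10, seed=5))

    def test_sphere_uniformity_mean_near_zero(self):
        v = rcs.random_unit_vectors(3, 100_000, seed=1)
        assert np.all(np.abs(v.mean(axis=0)) < 0.02)


class TestRunScan:
    def test_planted_axis_recovery(self):
        rng = np.random.default_rng(4)
        p1 = rng.standard_normal((2000, 5))
        p2 = rng.standard_normal((2000, 5))
        p1[:, 0] -= 5.0
        p2[:, 0] += 5.0
        cfg = db.SeparationSearchConfig(d=5, n_vectors=200, seed=0)
        v, o = rcs.run_scan(p1, p2, cfg, seed=0)
        assert abs(v[0]) > 0.99

    def test_refined_not_worse_than_best_candidate(self):
        rng = np.random.default_rng(5)
        p1 = rng.standard_normal((500, 4))
        p2 = rng.standard_normal((500, 4)) + [2, 0, 0, 0]
        cfg = db.SeparationSearchConfig(d=4, n_vectors=50, seed=1)
        obj = rcs._GaussianObjective(p1, p2)
        cands = rcs.random_unit_vectors(4, 50, np.random.default_rng(1))
        best_random = obj.batch(cands).min()
        _, o = rcs._run_scan(obj, 4, cfg, np.random.default_rng(1))
        assert o <= best_random + 1e-12

    def test_identical_clouds_hit_self_overlap(self):
        rng = np.random.default_rng(6)
        p = rng.standard_normal((4000, 3))
        cfg = db.SeparationSearchConfig(d=3, n_vectors=100, seed=2)
        _, o = rcs.run_scan(p, p.copy(), cfg, seed=2)
        # self-overlap of a unit gaussian is 1/(2 sqrt(pi) sigma)
        assert o == pytest.approx(1 / (2 * np.sqrt(np.pi)), rel=0.1)


class TestSearchSeparationRc:
    def test_planted_direction_recovery(self, planted_pair):
        cfg = db.SeparationSearchConfig(d=10, n_scans=10, n_vectors=200, seed=3)
        res = db.search_separation_rc(planted_pair["a"], planted_pair["b"], cfg)
        assert abs(res.n_hat @ planted_pair["v"]) > 0.99
        assert abs(np.linalg.norm(res.n_hat) - 1) < 1e-10

    def test_swap_symmetry(self, planted_pair):
        cfg = db.SeparationSearchConfig(d=6, n_scans=5, n_vectors=100, seed=4)
        r_ab = db.search_separation_rc(planted_pair["a"], planted_pair["b"], cfg)
        r_ba = db.search_separation_rc(planted_pair["b"], planted_pair["a"], cfg)
        dot = r_ab.n_hat @ r_ba.n_hat
        assert abs(abs(dot) - 1) < 1e-9
        assert r_ab.overlap_value == pytest.approx(r_ba.overlap_value, abs=1e-9)

    def test_variance_trace_converges_for_planted_case(self, planted_pair):
        cfg = db.SeparationSearchConfig(d=10, n_scans=10, n_vectors=200, seed=3)
        res = db.search_separation_rc(planted_pair["a"], planted_pair["b"], cfg)
        assert res.variance_trace.shape == (10, 10)
        assert res.variance_trace[-1].max() < 1e-3

    def test_not_worse_than_first_pca_eigenvector(self, planted_pair):
        cfg = db.SeparationSearchConfig(d=8, n_scans=5, n_vectors=100, seed=5)
        res = db.search_separation_rc(planted_pair["a"], planted_pair["b"], cfg)
        e1 = res.basis.eigenvectors[:, 0]
        o_e1 = rcs.overlap(planted_pair["a"].X @ e1, planted_pair["b"].X @ e1)
        assert res.overlap_value <= o_e1 + 1e-9

    def test_d_exceeding_modes_raises(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((6, 4))
        cfg = db.SeparationSearchConfig(d=12, n_scans=1, n_vectors=10, seed=0)
        with pytest.raises(ConfigurationError):
            db.search_separation_rc(_flat(X), _flat(X + 1), cfg)

    def test_recovery_improves_with_gap(self):
        # |1 - |n_hat . v|| decreases monotonically with the planted gap
        errors = []
        for gap in (2.0, 4.0, 8.0):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(100 + seed)
                v = rng.standard_normal(12)
                v /= np.linalg.norm(v)
                spec = db.PlantedEnsembleSpec(dim=12, n_frames=1500,
                                              separation_vector=v, gap=gap,
                                              covariance=1.0, seed=seed)
                fa, fb = db.gen_two_gaussian_ensembles(spec)
                cfg = db.SeparationSearchConfig(d=6, n_scans=6, n_vectors=100,
                                                seed=seed)
                res = db.search_separation_rc(fa, fb, cfg)
                errs.append(abs(1 - abs(res.n_hat @ v)))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]


class TestSweepD:
    def test_planted_one_axis_plateau(self, planted_pair):
        cfg = db.SeparationSearchConfig(d=2, n_scans=4, n_vectors=100, seed=6)
        table = db.sweep_d(planted_pair["a"], planted_pair["b"], [2, 4, 6], cfg)
        sims = table["similarity_prev"].dropna()
        assert ((sims >= 0) & (sims <= 1)).all()
        assert table["plateau"].any()
        # overlap is already tiny at d=2 and non-increasing within tolerance
        overlaps = table["overlap"].to_numpy()
        assert np.all(overlaps[1:] <= overlaps[:-1] + 1e-6)

    def test_non_increasing_d_values_raise(self, planted_pair):
        cfg = db.SeparationSearchConfig(d=2, n_scans=1, n_vectors=10, seed=0)
        with pytest.raises(ConfigurationError):
            db.sweep_d(planted_pair["a"], planted_pair["b"], [4, 4], cfg)
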