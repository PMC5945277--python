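"""Shared fixtures: planted ensembles and umbrella windows with known truth.

Expensive generators are session-scoped so recovery tests and error
estimators reuse the same sampled data.
"""

import numpy as np
import pytest

import dimerbend as db
from dimerbend import ensemble_io as eio


@pytest.fixture(scope="session")
def double_well():
    return db.ToyPotential(form="quartic_double_well", barrier_h=5.0, width_w=1.0)


@pytest.fixture(scope="session")
def double_well_windows(double_well):
    """11 Metropolis-sampled umbrella windows spanning the double well."""
    centers = np.linspace(-1.6, 1.6, 11)
    return db.gen_umbrella_windows(
        double_well, centers, spring_k=100.0, n_steps=20_000,
        step_size=0.25, discard=1_000, seed=2024,
    )


@pytest.fixture(scope="session")
def hinge_bundle():
    """Superposed hinge-dimer ensemble with two anchor states, plus labels."""
    ens, labels = db.gen_hinge_dimer(
        n_beads_per_arm=5, hinge_stiffness=10.0, anchor_shift=0.3,
        p_state=0.5, n_frames=600, noise_sigma=0.01, seed=11,
    )
    sup = eio.superpose(ens, reference=db.hinge_reference())
    flat = eio.flatten(sup)
    state = labels["state"].to_numpy()
    halves = tuple(
        eio.FlatEnsemble(X=flat.X[state == s], mean=flat.X[state == s].mean(axis=0))
        for s in (0, 1)
    )
    return {"flat": flat, "labels": labels, "halves": halves}


@pytest.fixture(scope="session")
def planted_pair():
    """Two 30-D Gaussian clouds separated by 8 sigma along a planted vector."""
    rng = np.random.default_rng(7)
    Q, _ = np.linalg.qr(rng.standard_normal((30, 30)))
    v = Q[:, 0]
    spec = db.PlantedEnsembleSpec(
        dim=30, n_frames=5000, separation_vector=v, gap=8.0, covariance=1.0, seed=42,
    )
    flat_a, flat_b = db.gen_two_gaussian_ensembles(spec)
    return {"v": v, "a": flat_a, "b": flat_b}


@pytest.fixture
def toy_structure_ensemble():
    """Tiny 5-atom ensemble (non-degenerate geometry) for superposition tests."""
    rng = np.random.default_rng(3)
    base = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
         [0.0, 0.0, 1.0], [0.5, 0.5, 0.5]]
    )
    frames = np.stack([base, base + 0.05 * rng.standard_normal(base.shape)])
    return db.StructureEnsemble(
        coords=frames,
        atom_labels=eio.generic_atom_labels(5),
        frame_labels=["ref", "perturbed"],
        reference_index=0,
    )


def rotation_grid_min_rmsd(P, Q, n: int = 16):
    """Brute-force minimum RMSD over rotations (oracle, Kabsch-independent).

    Scans a ZYZ Euler-angle grid, then polishes the best grid point with
    Nelder-Mead over the three angles.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def val(angles):
        R = Rotation.from_euler("zyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    betas = np.linspace(0, np.pi, n // 2)
    best, best_x = np.inf, None
    for a in angles:
        for b in betas:
            for c in angles:
                v = val([a, b, c])
                if v < best:
                    best, best_x = v, [a, b, c]
    res = minimize(val, best_x, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return min(best, float(res.fun))
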