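"""Synthetic ensembles and umbrella windows with planted ground truth.

Three generators emulate the data the analysis pipeline is built for:

* two multivariate-Gaussian conformational ensembles separated along a
  planted unit vector (stand-in for straight vs. kinked simulation
  ensembles) — oracle for the separation search;
* a hinge-dimer bead model: two rigid arms joined at a pivot bead, bending
  angle Boltzmann-distributed with tunable stiffness, and an optional
  two-state displacement of the pivot ("anchor" states) orthogonal to the
  bending plane — oracle for PCA/bending-mode recovery and the
  bending-vs-anchor decoupling geometry;
* Metropolis-sampled umbrella windows on analytic 1-D potentials with
  harmonic biases — oracle for WHAM.  Metropolis (not Langevin) sampling is
  used deliberately: the stationary distribution is exact, with no
  integrator bias.

All generators are deterministic under fixed seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_io import (
    FlatEnsemble,
    StructureEnsemble,
    generic_atom_labels,
    kabsch_rotation,
    write_pdb_ensemble,
)
from .exceptions import ConfigurationError, InputError
from .free_energy import FreeEnergyProfile, UmbrellaWindow
from .units import DEFAULT_TEMPERATURE, kt_kj_per_mol


@dataclasses.dataclass
class ToyPotential:
    """Analytic 1-D potential, energies in kT.

    ``harmonic``: U(z) = 1/2 stiffness (z - center)^2.
    ``quartic_double_well``: U(z) = h (((z - center)/w)^2 - 1)^2, with
    minima at center +/- w and barrier height h at the center.
    """

    form: str = "quartic_double_well"
    barrier_h: float = 5.0    # kT
    width_w: float = 1.0      # nm
    center: float = 0.0       # nm
    stiffness: float = 1.0    # kT/nm^2 (harmonic form only)

    def __post_init__(self):
        if self.form not in ("harmonic", "quartic_double_well"):
            raise ConfigurationError(f"unknown potential form {self.form!r}")
        if self.form == "quartic_double_well" and self.barrier_h <= 0:
            raise ConfigurationError("barrier_h must be > 0 for the double well")
        if self.width_w <= 0:
            raise ConfigurationError("width_w must be > 0")

    def energy(self, z):
        z = np.asarray(z, dtype=float)
        if self.form == "harmonic":
            return 0.5 * self.stiffness * (z - self.center) ** 2
        u = ((z - self.center) / self.width_w) ** 2 - 1.0
        return self.barrier_h * u * u


@dataclasses.dataclass
class PlantedEnsembleSpec:
    """Two Gaussian clouds with means +/- (gap/2) * separation_vector."""

    dim: int
    n_frames: int
    separation_vector: np.ndarray
    gap: float                     # nm, distance between ensemble means
    covariance: float | np.ndarray = 1.0  # scalar, per-axis spectrum, or matrix
    seed: int | None = None

    def __post_init__(self):
        self.separation_vector = np.asarray(self.separation_vector, dtype=float)
        norm = np.linalg.norm(self.separation_vector)
        if abs(norm - 1.0) > 1e-8:
            raise ConfigurationError("separation_vector must be a unit vector")
        if self.gap < 0:
            raise ConfigurationError("gap must be >= 0")


def gen_two_gaussian_ensembles(spec: PlantedEnsembleSpec):
    """Sample the two planted ensembles; seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    cov = np.asarray(spec.covariance, dtype=float)
    if cov.ndim == 0:
        scale = np.full(spec.dim, np.sqrt(float(cov)))
        sample = lambda n: rng.standard_normal((n, spec.dim)) * scale
    elif cov.ndim == 1:
        scale = np.sqrt(cov)
        sample = lambda n: rng.standard_normal((n, spec.dim)) * scale
    else:
        L = np.linalg.cholesky(cov)
        sample = lambda n: rng.standard_normal((n, spec.dim)) @ L.T
    offset = 0.5 * spec.gap * spec.separation_vector
    X1 = sample(spec.n_frames) - offset
    X2 = sample(spec.n_frames) + offset
    prov = {"generator": "two_gaussian", "gap": spec.gap, "seed": spec.seed}
    return (
        FlatEnsemble(X=X1, mean=X1.mean(axis=0), provenance={**prov, "side": 1}),
        FlatEnsemble(X=X2, mean=X2.mean(axis=0), provenance={**prov, "side": 2}),
    )


# ---------------------------------------------------------------------------
# Hinge dimer
# ---------------------------------------------------------------------------

def _hinge_geometry(theta: float, n_beads_per_arm: int, bond_length: float,
                    pivot_z: float = 0.0) -> np.ndarray:
    """Bead coordinates for a symmetric hinge at opening angle theta.

    The pivot bead sits at the origin (displaced by *pivot_z* along z in the
    second anchor state); each arm extends along a fixed in-plane direction
    at +/- theta/2 from the x-axis, so theta = pi is the straight dimer.
    Planted modes therefore have closed-form in-plane directions.
    """
    half = theta / 2.0
    dir_a = np.array([np.cos(half), np.sin(half), 0.0])
    dir_b = np.array([np.cos(half), -np.sin(half), 0.0])
    r = bond_length * np.arange(1, n_beads_per_arm + 1)
    coords = np.vstack(
        [np.array([[0.0, 0.0, pivot_z]]), np.outer(r, dir_a), np.outer(r, dir_b)]
    )
    return coords


def hinge_reference(n_beads_per_arm: int = 5, theta0: float = 2.1,
                    bond_length: float = 0.5) -> np.ndarray:
    """Noiseless hinge-dimer geometry at the equilibrium angle (N, 3)."""
    return _hinge_geometry(theta0, n_beads_per_arm, bond_length)


def hinge_bending_direction(n_beads_per_arm: int = 5, theta0: float = 2.1,
                            bond_length: float = 0.5, delta: float = 1e-5) -> np.ndarray:
    """Unit 3N vector of the planted bending mode at theta0.

    Central difference of the superposed geometry with respect to theta:
    frames at theta0 +/- delta are Kabsch-aligned onto the theta0 geometry
    before differencing, matching the convention of an analyzed (superposed)
    ensemble.
    """
    ref = _hinge_geometry(theta0, n_beads_per_arm, bond_length)
    ref_c = ref - ref.mean(axis=0)

    def aligned(theta):
        g = _hinge_geometry(theta, n_beads_per_arm, bond_length)
        gc = g - g.mean(axis=0)
        return gc @ kabsch_rotation(gc, ref_c)

    diff = (aligned(theta0 + delta) - aligned(theta0 - delta)) / (2 * delta)
    v = diff.ravel()
    return v / np.linalg.norm(v)


def gen_hinge_dimer(n_beads_per_arm: int = 5, hinge_stiffness: float = 10.0,
                    theta0: float = 2.1, anchor_shift: float = 0.0,
                    p_state: float = 0.0, n_frames: int = 500,
                    noise_sigma: float = 0.01, bond_length: float = 0.5,
                    seed=None):
    """Sample a hinge-dimer ensemble with Boltzmann-distributed bending.

    The bending angle is drawn from the Boltzmann distribution of
    1/2 kappa (theta - theta0)^2 (kappa in kT/rad^2, so the angle variance
    is 1/kappa by equipartition).  With probability ``p_state`` a frame is
    in the second anchor state, where the pivot bead is displaced by
    ``anchor_shift`` (nm) along z — an internal rearrangement orthogonal to
    the bending plane.  I.i.d. Gaussian jitter of ``noise_sigma`` (nm) is
    added per atom.

    Returns ``(StructureEnsemble, labels)`` where labels is a DataFrame
    with per-frame ``theta`` (rad) and ``state`` (0/1).
    """
    if n_beads_per_arm < 2:
        raise ConfigurationError("n_beads_per_arm must be >= 2")
    if hinge_stiffness <= 0:
        raise ConfigurationError("hinge_stiffness must be > 0")
    rng = np.random.default_rng(seed)
    thetas = theta0 + rng.standard_normal(n_frames) / np.sqrt(hinge_stiffness)
    states = (rng.random(n_frames) < p_state).astype(int)
    n_atoms = 2 * n_beads_per_arm + 1
    coords = np.empty((n_frames, n_atoms, 3))
    for i in range(n_frames):
        coords[i] = _hinge_geometry(
            thetas[i], n_beads_per_arm, bond_length,
            pivot_z=anchor_shift * states[i],
        )
    coords += noise_sigma * rng.standard_normal(coords.shape)
    ens = StructureEnsemble(
        coords=coords,
        atom_labels=generic_atom_labels(n_atoms),
        frame_labels=[f"frame{i}" for i in range(n_frames)],
        reference_index=0,
    )
    labels = pd.DataFrame({"theta": thetas, "state": states})
    return ens, labels


# ---------------------------------------------------------------------------
# Umbrella windows
# ---------------------------------------------------------------------------

def gen_umbrella_windows(potential: ToyPotential, centers, spring_k: float = 100.0,
                         n_steps: int = 20_000, step_size: float = 0.1,
                         discard: int = 1_000, seed=None,
                         temperature: float = DEFAULT_TEMPERATURE):
    """Metropolis-sample z under U(z) + harmonic bias for each window.

    ``spring_k`` is in kJ/mol/nm^2 (converted with kT at *temperature*);
    the toy potential is already in kT.  Proposals are uniform within
    +/- step_size.  Acceptance rates are logged in ``window.meta``; a rate
    below 1% raises a step-size error.
    """
    centers = list(centers)
    if not centers:
        raise InputError("centers must be non-empty")
    if n_steps <= discard:
        raise InputError("n_steps must exceed discard")
    kT = kt_kj_per_mol(temperature)
    k_kt = spring_k / kT  # bias stiffness in kT/nm^2
    seeds = np.random.SeedSequence(seed).spawn(len(centers))
    windows = []
    for c, ss in zip(centers, seeds):
        rng = np.random.default_rng(ss)

        def u_tot(z, _c=c):
            return potential.energy(z) + 0.5 * k_kt * (z - _c) ** 2

        z = float(c)
        e = u_tot(z)
        series = np.empty(n_steps)
        proposals = step_size * (2.0 * rng.random(n_steps) - 1.0)
        logu = np.log(rng.random(n_steps))
        accepted = 0
        for t in range(n_steps):
            z_new = z + proposals[t]
            e_new = u_tot(z_new)
            if e_new - e <= -logu[t]:
                z, e = z_new, e_new
                accepted += 1
            series[t] = z
        rate = accepted / n_steps
        if rate < 0.01:
            raise ConfigurationError(
                f"acceptance rate {rate:.3%} below 1% in window at {c:g}; "
                "reduce step_size"
            )
        windows.append(
            UmbrellaWindow(
                center=c,
                spring_k=spring_k,
                series=series,
                discard=discard,
                meta={
                    "acceptance_rate": rate,
                    "true_potential": dataclasses.asdict(potential),
                    "temperature": temperature,
                },
            )
        )
    return windows


def analytic_pmf(potential: ToyPotential, bins) -> FreeEnergyProfile:
    """Ground-truth profile G(z) = U(z) - min U on a bin grid, zero error.

    Both potential forms have a global minimum of exactly zero, so G does
    not depend on whether the grid happens to contain the minimum — grid
    refinement never changes G at shared points.
    """
    if np.isscalar(bins):
        raise InputError("analytic_pmf needs explicit bin centers or edges")
    grid = np.asarray(bins, dtype=float)
    G = potential.energy(grid)
    return FreeEnergyProfile(
        axis=grid, G=G, err=np.zeros_like(G), occupied=np.ones(grid.shape, dtype=bool)
    )


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_set(out_dir, master_seed: int = 0) -> dict:
    """Write a deterministic fixture bundle and return its manifest.

    Contents: a two-Gaussian ensemble pair (TSV), a hinge-dimer multi-model
    PDB with per-frame labels, and umbrella-window series files with a
    manifest — everything the pipeline and CLIs consume.
    """
    from .ensemble_io import write_flat

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(master_seed).spawn(3)
    manifest = {"master_seed": master_seed, "files": {}}

    # planted two-Gaussian pair
    dim = 30
    rng = np.random.default_rng(seeds[0])
    v = rng.standard_normal(dim)
    v /= np.linalg.norm(v)
    spec = PlantedEnsembleSpec(
        dim=dim, n_frames=400, separation_vector=v, gap=8.0, covariance=1.0,
        seed=int(seeds[0].generate_state(1)[0] % (2**31)),
    )
    flat_a, flat_b = gen_two_gaussian_ensembles(spec)
    for name, flat in (("ensemble_a.tsv", flat_a), ("ensemble_b.tsv", flat_b)):
        write_flat(flat, out / name)
        manifest["files"][name] = {
            "generator": "two_gaussian", "gap": spec.gap, "dim": dim,
            "n_frames": spec.n_frames, "seed": spec.seed,
            "sha256": _sha256(out / name),
        }
    np.savetxt(out / "separation_vector.tsv", v, delimiter="\t")
    manifest["files"]["separation_vector.tsv"] = {
        "generator": "two_gaussian", "sha256": _sha256(out / "separation_vector.tsv")
    }

    # hinge dimer
    hseed = int(seeds[1].generate_state(1)[0] % (2**31))
    params = dict(n_beads_per_arm=5, hinge_stiffness=10.0, anchor_shift=0.3,
                  p_state=0.5, n_frames=300, noise_sigma=0.01, seed=hseed)
    ens, labels = gen_hinge_dimer(**params)
    write_pdb_ensemble(ens, out / "hinge_dimer.pdb")
    labels.to_csv(out / "hinge_labels.tsv", sep="\t", index=False)
    manifest["files"]["hinge_dimer.pdb"] = {
        "generator": "hinge_dimer", **params, "sha256": _sha256(out / "hinge_dimer.pdb")
    }
    manifest["files"]["hinge_labels.tsv"] = {
        "generator": "hinge_dimer", "sha256": _sha256(out / "hinge_labels.tsv")
    }

    # umbrella windows on the quartic double well
    useed = int(seeds[2].generate_state(1)[0] % (2**31))
    pot = ToyPotential(form="quartic_double_well", barrier_h=5.0, width_w=1.0)
    centers = np.linspace(-1.6, 1.6, 11)
    windows = gen_umbrella_windows(pot, centers, spring_k=100.0, n_steps=8_000,
                                   step_size=0.25, discard=500, seed=useed)
    window_manifest = []
    for i, w in enumerate(windows):
        name = f"window_{i:02d}.tsv"
        df = pd.DataFrame({"time": np.arange(w.series.size) * w.dt, "z": w.series})
        df.to_csv(out / name, sep="\t", index=False)
        window_manifest.append(
            {"file": name, "center": w.center, "spring_k": w.spring_k,
             "discard": w.discard, "sha256": _sha256(out / name)}
        )
    manifest["files"]["windows"] = window_manifest
    manifest["umbrella"] = {
        "potential": dataclasses.asdict(pot), "spring_k": 100.0,
        "n_steps": 8_000, "discard": 500, "seed": useed,
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def read_window_manifest(manifest_path) -> list:
    """Load umbrella windows from a fixture/CLI manifest (JSON)."""
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    entries = spec["files"]["windows"] if "files" in spec else spec["windows"]
    windows = []
    for entry in entries:
        df = pd.read_csv(manifest_path.parent / entry["file"], sep="\t")
        windows.append(
            UmbrellaWindow(
                center=float(entry["center"]),
                spring_k=float(entry["spring_k"]),
                series=df["z"].to_numpy(),
                discard=int(entry.get("discard", 0)),
            )
        )
    return windows
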