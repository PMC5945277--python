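"""Principal component analysis of flattened conformational ensembles.

The covariance matrix of atomic positions, C_ij = <(x_i - <x_i>)(x_j - <x_j>)>,
is diagonalized into orthonormal eigenvectors (conformational modes) with
descending eigenvalues.  Projections q_k = (x - <x>) . v_k give collective
coordinates; the eigenvalue is the ensemble variance along the mode.

Conventions
-----------
* Covariance is normalized by F (population convention), since it is defined
  as an ensemble average.  This differs from the 1/(F-1) sample convention by
  (F-1)/F on every eigenvalue.
* When 3N > F the eigendecomposition goes through the F x F Gram matrix,
  which is exact for the at most F-1 nonzero modes and tractable for
  ensembles with few frames but many coordinates (e.g. ~100 structures of a
  protein dimer).
* Eigenvector signs are fixed deterministically: the largest-magnitude
  component is made positive.
* Eigenvalues below 1e-12 nm^2 are clipped to zero.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .ensemble_io import FlatEnsemble, StructureEnsemble, generic_atom_labels
from .exceptions import ConsistencyError, DegeneracyError, InsufficientDataError

EIGENVALUE_CLIP = 1e-12  # nm^2


@dataclasses.dataclass
class PCABasis:
    """Mean configuration, orthonormal eigenvectors, descending eigenvalues."""

    mean: np.ndarray          # (3N,)
    eigenvectors: np.ndarray  # (3N, K), columns are modes
    eigenvalues: np.ndarray   # (K,), descending, >= 0
    n_frames: int

    def __post_init__(self):
        if self.eigenvectors.shape[0] != self.mean.shape[0]:
            raise ConsistencyError("eigenvector dimension must match mean length")
        if self.eigenvectors.shape[1] != self.eigenvalues.shape[0]:
            raise ConsistencyError("one eigenvalue required per eigenvector")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]


@dataclasses.dataclass
class Projection:
    """Per-frame coordinates q_k along selected conformational modes."""

    coords: np.ndarray  # (F, d)
    mode_indices: list
    basis: PCABasis | None = None

    def __post_init__(self):
        if self.coords.ndim != 2 or self.coords.shape[1] != len(self.mode_indices):
            raise ConsistencyError("one projection column required per requested mode")


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude component is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def compute_pca(flat: FlatEnsemble) -> PCABasis:
    """Eigendecompose the population covariance of the mean-centered ensemble."""
    X = flat.X
    F, D = X.shape
    if F < 2:
        raise InsufficientDataError("PCA needs at least 2 frames")
    mean = X.mean(axis=0)
    Xc = X - mean

    if D <= F:
        C = (Xc.T @ Xc) / F
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
    else:
        # Gram-matrix route: eigenvectors of (1/F) Xc Xc^T lift to coordinate space
        G = (Xc @ Xc.T) / F
        gvals, gvecs = np.linalg.eigh(G)
        order = np.argsort(gvals)[::-1]
        gvals = gvals[order]
        gvecs = gvecs[:, order]
        keep = gvals > EIGENVALUE_CLIP
        V = Xc.T @ gvecs[:, keep]
        V /= np.sqrt(F * gvals[keep])[None, :]
        evals = gvals
        evecs = np.zeros((D, F))
        evecs[:, : keep.sum()] = V
        # pad the null modes with an arbitrary orthonormal completion is not
        # needed downstream; only modes with nonzero variance are meaningful
        evals = evals[: keep.sum()]
        evecs = evecs[:, : keep.sum()]

    evals = np.where(evals < EIGENVALUE_CLIP, 0.0, evals)
    evecs = _fix_signs(evecs)
    return PCABasis(mean=mean, eigenvectors=evecs, eigenvalues=evals, n_frames=F)


def project(flat: FlatEnsemble | np.ndarray, basis: PCABasis, modes=None) -> Projection:
    """Project frames onto selected modes, centering with the *basis* mean.

    Using the basis mean (not the projected ensemble's own) lets foreign
    ensembles — e.g. simulated trajectories projected onto an experimental
    basis — share one consistent coordinate system.
    """
    X = flat.X if isinstance(flat, FlatEnsemble) else np.asarray(flat, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != basis.dim:
        raise ConsistencyError(
            f"ensemble dimension {X.shape[1]} does not match basis dimension {basis.dim}"
        )
    if modes is None:
        modes = list(range(basis.n_modes))
    modes = list(modes)
    V = basis.eigenvectors[:, modes]
    return Projection(coords=(X - basis.mean) @ V, mode_indices=modes, basis=basis)


def variance_fractions(basis: PCABasis) -> np.ndarray:
    """Fraction of total ensemble variance carried by each mode (sums to 1)."""
    total = basis.eigenvalues.sum()
    if total <= 0:
        raise DegeneracyError("all eigenvalues are zero: degenerate ensemble")
    return basis.eigenvalues / total


def interpolate_mode(basis: PCABasis, mode: int, amplitudes,
                     template: StructureEnsemble | None = None) -> StructureEnsemble:
    """Structures <x> + a * v_mode for each amplitude a (nm), for rendering
    extreme conformations along a conformational mode."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(amplitudes)):
        raise ConsistencyError("amplitudes must be finite")
    v = basis.eigenvectors[:, mode]
    rows = basis.mean[None, :] + amplitudes[:, None] * v[None, :]
    coords = rows.reshape(len(amplitudes), -1, 3)
    labels = (
        template.atom_labels.iloc[np.flatnonzero(template.mask)].reset_index(drop=True)
        if template is not None
        else generic_atom_labels(coords.shape[1])
    )
    return StructureEnsemble(
        coords=coords,
        atom_labels=labels,
        frame_labels=[f"a={a:g}" for a in amplitudes],
        reference_index=0,
    )


def max_variance_orthogonal(flat: FlatEnsemble, n: np.ndarray) -> np.ndarray:
    """First principal axis of the ensemble restricted to the subspace
    orthogonal to the unit vector *n*.

    Degenerate residual spectra trigger a warning; the tie is broken
    deterministically by the eigensolver's ordering plus the sign convention.
    """
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ConsistencyError("n must be a unit vector")
    Xc = flat.X - flat.X.mean(axis=0)
    Xp = Xc - np.outer(Xc @ n, n)
    basis = compute_pca(FlatEnsemble(X=Xp, mean=np.zeros(Xp.shape[1])))
    lam = basis.eigenvalues
    if lam.size > 1 and lam[0] > 0 and (lam[0] - lam[1]) / lam[0] < 1e-6:
        warnings.warn("residual variance is degenerate; direction chosen by tie-break")
    v = basis.eigenvectors[:, 0]
    v = v - (v @ n) * n  # enforce exact orthogonality against roundoff
    v /= np.linalg.norm(v)
    idx = np.argmax(np.abs(v))
    if v[idx] < 0:
        v = -v
    return v
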