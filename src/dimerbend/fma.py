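"""Partial-least-squares functional mode analysis (FMA).

A scalar functional quantity f (here typically the RMSD to a straight
reference structure) is regressed on ensemble coordinate fluctuations,

    f = X^T W_k beta_k + eps,

with a PLS1 (NIPALS) basis W_k built iteratively from both the coordinate
variance and the linear correlation between f and X.  The component count k
is a regularization parameter chosen by cross-validation against held-out
frames; the ensemble-weighted mode is the normalized coefficient vector of
the fitted linear map, i.e. the collective direction whose motion correlates
best with f.

RMSD is a nonlinear function of the coordinates; it is nonetheless fitted
linearly and the adequacy of the model is judged purely by the
model-building (Rm) and cross-validation (Rv) correlations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ensemble_io import FlatEnsemble
from .exceptions import ConfigurationError, ConsistencyError, DegeneracyError
from .exceptions import InsufficientDataError

#: Parsimony tolerance: chosen k is the smallest within this of the best Rv.
CV_TOLERANCE = 0.005


@dataclasses.dataclass
class FMAModel:
    """Fitted PLS basis, coefficients and diagnostics."""

    basis_W: np.ndarray       # (3N, k) PLS weight vectors
    coeffs_beta: np.ndarray   # (k,) regression coefficients on the components
    k: int
    mean_x: np.ndarray        # (3N,) training mean
    mean_f: float
    coef_vector: np.ndarray   # (3N,) linear map from centered x to f_hat
    mode: np.ndarray          # (3N,) unit ensemble-weighted mode
    rm: float                 # Pearson correlation of f and f_hat on training data
    rv_by_k: np.ndarray | None = None
    k_chosen: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.mean_x.shape[0]:
            raise ConsistencyError("prediction input dimension does not match model")
        return self.mean_f + (X - self.mean_x) @ self.coef_vector


def rmsd_series(flat: FlatEnsemble, reference: np.ndarray) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference 3N vector over the masked atoms.

    Frames are assumed already superposed, so no refitting is done:
    RMSD_t = |x_t - x_ref| / sqrt(N_atoms).
    """
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.shape[0] != flat.X.shape[1]:
        raise ConsistencyError("reference length does not match ensemble dimension")
    n_atoms = flat.n_atoms
    return np.linalg.norm(flat.X - ref, axis=1) / np.sqrt(n_atoms)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def fit_pls(X: np.ndarray, f: np.ndarray, k: int) -> FMAModel:
    """Fit single-response PLS (NIPALS with deflation) with k components.

    At full rank the fitted linear map coincides with ordinary least
    squares, which pins the construction.
    """
    X = np.asarray(X, dtype=float)
    f = np.asarray(f, dtype=float).ravel()
    F, D = X.shape
    if f.shape[0] != F:
        raise ConsistencyError("f length must equal frame count")
    if k < 1 or k >= F:
        raise ConfigurationError(f"need F > k >= 1, got k={k}, F={F}")
    if np.ptp(f) == 0:
        raise DegeneracyError("functional quantity f is constant")

    mean_x = X.mean(axis=0)
    mean_f = float(f.mean())
    Xd = X - mean_x
    fd = f - mean_f

    W = np.zeros((D, k))
    P = np.zeros((D, k))
    q = np.zeros(k)
    n_used = 0
    for j in range(k):
        w = Xd.T @ fd
        wn = np.linalg.norm(w)
        if wn < 1e-14:
            break  # residual f uncorrelated with residual X; stop early
        w /= wn
        t = Xd @ w
        tt = t @ t
        if tt < 1e-28:
            break
        p = Xd.T @ t / tt
        qj = fd @ t / tt
        W[:, j] = w
        P[:, j] = p
        q[j] = qj
        Xd = Xd - np.outer(t, p)
        fd = fd - qj * t
        n_used = j + 1

    W, P, q = W[:, :n_used], P[:, :n_used], q[:n_used]
    # coefficient vector of the composed linear map centered-x -> f_hat
    coef = W @ np.linalg.solve(P.T @ W, q)
    f_hat = mean_f + (X - mean_x) @ coef
    rm = _pearson(f, f_hat)
    norm = np.linalg.norm(coef)
    mode = coef / norm if norm > 0 else coef
    return FMAModel(
        basis_W=W,
        coeffs_beta=q,
        k=n_used,
        mean_x=mean_x,
        mean_f=mean_f,
        coef_vector=coef,
        mode=mode,
        rm=rm,
    )


def _split_indices(F: int, split: str, seed=None):
    if split == "half":
        # first half builds the model, second half validates — matching the
        # use of consecutive trajectory halves
        idx = np.arange(F)
        return idx[: F // 2], idx[F // 2:]
    if split == "random":
        rng = np.random.default_rng(seed)
        idx = rng.permutation(F)
        return idx[: F // 2], idx[F // 2:]
    raise ConfigurationError(f"unknown split scheme {split!r}")


def cross_validate(X: np.ndarray, f: np.ndarray, k_max: int, split: str = "half",
                   seed=None, tolerance: float = CV_TOLERANCE):
    """Cross-validated correlation per component count and the chosen k.

    For each k <= k_max, fit on the building half and evaluate the Pearson
    correlation Rv on the validation half.  The chosen k is the smallest
    within *tolerance* of the maximal Rv (parsimony rule).

    Returns ``(rv_by_k, k_chosen, model)`` where the model is refit at
    k_chosen on the building half with ``rv_by_k``/``k_chosen`` recorded.
    """
    X = np.asarray(X, dtype=float)
    f = np.asarray(f, dtype=float).ravel()
    build, val = _split_indices(X.shape[0], split, seed)
    if len(build) < 2 or len(val) < 2:
        raise InsufficientDataError("split leaves fewer than 2 frames per side")
    if np.ptp(f[val]) == 0:
        raise DegeneracyError("validation half of f is constant")
    k_max = min(k_max, len(build) - 1)
    rv = np.empty(k_max)
    for k in range(1, k_max + 1):
        model = fit_pls(X[build], f[build], k)
        rv[k - 1] = _pearson(f[val], model.predict(X[val]))
    if not np.all(np.isfinite(rv)):
        raise DegeneracyError("non-finite cross-validation correlation")
    k_chosen = int(np.argmax(rv >= rv.max() - tolerance)) + 1
    model = fit_pls(X[build], f[build], k_chosen)
    model.rv_by_k = rv
    model.k_chosen = k_chosen
    return rv, k_chosen, model


def validate_independent(model: FMAModel, X2: np.ndarray, f2: np.ndarray) -> float:
    """Pearson correlation between f2 and model predictions on an
    independent ensemble X2."""
    f2 = np.asarray(f2, dtype=float).ravel()
    if np.ptp(f2) == 0:
        raise DegeneracyError("independent validation target is constant")
    return _pearson(f2, model.predict(X2))
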