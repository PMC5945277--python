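"""Ensemble-separation reaction-coordinate search.

Given two conformational ensembles, find the unit vector n whose projected
probability densities overlap least,

    O(n) = integral rho1(z, n) rho2(z, n) dz,

where z = n . x.  The search is regularized by expressing n in the first d
eigenvectors of a PCA on the combined ensemble, and proceeds by many
independent scans: each scan draws random unit vectors (i.i.d. normal
coordinates, normalized), keeps the one of minimal overlap, and refines it
with gradient-free downhill-simplex (Nelder-Mead) minimization.  Scan
results are sign-aligned, averaged and renormalized into the final
separation vector; per-coordinate variances of the scan vectors as a
function of scan count serve as the convergence diagnostic.

Density models: a Gaussian fit per ensemble (analytic overlap, smooth for
the simplex) is the default; a histogram model on a shared grid is kept as a
cross-check.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ensemble_io import FlatEnsemble
from .exceptions import ConfigurationError, ConsistencyError, DegeneracyError
from . import pca as _pca


@dataclasses.dataclass
class SeparationSearchConfig:
    """Knobs of the separation search.

    Defaults are production-scale (500 scans x 2000 vectors); recovery
    tests use reduced counts with fixed seeds.
    """

    d: int = 20
    n_scans: int = 500
    n_vectors: int = 2000
    density_model: str = "gaussian"
    seed: int | None = None
    simplex_tol: float = 1e-8
    simplex_maxiter: int | None = None

    def __post_init__(self):
        if self.d < 2:
            raise ConfigurationError("d must be >= 2")
        if self.n_scans < 1 or self.n_vectors < 1:
            raise ConfigurationError("n_scans and n_vectors must be >= 1")
        if self.density_model not in ("gaussian", "histogram"):
            raise ConfigurationError(f"unknown density model {self.density_model!r}")


@dataclasses.dataclass
class SeparationResult:
    """Best separating unit vector, its overlap, and per-scan diagnostics."""

    n_hat: np.ndarray            # (3N,) unit vector in coordinate space
    overlap_value: float
    scan_vectors: np.ndarray     # (n_scans, d), sign-aligned
    scan_overlaps: np.ndarray    # (n_scans,)
    variance_trace: np.ndarray   # (n_scans, d) running per-coordinate variance
    d_used: int
    n_hat_subspace: np.ndarray | None = None  # (d,) coefficients in PCA basis
    basis: object | None = None


# ---------------------------------------------------------------------------
# Densities and overlap
# ---------------------------------------------------------------------------

def projected_density(z, model: str = "gaussian", bins=None):
    """Fit a 1-D density to projected samples.

    Gaussian model returns ``(mu, sigma)`` (population sigma); histogram
    model returns ``(edges, densities)`` normalized to unit integral.
    """
    z = np.asarray(z, dtype=float)
    if model == "gaussian":
        if z.size < 2:
            raise DegeneracyError("gaussian density needs >= 2 samples")
        mu = float(z.mean())
        sigma = float(z.std())  # population convention
        if sigma == 0.0:
            raise DegeneracyError("zero variance: gaussian density is degenerate")
        return mu, sigma
    if model == "histogram":
        edges = _histogram_edges(z) if bins is None else np.asarray(bins, dtype=float)
        counts, edges = np.histogram(z, bins=edges)
        widths = np.diff(edges)
        dens = counts / (counts.sum() * widths)
        return edges, dens
    raise ConfigurationError(f"unknown density model {model!r}")


def gaussian_overlap(mu1: float, s1: float, mu2: float, s2: float) -> float:
    """Closed-form overlap integral of two Gaussian densities."""
    var = s1 * s1 + s2 * s2
    return float(np.exp(-((mu1 - mu2) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var))


def _histogram_edges(pooled: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis bins over the pooled range, padded by 3 bin widths."""
    q75, q25 = np.percentile(pooled, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        width = max(pooled.std() / 10.0, 1e-12)
    else:
        width = 2.0 * iqr / np.cbrt(pooled.size)
    lo = pooled.min() - 3 * width
    hi = pooled.max() + 3 * width
    n_bins = max(int(np.ceil((hi - lo) / width)), 1)
    return np.linspace(lo, hi, n_bins + 1)


def overlap(ens1_proj, ens2_proj, model: str = "gaussian") -> float:
    """Density-overlap integral O between two projected 1-D samples."""
    z1 = np.asarray(ens1_proj, dtype=float)
    z2 = np.asarray(ens2_proj, dtype=float)
    if model == "gaussian":
        mu1, s1 = projected_density(z1, "gaussian")
        mu2, s2 = projected_density(z2, "gaussian")
        return gaussian_overlap(mu1, s1, mu2, s2)
    if model == "histogram":
        edges = _histogram_edges(np.concatenate([z1, z2]))
        _, d1 = projected_density(z1, "histogram", bins=edges)
        _, d2 = projected_density(z2, "histogram", bins=edges)
        return float(np.sum(d1 * d2 * np.diff(edges)))
    raise ConfigurationError(f"unknown density model {model!r}")


def random_unit_vectors(d: int, count: int, seed=None) -> np.ndarray:
    """(count, d) array of unit vectors with i.i.d. normal coordinates."""
    if d < 1:
        raise ConfigurationError("d must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = rng.standard_normal((count, d))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


# ---------------------------------------------------------------------------
# Scan machinery
# ---------------------------------------------------------------------------

class _GaussianObjective:
    """Overlap as a function of n, from sufficient statistics of each side.

    For a Gaussian density model the projected mean and variance are
    m_i . n and n^T C_i n, so one evaluation is O(d^2) regardless of frame
    count.
    """

    def __init__(self, proj1: np.ndarray, proj2: np.ndarray):
        self.m1 = proj1.mean(axis=0)
        self.m2 = proj2.mean(axis=0)
        c1 = proj1 - self.m1
        c2 = proj2 - self.m2
        self.C1 = (c1.T @ c1) / proj1.shape[0]
        self.C2 = (c2.T @ c2) / proj2.shape[0]

    def __call__(self, n: np.ndarray) -> float:
        norm = np.linalg.norm(n)
        if norm == 0:
            return np.inf
        u = n / norm
        mu1 = self.m1 @ u
        mu2 = self.m2 @ u
        v1 = u @ self.C1 @ u
        v2 = u @ self.C2 @ u
        if v1 <= 0 or v2 <= 0:
            return np.inf
        return gaussian_overlap(mu1, np.sqrt(v1), mu2, np.sqrt(v2))

    def batch(self, candidates: np.ndarray) -> np.ndarray:
        """Vectorized overlap for (count, d) unit candidates."""
        U = candidates.T  # (d, count)
        mu1 = self.m1 @ U
        mu2 = self.m2 @ U
        v1 = np.einsum("dk,dk->k", U, self.C1 @ U)
        v2 = np.einsum("dk,dk->k", U, self.C2 @ U)
        var = v1 + v2
        return np.exp(-((mu1 - mu2) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)


class _HistogramObjective:
    def __init__(self, proj1: np.ndarray, proj2: np.ndarray):
        self.proj1 = proj1
        self.proj2 = proj2

    def __call__(self, n: np.ndarray) -> float:
        norm = np.linalg.norm(n)
        if norm == 0:
            return np.inf
        u = n / norm
        return overlap(self.proj1 @ u, self.proj2 @ u, model="histogram")

    def batch(self, candidates: np.ndarray) -> np.ndarray:
        return np.array([self(c) for c in candidates])


def _make_objective(proj1, proj2, model):
    if model == "gaussian":
        return _GaussianObjective(proj1, proj2)
    return _HistogramObjective(proj1, proj2)


def run_scan(proj1: np.ndarray, proj2: np.ndarray, config: SeparationSearchConfig,
             seed=None):
    """One scan: best of ``n_vectors`` random candidates, simplex-refined.

    Returns ``(unit d-vector, overlap)``.
    """
    proj1 = np.asarray(proj1, dtype=float)
    proj2 = np.asarray(proj2, dtype=float)
    if proj1.shape[1] != proj2.shape[1]:
        raise ConsistencyError("projections must share the basis dimension")
    objective = _make_objective(proj1, proj2, config.density_model)
    return _run_scan(objective, proj1.shape[1], config, seed)


def _run_scan(objective, d, config, seed):
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = random_unit_vectors(d, config.n_vectors, rng)
    values = objective.batch(candidates)
    best = int(np.argmin(values))
    x0, f0 = candidates[best], float(values[best])

    maxiter = config.simplex_maxiter or 200 * d
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": config.simplex_tol,
            "fatol": config.simplex_tol,
            "maxiter": maxiter,
            "maxfev": 4 * maxiter,
        },
    )
    if not res.success:
        warnings.warn("downhill simplex did not converge; returning best-so-far")
    if res.fun <= f0:
        x, f = res.x, float(res.fun)
    else:  # minimization contract: never worse than the best random candidate
        x, f = x0, f0
    x = x / np.linalg.norm(x)
    return x, f


def search_separation_rc(flat1: FlatEnsemble, flat2: FlatEnsemble,
                         config: SeparationSearchConfig) -> SeparationResult:
    """Full separation search between two ensembles sharing an atom mask.

    Builds a PCA basis on the combined ensemble, expresses both ensembles in
    the first ``d`` modes, runs ``n_scans`` independent scans, sign-aligns
    the scan vectors (each flipped to a positive dot product with the
    running mean; the first scan defines the orientation), averages and
    renormalizes, and re-embeds the result into 3N coordinate space.
    """
    if flat1.X.shape[1] != flat2.X.shape[1]:
        raise ConsistencyError("ensembles must share the flattened dimension")
    combined = FlatEnsemble(
        X=np.vstack([flat1.X, flat2.X]),
        mean=np.vstack([flat1.X, flat2.X]).mean(axis=0),
    )
    basis = _pca.compute_pca(combined)
    n_avail = int(np.count_nonzero(basis.eigenvalues > 0))
    if config.d > n_avail:
        raise ConfigurationError(
            f"d={config.d} exceeds the {n_avail} available nonzero PCA modes"
        )
    modes = list(range(config.d))
    proj1 = _pca.project(flat1, basis, modes).coords
    proj2 = _pca.project(flat2, basis, modes).coords
    objective = _make_objective(proj1, proj2, config.density_model)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_scans)
    d = config.d
    vectors = np.empty((config.n_scans, d))
    overlaps = np.empty(config.n_scans)
    running_sum = np.zeros(d)
    variance_trace = np.empty((config.n_scans, d))
    for s in range(config.n_scans):
        v, o = _run_scan(objective, d, config, np.random.default_rng(seeds[s]))
        if s > 0 and v @ running_sum < 0:
            v = -v
        vectors[s] = v
        overlaps[s] = o
        running_sum += v
        variance_trace[s] = vectors[: s + 1].var(axis=0)

    mean_vec = vectors.mean(axis=0)
    n_sub = mean_vec / np.linalg.norm(mean_vec)
    overlap_value = float(objective(n_sub))
    n_hat = basis.eigenvectors[:, modes] @ n_sub
    n_hat /= np.linalg.norm(n_hat)
    return SeparationResult(
        n_hat=n_hat,
        overlap_value=overlap_value,
        scan_vectors=vectors,
        scan_overlaps=overlaps,
        variance_trace=variance_trace,
        d_used=d,
        n_hat_subspace=n_sub,
        basis=basis,
    )


def sweep_d(flat1: FlatEnsemble, flat2: FlatEnsemble, d_values,
            config: SeparationSearchConfig,
            plateau_threshold: float = 0.99) -> pd.DataFrame:
    """Repeat the search over increasing regularization dimensions d.

    Returns a table with the overlap per d and the cosine similarity of each
    solution with the previous one (in full coordinate space); the column
    ``plateau`` flags the smallest d at which the similarity exceeds the
    threshold, i.e. where the solution has become independent of d.
    """
    d_values = list(d_values)
    if any(b <= a for a, b in zip(d_values, d_values[1:])):
        raise ConfigurationError("d_values must be strictly increasing")
    rows = []
    prev = None
    for d in d_values:
        cfg = dataclasses.replace(config, d=d)
        res = search_separation_rc(flat1, flat2, cfg)
        sim = np.nan if prev is None else abs(float(prev @ res.n_hat))
        rows.append({"d": d, "overlap": res.overlap_value, "similarity_prev": sim})
        prev = res.n_hat
    df = pd.DataFrame(rows)
    df["plateau"] = False
    hit = df.index[df["similarity_prev"] >= plateau_threshold]
    if len(hit):
        df.loc[hit[0], "plateau"] = True
    return df
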