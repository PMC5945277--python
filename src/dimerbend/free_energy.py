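"""Free-energy surfaces, umbrella sampling / WHAM, and basin energetics.

Profiles come from two sources: direct Boltzmann inversion of unbiased
projections (G = -ln rho / rho_max, in kT), and WHAM reconstruction from
umbrella windows with harmonic biases V_i(z) = 1/2 k (z - x_i)^2.
Uncertainties are estimated two ways: Bayesian bootstrap over complete
window histograms (Dirichlet weights), and, as an independent cross-check,
block-averaged mean-force errors integrated along the window ladder.

Basin analytics report depths relative to the dividing transition-state
maximum (negative numbers), their difference ddG, and the two-state
Boltzmann population of the deeper basin.

All free energies are in kT; spring constants in kJ/mol/nm^2 (default
temperature 300 K, kT = 2.494 kJ/mol).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .exceptions import (
    ConnectivityError,
    DegeneracyError,
    InputError,
    InsufficientDataError,
    NoBarrierError,
    OutOfRangeError,
)
from .units import DEFAULT_TEMPERATURE, kt_kj_per_mol


@dataclasses.dataclass
class UmbrellaWindow:
    """One umbrella window: bias parameters plus the sampled RC time series."""

    center: float                 # bias position x_i (nm)
    spring_k: float               # harmonic constant (kJ/mol/nm^2); 0 = unbiased
    series: np.ndarray            # time-ordered z(t) samples (nm)
    dt: float = 1.0               # sampling interval (arbitrary time unit)
    discard: int = 0              # initial equilibration samples to drop
    tau: float | None = None      # integrated autocorrelation time (samples)
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float).ravel()
        if self.spring_k < 0:
            raise InputError("spring_k must be >= 0")
        if self.discard >= self.series.size:
            raise InputError("discard span covers the whole series")

    @property
    def production(self) -> np.ndarray:
        return self.series[self.discard:]


@dataclasses.dataclass
class FreeEnergyProfile:
    """Binned free energies (kT) along one or two reaction coordinates."""

    axis: np.ndarray              # bin centers (nm)
    G: np.ndarray                 # free energy per bin (kT), min over occupied = 0
    err: np.ndarray               # per-bin standard error (kT)
    occupied: np.ndarray          # bool mask of bins with data
    axis2: np.ndarray | None = None  # second axis for 2-D profiles

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.err = np.asarray(self.err, dtype=float)
        self.occupied = np.asarray(self.occupied, dtype=bool)

    @property
    def bin_width(self) -> float:
        return float(self.axis[1] - self.axis[0]) if self.axis.size > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        if self.axis2 is not None:
            raise NotImplementedError("tabulation implemented for 1-D profiles")
        return pd.DataFrame(
            {"rc": self.axis, "G_kT": self.G, "err_kT": self.err, "occupied": self.occupied}
        )


@dataclasses.dataclass
class BasinAnalysis:
    """Depths of two basins relative to the dividing maximum, and populations."""

    dg_basin_1: float         # kT, negative (minimum below barrier)
    dg_basin_2: float         # kT
    ddg: float                # dg_basin_1 - dg_basin_2 (kT)
    p_deeper: float           # two-state Boltzmann population of the deeper basin
    barrier_position: float   # RC value of the dividing maximum (nm)
    minima_positions: tuple = ()


# ---------------------------------------------------------------------------
# Unbiased profiles
# ---------------------------------------------------------------------------

def pmf_from_projection(proj, bins=100, temperature: float = DEFAULT_TEMPERATURE,
                        range_=None) -> FreeEnergyProfile:
    """Boltzmann inversion of an unbiased projection: G = -ln(rho/rho_max) in kT.

    *proj* is a Projection or raw array; one column gives a 1-D profile, two
    columns a 2-D surface.  Empty bins are marked unoccupied, not zero.
    """
    coords = getattr(proj, "coords", proj)
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise InputError("empty projection")
    if coords.ndim == 1:
        coords = coords[:, None]
    if coords.shape[1] == 1:
        counts, edges = np.histogram(coords[:, 0], bins=bins, range=range_)
        centers = 0.5 * (edges[:-1] + edges[1:])
        occupied = counts > 0
        G = np.full(counts.shape, np.nan)
        G[occupied] = -np.log(counts[occupied] / counts.max())
        return FreeEnergyProfile(centers, G, np.zeros_like(G), occupied)
    if coords.shape[1] == 2:
        counts, xe, ye = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins,
                                        range=range_)
        occupied = counts > 0
        G = np.full(counts.shape, np.nan)
        G[occupied] = -np.log(counts[occupied] / counts.max())
        return FreeEnergyProfile(
            axis=0.5 * (xe[:-1] + xe[1:]),
            G=G,
            err=np.zeros_like(G),
            occupied=occupied,
            axis2=0.5 * (ye[:-1] + ye[1:]),
        )
    raise InputError("pmf_from_projection handles 1 or 2 coordinates")


def bias_energy(z, window: UmbrellaWindow):
    """Harmonic bias V_i(z) = 1/2 k (z - x_i)^2 in kJ/mol."""
    z = np.asarray(z, dtype=float)
    return 0.5 * window.spring_k * (z - window.center) ** 2


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def _window_histograms(windows, bins, range_=None):
    data = [w.production for w in windows]
    pooled = np.concatenate(data)
    if range_ is None:
        range_ = (pooled.min(), pooled.max())
    edges = np.histogram_bin_edges(pooled, bins=bins, range=range_)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_ib = np.stack([np.histogram(d, bins=edges)[0] for d in data]).astype(float)
    return centers, edges, n_ib


def _check_connectivity(windows, n_ib):
    """Windows must form one chain through shared occupied bins."""
    W = len(windows)
    if W == 1:
        return
    order = np.argsort([w.center for w in windows])
    occ = n_ib > 0
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occ[a] & occ[b]):
            # direct neighbours not overlapping is tolerable if the chain is
            # still connected through other windows
            reach = _connected(occ)
            if not reach:
                raise ConnectivityError(
                    f"no histogram overlap between windows at centers "
                    f"{windows[a].center:g} and {windows[b].center:g}"
                )
            warnings.warn(
                f"adjacent windows at {windows[a].center:g} and "
                f"{windows[b].center:g} share no occupied bin"
            )


def _connected(occ: np.ndarray) -> bool:
    W = occ.shape[0]
    adj = [
        {j for j in range(W) if j != i and np.any(occ[i] & occ[j])}
        for i in range(W)
    ]
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == W


def wham(windows, bins=100, temperature: float = DEFAULT_TEMPERATURE,
         tol: float = 1e-7, max_iter: int = 100_000, range_=None,
         window_weights=None, bias_offsets=None) -> FreeEnergyProfile:
    """Self-consistent WHAM reconstruction of the unbiased profile (kT).

    Equilibration spans (``window.discard``) are dropped first.  Iteration
    runs on the log window constants until the maximum change drops below
    *tol* (kT).  ``window_weights`` rescales whole windows (used by the
    Bayesian bootstrap); by default every window has weight 1.
    ``bias_offsets`` adds a constant (kJ/mol) to each window's bias — the
    reconstructed profile is invariant to these after min-alignment, which
    the tests exercise.
    """
    windows = list(windows)
    if not windows:
        raise InputError("no umbrella windows given")
    kT = kt_kj_per_mol(temperature)
    centers, edges, n_ib = _window_histograms(windows, bins, range_)
    _check_connectivity(windows, n_ib)
    if window_weights is not None:
        wgt = np.asarray(window_weights, dtype=float)[:, None]
        n_ib = n_ib * wgt
    N_i = n_ib.sum(axis=1)

    # Boltzmann factors of the biases at the bin centers
    biases = np.stack([bias_energy(centers, w) for w in windows])
    if bias_offsets is not None:
        biases = biases + np.asarray(bias_offsets, dtype=float)[:, None]
    c_ib = np.exp(-biases / kT)

    num = n_ib.sum(axis=0)
    occupied = num > 0
    g = np.zeros(len(windows))  # ln f_i
    P = np.zeros_like(centers)
    for _ in range(max_iter):
        denom = (N_i * np.exp(g)) @ c_ib
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, num / denom, 0.0)
        s = (c_ib * P).sum(axis=1)
        g_new = -np.log(s)
        g_new -= g_new[0]
        if np.max(np.abs(g_new - g)) < tol:
            g = g_new
            break
        g = g_new
    else:
        warnings.warn("WHAM did not reach tolerance within max_iter")

    denom = (N_i * np.exp(g)) @ c_ib
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(denom > 0, num / denom, 0.0)
    G = np.full_like(P, np.nan)
    with np.errstate(divide="ignore"):
        G[occupied] = -np.log(P[occupied])
    G[occupied] -= np.nanmin(G[occupied])
    return FreeEnergyProfile(centers, G, np.zeros_like(G), occupied)


# ---------------------------------------------------------------------------
# Time-series error machinery
# ---------------------------------------------------------------------------

def autocorr_time(series, c: float = 6.0) -> float:
    """Integrated autocorrelation time tau (samples).

    Convention: tau = 1/2 + sum_{t>=1} rho(t), summed to a self-consistent
    cutoff M >= c * tau(M) (default c = 6).  White noise gives tau = 1/2;
    an AR(1) process with coefficient phi gives (1 + phi) / (2 (1 - phi)).
    """
    z = np.asarray(series, dtype=float).ravel()
    if z.size < 100:
        raise InsufficientDataError("autocorrelation time needs >= 100 samples")
    z = z - z.mean()
    var = z @ z
    if var == 0:
        raise DegeneracyError("constant series has no autocorrelation time")
    n = z.size
    nfft = 1 << (2 * n - 1).bit_length()
    fz = np.fft.rfft(z, nfft)
    acov = np.fft.irfft(fz * np.conj(fz), nfft)[:n]
    rho = acov / acov[0]
    taus = 0.5 + np.cumsum(rho[1:])
    for m in range(1, n - 1):
        if m >= c * taus[m - 1]:
            return float(max(taus[m - 1], 1e-12))
    return float(max(taus[-1], 1e-12))


def block_size(T_i: int, tau: float) -> int:
    """Optimal block size T / (2 tau + 1), floored to >= 1."""
    if T_i <= 0:
        raise InputError("T_i must be positive")
    if tau < 0:
        raise InputError("tau must be >= 0")
    return max(1, int(T_i / (2.0 * tau + 1.0)))


def mean_force_error(windows, temperature: float = DEFAULT_TEMPERATURE,
                     min_blocks: int = 20) -> pd.DataFrame:
    """Block-average error of the mean force per window, with a propagated
    profile-level uncertainty (cross-check to the Bayesian bootstrap).

    For each window the standard error of the mean RC position is computed
    from block means at the optimal block size T/(2 tau + 1); the mean-force
    error is k times that.  Integrating force errors across the window
    ladder (in quadrature, spacing times force error) gives a cumulative
    profile uncertainty in kT.

    The formula sets the largest useful block; for weakly correlated series
    it approaches T/2, where two blocks would make the error-of-the-error
    enormous, so the block size is additionally capped to leave at least
    ``min_blocks`` blocks (any block longer than the correlation time is
    unbiased).
    """
    kT = kt_kj_per_mol(temperature)
    rows = []
    for w in windows:
        z = w.production
        tau = w.tau if w.tau is not None else autocorr_time(z)
        b = min(block_size(z.size, tau), max(1, z.size // min_blocks))
        n_blocks = z.size // b
        if n_blocks < 2:
            raise InsufficientDataError(
                f"window at {w.center:g} has fewer than 2 blocks of size {b}"
            )
        blocks = z[: n_blocks * b].reshape(n_blocks, b).mean(axis=1)
        se_mean = float(blocks.std(ddof=1) / np.sqrt(n_blocks))
        rows.append(
            {
                "center": w.center,
                "tau": tau,
                "block": b,
                "n_blocks": n_blocks,
                "se_mean_z": se_mean,
                "force_err_kT_per_nm": w.spring_k * se_mean / kT,
            }
        )
    df = pd.DataFrame(rows).sort_values("center").reset_index(drop=True)
    if len(df) > 1:
        spacing = np.gradient(df["center"].to_numpy())
    else:
        spacing = np.zeros(1)  # a single window spans no profile interval
    df["profile_err_kT"] = np.sqrt(
        np.cumsum((df["force_err_kT_per_nm"].to_numpy() * spacing) ** 2)
    )
    return df


def bootstrap_profile_error(windows, bins=100,
                            temperature: float = DEFAULT_TEMPERATURE,
                            n_boot: int = 50, seed=None, tol: float = 1e-7,
                            range_=None, equal_weights: bool = False) -> np.ndarray:
    """Bayesian bootstrap of complete window histograms.

    Each replica reruns WHAM with windows reweighted by Dirichlet(1, ..., 1)
    weights (scaled to mean 1); whole histograms are reweighted, never
    individual samples.  Replicas are min-aligned before taking the per-bin
    standard deviation.  ``equal_weights=True`` is a degenerate test hook
    that must give zero error.
    """
    if n_boot < 2:
        raise InputError("n_boot must be >= 2")
    windows = list(windows)
    rng = np.random.default_rng(seed)
    W = len(windows)
    pooled = np.concatenate([w.production for w in windows])
    if range_ is None:
        range_ = (pooled.min(), pooled.max())
    replicas = []
    for _ in range(n_boot):
        wgt = np.ones(W) if equal_weights else rng.dirichlet(np.ones(W)) * W
        prof = wham(windows, bins=bins, temperature=temperature, tol=tol,
                    range_=range_, window_weights=wgt)
        replicas.append(prof.G)
    stack = np.stack(replicas)  # already min-aligned by wham
    return np.nanstd(stack, axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Basin analytics
# ---------------------------------------------------------------------------

def _moving_average(y: np.ndarray, width: int = 3) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def population_fractions(ddg: float) -> tuple:
    """Signed two-state Boltzmann populations (p_basin_1, p_basin_2).

    ddg = dG_1 - dG_2 in kT; a positive ddg means basin 2 is deeper.  The
    two fractions sum to one exactly.
    """
    p1 = 1.0 / (1.0 + np.exp(ddg))
    return float(p1), float(1.0 - p1)


def population_fraction(ddg: float) -> float:
    """Two-state Boltzmann population of the deeper basin: 1/(1+exp(-|ddg|))."""
    if not np.isfinite(ddg):
        raise InputError("ddg must be finite")
    return float(1.0 / (1.0 + np.exp(-abs(ddg))))


def basin_analysis(profile: FreeEnergyProfile, split="auto") -> BasinAnalysis:
    """Basin depths relative to the dividing maximum, ddG, and populations.

    With ``split="auto"`` the dividing point is the highest interior maximum
    between the two deepest local minima of the 3-bin moving-averaged
    profile (raw histogram profiles are noisy); depths are reported from the
    raw free energies at the located bins, as negative numbers.
    """
    occ = profile.occupied
    x = profile.axis[occ]
    G = profile.G[occ]
    if G.size < 3:
        raise NoBarrierError("profile too short for basin analysis")
    Gs = _moving_average(G, 3)

    if split == "auto":
        interior = np.arange(1, G.size - 1)
        minima = interior[(Gs[interior] < Gs[interior - 1]) & (Gs[interior] <= Gs[interior + 1])]
        if minima.size < 2:
            raise NoBarrierError("profile has fewer than two local minima")
        deepest = minima[np.argsort(Gs[minima])[:2]]
        lo, hi = np.sort(deepest)
        if hi - lo < 2:
            raise NoBarrierError("minima are adjacent; no interior barrier")
        barrier = lo + 1 + int(np.argmax(Gs[lo + 1: hi]))
    else:
        barrier = int(np.argmin(np.abs(x - float(split))))
        if barrier in (0, G.size - 1):
            raise NoBarrierError("split point at the edge leaves a single basin")
        lo = int(np.argmin(G[:barrier]))
        hi = barrier + int(np.argmin(G[barrier:]))

    g_barrier = G[barrier]
    i1 = int(np.argmin(G[:barrier]))
    i2 = barrier + int(np.argmin(G[barrier:]))
    dg1 = float(G[i1] - g_barrier)
    dg2 = float(G[i2] - g_barrier)
    ddg = dg1 - dg2
    return BasinAnalysis(
        dg_basin_1=dg1,
        dg_basin_2=dg2,
        ddg=ddg,
        p_deeper=population_fraction(ddg) if ddg != 0 else 0.5,
        barrier_position=float(x[barrier]),
        minima_positions=(float(x[i1]), float(x[i2])),
    )


def kink_energy(profile: FreeEnergyProfile, position: float) -> float:
    """Free energy (kT) at a reference RC position above the profile minimum.

    Nearest-bin lookup; the position must fall inside the occupied range.
    """
    occ = profile.occupied
    x = profile.axis[occ]
    half = 0.5 * profile.bin_width if np.isfinite(profile.bin_width) else 0.0
    if position < x.min() - half or position > x.max() + half:
        raise OutOfRangeError(
            f"position {position:g} outside occupied range [{x.min():g}, {x.max():g}]"
        )
    idx = int(np.argmin(np.abs(x - position)))
    return float(profile.G[occ][idx])


def bond_energy_budget(longitudinal: float, lateral: float) -> float:
    """Combined energy of one longitudinal and one lateral lattice bond (kT).

    Bookkeeping helper for comparing bond energies against basin barriers."""
    return float(longitudinal + lateral)
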