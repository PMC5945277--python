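# Methods

`dimerbend` analyzes conformational ensembles of a flexible protein dimer —
the motivating system is the αβ-tubulin heterodimer, whose bending between
straight (lattice-like) and kinked (solution) conformations governs
microtubule assembly.  Four stages are implemented: PCA of structure
ensembles, a reaction-coordinate search that best separates two ensembles,
PLS-based functional mode analysis of bending, and umbrella-sampling/WHAM
free-energy reconstruction with basin analytics.  A synthetic-data module
plants known structure into every input so each stage is validated against
an analytic or brute-force oracle.

## Ensembles and superposition

An ensemble is F frames of N atoms (nm).  Rigid-body motion is removed by
unweighted Kabsch least-squares superposition of each frame onto a reference
over a mask of analysis atoms (default: protein backbone N/CA/C/O; flexible
termini are expected to be excluded by the mask).  Mass weighting is not
used.  Masked coordinates are flattened to an F × 3N matrix, the common
currency of all downstream stages.  PDB files are read and written through
biotite (Å converted to nm); XTC/DCD trajectories can be read through
MDAnalysis against a PDB topology.  Superposition requires at least three
non-collinear mask atoms; near-collinear structures make the rotation about
the long axis ill-conditioned, which is why the synthetic hinge dimer is
generated clearly kinked (see below).

## PCA (conformational modes)

The covariance of atomic positions C = ⟨(x −⟨x⟩)(x − ⟨x⟩)ᵀ⟩ is
diagonalized; eigenvectors are conformational modes, eigenvalues their
variances (nm²), and projections q_k = (x − ⟨x⟩)·v_k collective coordinates.
Numerical choices:

* covariance normalized by F (population convention — C is an ensemble
  average); this differs from 1/(F−1) by (F−1)/F on every eigenvalue;
* when 3N > F the decomposition runs through the F × F Gram matrix, exact
  for the ≤ F−1 nonzero modes and tractable for, e.g., ~100 experimental
  structures of a dimer with thousands of coordinates;
* eigenvalues below 1e-12 nm² are clipped to zero; eigenvector sign is fixed
  by making the largest-magnitude component positive, so downstream
  averaging and plots are reproducible;
* projections always center with the *basis* mean, so foreign ensembles
  (e.g. simulation frames projected onto an experimental-structure basis)
  share one coordinate system.

Superposition before PCA uses the full masked atom set of the dimer; an
alternative would be fitting on one monomer only, which changes how bending
is distributed between the subunits but not the machinery.

## Ensemble-separation reaction coordinate

Given two ensembles, the separation RC is the unit vector n minimizing the
overlap of the projected densities, O(n) = ∫ ρ̄₁(z,n) ρ̄₂(z,n) dz with
z = n·x.  The search is regularized by expressing n in the first d
eigenvectors of a PCA on the combined ensemble; d is increased until the
solution stabilizes (`sweep_d` reports the cosine similarity between
consecutive solutions and flags the plateau).

Each of `n_scans` independent scans draws `n_vectors` random unit vectors
(i.i.d. normal coordinates, normalized), keeps the candidate of minimal
overlap, and refines it by Nelder–Mead over unconstrained d-vectors with
normalization inside the objective (avoiding constrained optimization on
the sphere).  Because O(n) = O(−n), scan vectors are sign-aligned before
averaging: each is flipped to a positive dot product with the running mean,
the first scan defining the orientation.  The averaged, renormalized vector
is re-embedded into 3N space.  Convergence is monitored through the running
per-coordinate variance of the scan vectors.

Two density models are provided.  The default fits a Gaussian per side —
the overlap is then the closed form
exp(−(μ₁−μ₂)²/(2(σ₁²+σ₂²)))/√(2π(σ₁²+σ₂²)), smooth for the simplex and
computable in O(d²) per evaluation from the per-ensemble mean vectors and
covariance matrices.  A histogram model (Freedman–Diaconis bins on the
pooled samples, padded by three bin widths, shared-grid summation) is kept
as a cross-check; the two agree on well-sampled data and the tests pin the
Gaussian closed form against numerical quadrature.  Scans are averaged
unweighted.

Defaults are 500 scans × 2000 vectors; recovery tests use 20 × 200 with
fixed seeds, which already recovers a planted 8σ separation direction in
30 dimensions to |n_hat·v| > 0.99.

## Functional mode analysis (PLS)

A scalar functional quantity f — here the per-frame RMSD to a straight
reference structure — is regressed on the centered coordinates with
single-response PLS (NIPALS with deflation).  The component count k is the
regularization parameter; `cross_validate` fits on the first half of the
frames (matching the use of consecutive trajectory halves) and evaluates
the Pearson correlation Rv on the second half, choosing the smallest k
within 0.005 of the maximal Rv (parsimony rule; random splits are also
available).  Rm is the training correlation; `validate_independent`
evaluates a fitted model on a fresh ensemble.

The *ensemble-weighted mode* is the normalized coefficient vector of the
fitted linear map from centered coordinates to f̂ — the direction whose
motion correlates best with f.  At full rank PLS coincides with ordinary
least squares, which pins the construction in the tests (plus an
independent cross-check against scikit-learn's PLSRegression).  RMSD is a
nonlinear functional of the coordinates; it is nonetheless fitted linearly
and the adequacy of the model is judged purely by Rm/Rv.

## Free energies

Unbiased profiles are Boltzmann inversions of binned projections,
G = −ln(ρ̂/ρ̂_max) in kT, with empty bins marked unoccupied rather than
zero.  Umbrella windows carry a harmonic bias V_i(z) = ½k(z−x_i)² (k in
kJ/mol/nm²; energies reported in kT with kT = 2.494 kJ/mol at the default
300 K).  WHAM iterates the window constants self-consistently in log space
until the maximum change is below 1e-7 kT; each window's initial
equilibration span is discarded first; 100 bins over the occupied range by
default.  A single zero-bias window reduces WHAM exactly to Boltzmann
inversion, and the profile is invariant to adding a constant to any one
window's bias — both are asserted in the tests.  Windows must form a chain
connected through shared occupied bins (error otherwise; a warning if
adjacent-by-center windows only connect indirectly).

Uncertainties are estimated two ways:

* **Bayesian bootstrap of complete window histograms** — WHAM is rerun with
  whole windows reweighted by Dirichlet(1,…,1) weights (never individual
  samples); replicas are min-aligned and the per-bin standard deviation
  reported.
* **Block-averaged mean-force errors** (independent cross-check) — per
  window, the standard error of the mean RC position from block means, the
  mean-force error being k times that, integrated in quadrature along the
  window ladder.  The integrated autocorrelation time uses the convention
  τ = ½ + Σ_{t≥1} ρ(t) with a self-consistent summation cutoff at lag
  ≥ 6τ, so white noise gives τ = ½ and an AR(1) process (1+φ)/(2(1−φ)).
  The optimal block size is T/(2τ+1); since that approaches T/2 for weakly
  correlated series (where two blocks would make the error of the error
  enormous), the block size is additionally capped so at least 20 blocks
  remain — any block longer than the correlation time is unbiased, so the
  cap only stabilizes the estimate.

Basin analytics: with `split="auto"` the dividing point is the highest
interior maximum between the two deepest local minima of the 3-bin
moving-averaged profile (raw histogram profiles are noisy); depths are the
raw free energies of the minima relative to the barrier (negative numbers),
ΔΔG their difference, and the two-state Boltzmann populations
p₁ = 1/(1+e^ΔΔG), p₂ = 1−p₁ follow.  `kink_energy` reads the profile at a
reference position (nearest occupied bin) above the minimum — the strain
stored in a structure held at that position.  `bond_energy_budget` is
bookkeeping for comparing one longitudinal plus one lateral lattice-bond
energy against a basin barrier.

## Synthetic data: what it emulates and what it does not

* **Two-Gaussian ensembles** plant a unit separation direction with a given
  gap and covariance — a stand-in for straight vs. kinked simulation
  ensembles that do not overlap along some internal coordinate.
* **Hinge dimer**: two rigid bead arms joined at a pivot bead; the bending
  angle is Boltzmann-distributed for a harmonic hinge (variance 1/κ by
  equipartition, κ in kT/rad²), and with probability `p_state` the pivot is
  displaced out of the bending plane — a two-state "anchor" rearrangement
  geometrically orthogonal to bending.  Arms are built along fixed lab axes
  before jitter so the planted bending mode has a closed form.  The default
  equilibrium angle is 2.1 rad (clearly kinked): a near-straight hinge is
  almost collinear and makes superposition ill-conditioned about the rod
  axis.
* **Umbrella windows** are Metropolis-sampled on analytic 1-D potentials
  (harmonic, or a quartic double well h((z/w)²−1)² with exact barrier h).
  Metropolis rather than Langevin sampling is used deliberately: the
  stationary distribution is exact, so WHAM errors are attributable to
  WHAM, not to integrator bias.

The generators do not emulate anharmonic force fields, solvent friction,
correlated time series within windows (Metropolis correlation is short), or
the atom-count scale of a real dimer.  Passing tests therefore demonstrate
the correctness of the estimators and the geometric decoupling claim on
planted ground truth — not the reproduction of any simulation-scale free
energy, which would require microsecond MD inputs.

## Problem sizes

The test suite and analysis scripts use deliberately small study sizes:
20 scans × 200 vectors and 5000 frames/side for separation-search recovery,
600-frame hinge ensembles, 11 umbrella windows of 8,000–20,000 Metropolis
steps.  The full suite runs in well under five minutes on one CPU; all
randomness is seeded.

## Known limitations

* WHAM is 1-D; 2-D surfaces come only from unbiased projections.
* The separation RC is linear by construction; strongly curved dividing
  surfaces would need nonlinear coordinates.
* FMA fits a nonlinear functional (RMSD) linearly; quality is judged by
  Rm/Rv only.
* `basin_analysis` assumes exactly two basins of interest; multi-basin
  profiles report the two deepest.
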