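# dimerbend

Conformational-ensemble analysis of protein dimer bending: principal
component analysis of structure ensembles, an ensemble-separation
reaction-coordinate (RC) search, partial-least-squares functional mode
analysis (FMA), and umbrella-sampling/WHAM free-energy reconstruction with
basin energetics.

## The problem

Flexible protein dimers — the motivating case is αβ-tubulin, whose
kinked-to-straight transition underlies microtubule assembly — populate
distinct conformational states that simulations sample as non-overlapping
ensembles.  Three questions recur:

1. **What are the dominant collective motions?**  PCA of superposed
   coordinates: the covariance C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩ is diagonalized into
   conformational modes v_k with variances λ_k; projections
   q_k = (x−⟨x⟩)·v_k are the collective coordinates.
2. **Along which direction do two ensembles separate?**  The unit vector n
   minimizing the overlap of the projected densities,
   O(n) = ∫ ρ̄₁(z,n) ρ̄₂(z,n) dz with z = n·x, found by many independent
   random scans refined with downhill simplex in a d-dimensional PCA
   subspace, then averaged.  This reveals hidden barriers that the dominant
   (bending) modes mask.
3. **What motion drives a functional quantity, and how much does a state
   cost?**  FMA regresses f (e.g. RMSD to a straight reference) on the
   coordinate fluctuations, f = XᵀW_k β_k + ε, choosing k by
   cross-validation; umbrella sampling with harmonic biases ½k(z−x_i)² plus
   WHAM reconstructs G(z) in kT, from which basin depths ΔG (relative to
   the dividing barrier), their difference ΔΔG, two-state Boltzmann
   populations 1/(1+e^ΔΔG), and kinking strain energies follow.

Because real inputs are microseconds of MD, the package ships a
synthetic-data module that plants known ground truth — Gaussian ensembles
separated along a known vector, a hinge-dimer bead model with a
Boltzmann-distributed bending angle and a two-state "anchor" shift, and
Metropolis-sampled umbrella windows on analytic potentials — so every stage
is verified against an oracle.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write tables under `results/` (fixtures are regenerated on demand
under `scratch/`):

```sh
cd analysis
python 01_generate_data.py
python 02_pca_modes.py
python 03_separation_search.py
python 04_fma_bending.py
python 05_umbrella_wham.py
python 06_basin_energetics.py
```

Output (seeded, reproducible):

```
mode 1 carries 93.4% of the ensemble variance (mode 2: 4.1%)
mode-1 projection vs planted bending angle: |r| = 0.996

planted pair: |n_hat . v| = 0.9935, overlap O = 9.07e-09
hinge dimer: |cos(anchor RC, bending mode)| = 0.0002 (anchor transition is
decoupled from bending)

cross-validation: chosen k = 1, Rm = 0.999, Rv = 0.999
|cos(FMA mode, planted bending direction)| = 1.000

recovered barrier: 5.11 kT (analytic: 5.00 kT); RMS to analytic: 0.321 kT
ddG = -0.34 kT -> populations 0.5841 / 0.4159
a reported 8.6 kT depth difference corresponds to 99.98% in the deeper basin
```

Reading the numbers: the hinge dimer's first conformational mode is its
bending (93% of the variance, tracking the planted angle at r ≈ 1).  The
separation search between the two anchor states finds an RC essentially
orthogonal to bending — the planted rearrangement is a distinct, hidden
transition, invisible to the bending coordinate.  FMA recovers the bending
mode from the RMSD signal with one component.  WHAM rebuilds the 5 kT
double-well barrier from 11 umbrella windows within sampling error; the
symmetric well splits its population nearly 50/50, whereas a depth
difference of 8.6 kT would put 99.98% of the population into the deeper
basin.

The same stages are available as a CLI (`dimerbend synth|pca|separate|fma|
wham|basins|run`) and as one YAML-configured pipeline
(`dimerbend run --config pipeline.yml`).

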