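"""Structure-ensemble containers, superposition, and flattening.

Every downstream stage (PCA, reaction-coordinate search, functional mode
analysis) consumes an ensemble of conformations of a *fixed* atom set as an
F x 3N matrix of superposed Cartesian coordinates.  This module reads such
ensembles from PDB files (or MD trajectories), removes rigid-body motion by
unweighted Kabsch least-squares superposition onto a reference frame, and
flattens the masked coordinates into matrix form.

Coordinates are stored in nanometres; PDB Angstroms are converted on read
and write.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, DegeneracyError, InputError
from .units import ANGSTROM_PER_NM

#: Atom names treated as protein backbone by the default mask.
BACKBONE_NAMES = ("N", "CA", "C", "O")

MaskSpec = "str | Sequence[str] | np.ndarray | Callable"


@dataclasses.dataclass
class StructureEnsemble:
    """Ordered frames of 3-D coordinates for a fixed atom set.

    Parameters
    ----------
    coords
        Array of shape (F, N, 3), nanometres.
    atom_labels
        DataFrame with one row per atom: columns ``name``, ``res_id``,
        ``res_name``, ``chain``.
    frame_labels
        One identifier per frame (file stem, model number, or time in ns).
    reference_index
        Index of the frame used as superposition reference.
    mask
        Boolean array (N,) selecting the atoms used for analysis
        (superposition fit, flattening).  All atoms are transformed.
    """

    coords: np.ndarray
    atom_labels: pd.DataFrame
    frame_labels: list
    reference_index: int = 0
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConsistencyError(f"coords must be (F, N, 3), got {self.coords.shape}")
        if len(self.frame_labels) != self.n_frames:
            raise ConsistencyError("one frame label required per frame")
        if len(self.atom_labels) != self.n_atoms:
            raise ConsistencyError("one atom label row required per atom")
        if not (0 <= self.reference_index < self.n_frames):
            raise ConsistencyError(
                f"reference_index {self.reference_index} outside 0..{self.n_frames - 1}"
            )
        if self.mask is None:
            self.mask = np.ones(self.n_atoms, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_atoms,):
            raise ConsistencyError("mask length must equal atom count")
        if not self.mask.any():
            raise ConsistencyError("mask selects no atoms")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def masked_coords(self) -> np.ndarray:
        """(F, M, 3) view of the analysis atoms."""
        return self.coords[:, self.mask, :]

    def with_mask(self, mask_spec) -> "StructureEnsemble":
        """Return a copy with a new analysis mask resolved from *mask_spec*."""
        mask = resolve_mask(self.atom_labels, mask_spec)
        return dataclasses.replace(self, mask=mask)


@dataclasses.dataclass
class FlatEnsemble:
    """F x 3N matrix of masked, superposed coordinates plus its column mean.

    Coordinate ensembles have 3N columns (x1, y1, z1, x2, ...); abstract
    planted ensembles may use any column count, in which case ``n_atoms``
    treats every 3 columns as one pseudo-atom.
    """

    X: np.ndarray
    mean: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ConsistencyError("X must be 2-D (frames x columns)")
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != (self.X.shape[1],):
            raise ConsistencyError("mean length must equal column count")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_atoms(self) -> int:
        return max(1, self.X.shape[1] // 3)


def resolve_mask(atom_labels: pd.DataFrame, mask_spec) -> np.ndarray:
    """Resolve a mask specification against an atom-label table.

    Accepted forms: ``"all"``; ``"backbone"`` (N, CA, C, O); a sequence of
    atom names; a boolean array; or a callable mapping the label DataFrame to
    a boolean array.
    """
    n = len(atom_labels)
    if mask_spec is None or (isinstance(mask_spec, str) and mask_spec == "all"):
        return np.ones(n, dtype=bool)
    if isinstance(mask_spec, str) and mask_spec == "backbone":
        return atom_labels["name"].isin(BACKBONE_NAMES).to_numpy()
    if callable(mask_spec):
        return np.asarray(mask_spec(atom_labels), dtype=bool)
    arr = np.asarray(mask_spec)
    if arr.dtype == bool:
        if arr.shape != (n,):
            raise ConsistencyError("boolean mask length must equal atom count")
        return arr
    # sequence of atom names
    return atom_labels["name"].isin(list(mask_spec)).to_numpy()


# ---------------------------------------------------------------------------
# PDB / trajectory I/O (biotite for PDB, MDAnalysis for XTC/DCD)
# ---------------------------------------------------------------------------

def _labels_from_atom_array(array) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": array.atom_name,
            "res_id": array.res_id,
            "res_name": array.res_name,
            "chain": array.chain_id,
        }
    )


def _read_pdb_models(path: Path):
    """Return (coords_nm (M, N, 3), labels) for all models in one PDB file."""
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb.get_structure(pdb_file)
    except Exception as exc:  # unreadable / malformed file
        raise InputError(f"could not read PDB file {path}: {exc}") from exc
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:  # single model returned as AtomArray
        coords = coords[None]
    template = stack[0] if stack.stack_depth() else stack
    return coords / ANGSTROM_PER_NM, _labels_from_atom_array(template)


def read_pdb_ensemble(paths, mask_spec="backbone") -> StructureEnsemble:
    """Read an ensemble from PDB files (one frame per model per file).

    All files must resolve to the same masked atom count.  If every file also
    shares the full atom layout, all atoms are kept and the selection becomes
    the ensemble mask; otherwise only the selected atoms are retained (mask
    all-True) so frames remain stackable.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if not paths:
        raise InputError("no PDB paths given")

    per_file = []
    for p in paths:
        if not p.exists():
            raise InputError(f"PDB file not found: {p}")
        coords, labels = _read_pdb_models(p)
        mask = resolve_mask(labels, mask_spec)
        if not mask.any():
            raise ConsistencyError(f"atom selection matches no atoms in {p}")
        per_file.append((p, coords, labels, mask))

    masked_counts = {p.name: int(m.sum()) for p, _, _, m in per_file}
    if len(set(masked_counts.values())) != 1:
        raise ConsistencyError(f"masked atom counts differ across files: {masked_counts}")

    full_counts = {c.shape[1] for _, c, _, _ in per_file}
    same_layout = len(full_counts) == 1 and all(
        per_file[0][2]["name"].tolist() == labels["name"].tolist()
        for _, _, labels, _ in per_file
    )

    frames, frame_labels = [], []
    if same_layout:
        labels, mask = per_file[0][2], per_file[0][3]
        for p, coords, _, _ in per_file:
            for m in range(coords.shape[0]):
                frames.append(coords[m])
                frame_labels.append(p.stem if coords.shape[0] == 1 else f"{p.stem}:{m}")
    else:
        labels = per_file[0][2][per_file[0][3]].reset_index(drop=True)
        mask = np.ones(len(labels), dtype=bool)
        for p, coords, _, fmask in per_file:
            for m in range(coords.shape[0]):
                frames.append(coords[m][fmask])
                frame_labels.append(p.stem if coords.shape[0] == 1 else f"{p.stem}:{m}")

    return StructureEnsemble(
        coords=np.stack(frames),
        atom_labels=labels,
        frame_labels=frame_labels,
        reference_index=0,
        mask=mask,
    )


def read_trajectory_ensemble(topology, trajectory, mask_spec="backbone",
                             stride: int = 1) -> StructureEnsemble:
    """Read frames from an MD trajectory (XTC/DCD/...) against a PDB topology."""
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(topology), str(trajectory))
    except Exception as exc:
        raise InputError(f"could not open trajectory {trajectory}: {exc}") from exc
    labels = pd.DataFrame(
        {
            "name": u.atoms.names,
            "res_id": u.atoms.resids,
            "res_name": u.atoms.resnames,
            "chain": getattr(u.atoms, "chainIDs", np.full(len(u.atoms), "A")),
        }
    )
    mask = resolve_mask(labels, mask_spec)
    if not mask.any():
        raise ConsistencyError("atom selection matches no atoms in topology")
    frames, frame_labels = [], []
    for ts in u.trajectory[::stride]:
        frames.append(u.atoms.positions / ANGSTROM_PER_NM)  # MDAnalysis is in A
        frame_labels.append(f"t={ts.time:.1f}ps")
    return StructureEnsemble(np.stack(frames), labels, frame_labels, 0, mask)


def write_pdb_ensemble(ens: StructureEnsemble, path) -> None:
    """Write an ensemble as one multi-model PDB file (coordinates in A)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ens.n_atoms
    template = struc.AtomArray(n)
    template.atom_name = ens.atom_labels["name"].to_numpy(dtype="U6")
    template.res_id = ens.atom_labels["res_id"].to_numpy(dtype=int)
    template.res_name = ens.atom_labels["res_name"].to_numpy(dtype="U5")
    template.chain_id = ens.atom_labels["chain"].to_numpy(dtype="U4")
    template.element = np.array(
        [str(nm)[:1] if str(nm)[:1].isalpha() else "C" for nm in template.atom_name],
        dtype="U2",
    )
    stack = struc.stack([template] * ens.n_frames)
    stack.coord = ens.coords * ANGSTROM_PER_NM
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation R (3x3) minimizing ||P R - Q|| for centered P, Q (n x 3)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def superpose(ens: StructureEnsemble, reference: np.ndarray | None = None) -> StructureEnsemble:
    """Rigid-body superpose every frame onto the reference (unweighted Kabsch).

    The fit uses the masked atoms; the transform is applied to all atoms.
    *reference* may override the ensemble's own reference frame with external
    (N, 3) coordinates.  Raises :class:`DegeneracyError` for masks with fewer
    than three non-collinear atoms.
    """
    if ens.n_frames < 1:
        raise ConsistencyError("ensemble has no frames")
    ref_all = ens.coords[ens.reference_index] if reference is None else np.asarray(reference)
    if ref_all.shape != (ens.n_atoms, 3):
        raise ConsistencyError("reference shape must be (N, 3)")
    ref = ref_all[ens.mask]
    if ref.shape[0] < 3:
        raise DegeneracyError("superposition mask needs at least 3 atoms")
    ref_cm = ref.mean(axis=0)
    ref_c = ref - ref_cm
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise DegeneracyError("masked reference atoms are collinear or coincident")

    out = np.empty_like(ens.coords)
    for i in range(ens.n_frames):
        mob = ens.coords[i][ens.mask]
        cm = mob.mean(axis=0)
        R = kabsch_rotation(mob - cm, ref_c)
        out[i] = (ens.coords[i] - cm) @ R + ref_cm
    return dataclasses.replace(ens, coords=out)


def rmsd(frame_a, frame_b, superposition: bool = True) -> float:
    """RMSD (nm) between two frames, by default after optimal superposition.

    Frames may be given flat (3N,) or as (N, 3).
    """
    a = np.asarray(frame_a, dtype=float).reshape(-1, 3)
    b = np.asarray(frame_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ConsistencyError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if superposition:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        a = a @ kabsch_rotation(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def flatten(ens: StructureEnsemble) -> FlatEnsemble:
    """Concatenate masked coordinates per frame (x1, y1, z1, x2, ...)."""
    X = ens.masked_coords.reshape(ens.n_frames, -1)
    return FlatEnsemble(
        X=X.copy(),
        mean=X.mean(axis=0),
        provenance={
            "mask_indices": np.flatnonzero(ens.mask),
            "frame_labels": list(ens.frame_labels),
            "n_source_atoms": ens.n_atoms,
        },
    )


def unflatten(row: np.ndarray) -> np.ndarray:
    """Reshape one flat 3N vector back to (N, 3) coordinates."""
    row = np.asarray(row, dtype=float)
    return row.reshape(-1, 3)


def write_flat(flat: FlatEnsemble, path, frame_labels=None) -> None:
    """Write a FlatEnsemble as tab-delimited text (one frame per row)."""
    d = flat.X.shape[1]
    if d % 3 == 0:
        cols = [f"{ax}{i}" for i in range(d // 3) for ax in ("x", "y", "z")]
    else:
        cols = [f"c{i}" for i in range(d)]
    df = pd.DataFrame(flat.X, columns=cols)
    labels = frame_labels or flat.provenance.get("frame_labels")
    if labels is not None and len(labels) == flat.n_frames:
        df.insert(0, "frame", labels)
    df.to_csv(path, sep="\t", index=False)


def read_flat(path) -> FlatEnsemble:
    """Read a FlatEnsemble written by :func:`write_flat`."""
    df = pd.read_csv(path, sep="\t")
    labels = None
    if "frame" in df.columns:
        labels = df.pop("frame").tolist()
    X = df.to_numpy(dtype=float)
    prov = {"source": str(path)}
    if labels is not None:
        prov["frame_labels"] = labels
    return FlatEnsemble(X=X, mean=X.mean(axis=0), provenance=prov)


def write_flat_npz(flat: FlatEnsemble, path) -> None:
    """Binary container: an ``.npz`` with arrays ``X`` and ``mean``."""
    np.savez(path, X=flat.X, mean=flat.mean)


def read_flat_npz(path) -> FlatEnsemble:
    with np.load(path) as data:
        return FlatEnsemble(X=data["X"], mean=data["mean"], provenance={"source": str(path)})


def generic_atom_labels(n_atoms: int, name: str = "CA") -> pd.DataFrame:
    """Placeholder labels for synthetic bead models (one residue per bead)."""
    return pd.DataFrame(
        {
            "name": [name] * n_atoms,
            "res_id": np.arange(1, n_atoms + 1),
            "res_name": ["GLY"] * n_atoms,
            "chain": ["A"] * n_atoms,
        }
    )
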