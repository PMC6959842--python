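"""Trajectory containers and I/O.

Reads topology (PDB/PSF) and coordinate (DCD/XTC) files through MDAnalysis,
resamples frames, strips solvent/ions, superposes frames onto a reference by
rigid-body (Kabsch) fitting, and concatenates trajectories of common atoms.
All downstream analysis stages consume the :class:`Trajectory` produced here:
solvent-free, aligned coordinates in Å with a per-frame system label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "load_trajectory",
    "strip_solvent",
    "superpose",
    "concatenate",
    "kabsch",
    "SOLVENT_RESNAMES",
    "ION_RESNAMES",
]

# Residue-name tables for molecule classification. Topology formats disagree
# on naming (CHARMM vs PDB conventions), so these are deliberately generous
# and user-extensible via the ``extra_*`` arguments of ``classify_molecules``.
SOLVENT_RESNAMES = {
    "HOH", "H2O", "WAT", "SOL", "TIP", "TIP3", "TP3", "TIP4", "TP4", "TIP5", "SPC", "SPCE",
}
ION_RESNAMES = {
    "NA", "NA+", "SOD", "CL", "CL-", "CLA", "K", "K+", "POT", "MG", "MG2",
    "CAL", "CA2", "ZN", "ZN2", "CES", "LIT", "RUB", "BAR",
}
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}
NUCLEIC_RESNAMES = {
    "DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U", "T",
    "ADE", "CYT", "GUA", "THY", "URA", "RA", "RC", "RG", "RU",
    "DA5", "DC5", "DG5", "DT5", "DA3", "DC3", "DG3", "DT3", "FDU", "5FU",
}

MOLECULE_CLASSES = ("protein", "nucleic", "cofactor", "solvent", "ion")


class StructuralError(ValueError):
    """Topology and coordinates disagree (atom counts, identities...)."""


class EmptySelectionError(ValueError):
    """A selection resolved to zero atoms."""


class DegenerateFitError(ValueError):
    """Superposition selection is too small or collinear."""


class IncompatibleTrajectoriesError(ValueError):
    """Trajectories cannot be concatenated under the common-atom rule."""


@dataclass
class Topology:
    """Per-atom metadata for one system.

    Arrays are index-aligned; atom indices are implicit and contiguous from 0.
    ``moltype`` holds one of :data:`MOLECULE_CLASSES` per atom; ``heavy`` is
    False exactly for hydrogens.
    """

    names: np.ndarray           # str per atom
    elements: np.ndarray        # str per atom, e.g. "C", "H", "N"
    resnames: np.ndarray        # str per atom
    resids: np.ndarray          # int per atom
    segids: np.ndarray          # str per atom (segment / chain)
    moltype: np.ndarray         # str per atom, one of MOLECULE_CLASSES
    bonds: np.ndarray | None = None  # (n_bonds, 2) atom-index pairs, optional

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "resnames", "resids", "segids", "moltype"):
            if len(getattr(self, attr)) != n:
                raise StructuralError(f"topology field {attr!r} length != atom count {n}")
        bad = set(np.unique(self.moltype)) - set(MOLECULE_CLASSES)
        if bad:
            raise StructuralError(f"unknown molecule classes: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def heavy(self) -> np.ndarray:
        """Heavy-atom flag: False iff the element is hydrogen."""
        return np.char.upper(self.elements.astype(str)) != "H"

    def residue_descriptors(self) -> np.ndarray:
        """Per-atom residue descriptor 'SEG:Resname123' (field style, e.g. MSH6:Thr781)."""
        res = np.char.add(
            np.char.capitalize(self.resnames.astype(str)),
            self.resids.astype(str),
        )
        return np.char.add(np.char.add(self.segids.astype(str), ":"), res)

    def atom_subset(self, indices: np.ndarray) -> "Topology":
        """Reindexed topology restricted to ``indices`` (order preserved)."""
        indices = np.asarray(indices, dtype=np.intp)
        bonds = None
        if self.bonds is not None and len(self.bonds):
            remap = -np.ones(self.n_atoms, dtype=np.intp)
            remap[indices] = np.arange(len(indices))
            keep = np.all(remap[self.bonds] >= 0, axis=1)
            bonds = remap[self.bonds[keep]]
        return Topology(
            names=self.names[indices],
            elements=self.elements[indices],
            resnames=self.resnames[indices],
            resids=self.resids[indices],
            segids=self.segids[indices],
            moltype=self.moltype[indices],
            bonds=bonds,
        )

    def identity_keys(self) -> list[tuple]:
        """(segid, resid, resname, name) per atom — the cross-system atom identity."""
        return list(
            zip(
                self.segids.tolist(),
                self.resids.tolist(),
                self.resnames.tolist(),
                self.names.tolist(),
            )
        )


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) with topology and per-frame labels.

    ``frame_interval`` is the time between stored frames in ps.  ``labels``
    carries the system/damage-class name of each frame and survives
    concatenation, which is what lets the classifier stages downstream know
    which system a frame came from.
    """

    topology: Topology
    coords: np.ndarray                    # (n_frames, n_atoms, 3) float, Å
    frame_interval: float = 1.0           # ps
    labels: np.ndarray = field(default=None)  # str per frame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructuralError(f"coords must be (frames, atoms, 3); got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise StructuralError("trajectory needs >= 1 frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructuralError(
                f"coordinate atom count {self.coords.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructuralError("non-finite coordinates")
        if self.labels is None:
            self.labels = np.full(self.n_frames, "system", dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.n_frames:
            raise StructuralError("label count != frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_subset(self, indices: np.ndarray) -> "Trajectory":
        indices = np.asarray(indices, dtype=np.intp)
        if indices.size == 0:
            raise EmptySelectionError("atom subset is empty")
        return Trajectory(
            topology=self.topology.atom_subset(indices),
            coords=self.coords[:, indices, :],
            frame_interval=self.frame_interval,
            labels=self.labels.copy(),
        )

    def ca_indices(self) -> np.ndarray:
        """Protein alpha-carbon atom indices (the default fit/analysis subset)."""
        top = self.topology
        mask = (np.char.upper(top.names.astype(str)) == "CA") & (top.moltype == "protein")
        return np.flatnonzero(mask)


def classify_molecules(
    resnames: np.ndarray,
    elements: np.ndarray,
    extra_solvent: set[str] | None = None,
    extra_ions: set[str] | None = None,
) -> np.ndarray:
    """Assign a molecule class per atom from residue-name tables.

    Single-atom non-hydrogen residues with ionic names are ions; unknown
    residue names fall through to 'cofactor' (ADP, drugs, modified bases that
    are not in the nucleic table).
    """
    solvent = SOLVENT_RESNAMES | (extra_solvent or set())
    ions = ION_RESNAMES | (extra_ions or set())
    out = np.empty(len(resnames), dtype=object)
    for i, rn in enumerate(np.char.upper(resnames.astype(str))):
        if rn in solvent:
            out[i] = "solvent"
        elif rn in ions:
            out[i] = "ion"
        elif rn in PROTEIN_RESNAMES:
            out[i] = "protein"
        elif rn in NUCLEIC_RESNAMES:
            out[i] = "nucleic"
        else:
            out[i] = "cofactor"
    return out


def _elements_from_universe(u) -> np.ndarray:
    try:
        return np.asarray([e.capitalize() for e in u.atoms.elements], dtype=object)
    except Exception:
        # PSF/DCD inputs often lack elements; fall back on the leading
        # alphabetic character of the atom name (CHARMM convention).
        els = []
        for name in u.atoms.names:
            alpha = [c for c in str(name) if c.isalpha()]
            els.append(alpha[0].upper() if alpha else "X")
        return np.asarray(els, dtype=object)


def topology_from_universe(u, extra_solvent=None, extra_ions=None) -> Topology:
    """Build a :class:`Topology` from an ``MDAnalysis.Universe``."""
    elements = _elements_from_universe(u)
    resnames = np.asarray(u.atoms.resnames, dtype=object)
    try:
        segids = np.asarray(u.atoms.segids, dtype=object)
    except Exception:
        segids = np.full(len(u.atoms), "SYS", dtype=object)
    try:
        bonds = np.asarray(u.bonds.to_indices(), dtype=np.intp) if len(u.bonds) else None
    except Exception:
        bonds = None
    return Topology(
        names=np.asarray(u.atoms.names, dtype=object),
        elements=elements,
        resnames=resnames,
        resids=np.asarray(u.atoms.resids, dtype=np.int64),
        segids=segids,
        moltype=classify_molecules(resnames, elements, extra_solvent, extra_ions),
        bonds=bonds,
    )


def load_trajectory(
    topology_file,
    coords_file,
    stride: int = 1,
    label: str = "system",
    frame_interval: float | None = None,
    extra_solvent: set[str] | None = None,
    extra_ions: set[str] | None = None,
) -> Trajectory:
    """Read a trajectory, keeping frames 0, stride, 2·stride, ...

    ``frame_interval`` is the time per *stored input* frame in ps (taken from
    the file when it records one); the returned trajectory's interval is
    multiplied by ``stride``.  Every frame carries ``label``.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology_file), str(coords_file))
    except OSError as exc:
        raise IOError(f"cannot read {topology_file!s} / {coords_file!s}: {exc}") from exc
    except ValueError as exc:
        raise StructuralError(
            f"topology {topology_file!s} does not match coordinates {coords_file!s}: {exc}"
        ) from exc
    top = topology_from_universe(u, extra_solvent, extra_ions)
    coords = np.stack([u.atoms.positions.astype(np.float64) for _ in u.trajectory[::stride]])
    if frame_interval is None:
        dt = getattr(u.trajectory, "dt", None)
        frame_interval = float(dt) if dt else 1.0
    return Trajectory(
        topology=top,
        coords=coords,
        frame_interval=frame_interval * stride,
        labels=np.full(coords.shape[0], label, dtype=object),
    )


def write_trajectory(traj: Trajectory, topology_path, coords_path) -> None:
    """Write the trajectory as a PDB topology plus DCD coordinates."""
    import MDAnalysis as mda

    top = traj.topology
    n = top.n_atoms
    resids, res_index = np.unique(top.resids, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=len(resids), atom_resindex=res_index, trajectory=True
    )
    u.add_TopologyAttr("names", top.names.tolist())
    u.add_TopologyAttr("elements", top.elements.tolist())
    u.add_TopologyAttr("resids", resids)
    first_atom = np.asarray([np.argmax(res_index == r) for r in range(len(resids))])
    u.add_TopologyAttr("resnames", top.resnames[first_atom].tolist())
    u.add_TopologyAttr("segids", [str(top.segids[0])])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.positions = traj.coords[0]
        u.atoms.write(str(topology_path))
        with mda.Writer(str(coords_path), n) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                w.write(u.atoms)


def strip_solvent(traj: Trajectory) -> Trajectory:
    """Drop solvent and ion atoms; topology is reindexed contiguously."""
    keep = ~np.isin(traj.topology.moltype, ("solvent", "ion"))
    if not keep.any():
        raise EmptySelectionError("stripping solvent/ions removed every atom")
    if keep.all():
        return traj
    return traj.atom_subset(np.flatnonzero(keep))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R (det +1) and translation t minimising ||(P R + t) − Q||.

    Rows of P are moved onto rows of Q. Reflections are rejected by flipping
    the sign of the smallest singular direction when det < 0.
    """
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = qc - pc @ R
    return R, t


def superpose(
    traj: Trajectory,
    fit_selection: np.ndarray | None = None,
    reference: int = 0,
    reference_coords: np.ndarray | None = None,
) -> Trajectory:
    """Least-squares rigid-body fit of every frame onto a reference.

    ``fit_selection`` defaults to protein alpha carbons.  The reference is
    frame ``reference`` of this trajectory unless explicit
    ``reference_coords`` (full atom set, Å) are given — the latter is how
    several trajectories are put on one common frame before concatenated PCA.
    """
    if fit_selection is None:
        fit_selection = traj.ca_indices()
        if fit_selection.size == 0:
            fit_selection = np.flatnonzero(traj.topology.heavy)
    fit_selection = np.asarray(fit_selection, dtype=np.intp)
    if fit_selection.size < 3:
        raise DegenerateFitError("need >= 3 fit atoms")
    ref_all = traj.coords[reference] if reference_coords is None else np.asarray(reference_coords)
    ref = ref_all[fit_selection]
    # collinearity check: rank of centered reference selection must be >= 2
    if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-8) < 2:
        raise DegenerateFitError("fit selection is collinear")
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        mobile = traj.coords[f, fit_selection]
        before = np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1)))
        R, t = kabsch(mobile, ref)
        moved = traj.coords[f] @ R + t
        after = np.sqrt(np.mean(np.sum((moved[fit_selection] - ref) ** 2, axis=1)))
        if after > before + 1e-9:
            raise RuntimeError("superposition increased RMSD (numerical failure)")
        out[f] = moved
    return replace(traj, coords=out, labels=traj.labels.copy())


def concatenate(trajs: list[Trajectory], common_atoms: str = "intersection") -> Trajectory:
    """Append trajectories of common atoms in input order, keeping labels.

    ``common_atoms='intersection'`` restricts every input to the atoms whose
    (segid, resid, resname, name) identity occurs in all inputs, in the first
    trajectory's order; ``'strict'`` requires identical atom identity
    sequences and raises on the first mismatch.
    """
    if not trajs:
        raise ValueError("need >= 1 trajectory")
    if len(trajs) == 1:
        return trajs[0]
    keys = [t.topology.identity_keys() for t in trajs]
    if common_atoms == "strict":
        for i, k in enumerate(keys[1:], start=1):
            if k != keys[0]:
                n = min(len(k), len(keys[0]))
                for j in range(n):
                    if k[j] != keys[0][j]:
                        raise IncompatibleTrajectoriesError(
                            f"atom {j} differs between input 0 and input {i}: "
                            f"{keys[0][j]} vs {k[j]}"
                        )
                raise IncompatibleTrajectoriesError(
                    f"atom counts differ: {len(keys[0])} vs {len(k)} (inputs 0 and {i})"
                )
        subsets = [np.arange(t.n_atoms) for t in trajs]
    elif common_atoms == "intersection":
        common = set(keys[0])
        for k in keys[1:]:
            common &= set(k)
        if not common:
            raise IncompatibleTrajectoriesError(
                f"no common atoms; first atom of input 0 is {keys[0][0]}"
            )
        order = [key for key in keys[0] if key in common]
        subsets = []
        for k in keys:
            lookup = {key: i for i, key in enumerate(k)}
            if len(lookup) != len(k):
                raise IncompatibleTrajectoriesError("duplicate atom identities in an input")
            subsets.append(np.asarray([lookup[key] for key in order], dtype=np.intp))
    else:
        raise ValueError(f"unknown common_atoms rule {common_atoms!r}")
    parts = [
        t if np.array_equal(s, np.arange(t.n_atoms)) else t.atom_subset(s)
        for t, s in zip(trajs, subsets)
    ]
    coords = np.concatenate([p.coords for p in parts], axis=0)
    labels = np.concatenate([p.labels for p in parts])
    return Trajectory(
        topology=parts[0].topology,
        coords=coords,
        frame_interval=trajs[0].frame_interval,
        labels=labels,
    )
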