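"""Synthetic data with planted, recoverable structure.

Every analysis stage in this package is validated by parameter recovery on
data whose ground truth is known by construction:

* :func:`gen_hbond_matrix` — per-frame binary hydrogen-bond indicators whose
  per-class Bernoulli occupancies hide a small set of class-discriminative
  bonds among uninformative background bonds (what a damage classifier
  should find).
* :func:`gen_trajectory` — coordinates drawn from a mixture of Gaussian
  conformational wells with class-dependent occupancy, planted high-mobility
  atoms, planted correlated atom pairs, and donor–H–acceptor triads whose
  geometry toggles across the hydrogen-bond criteria.
* :func:`gen_ring_pair` / :func:`gen_stacking_trajectory` — two-ring
  geometries in stacked and unstacked poses for the stacking classifier.

All generators take an explicit seed and draw from one local
``numpy.random.Generator``; the same seed reproduces output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Topology, Trajectory

__all__ = [
    "HBondPlantSpec",
    "ConformerPlantSpec",
    "gen_hbond_matrix",
    "gen_trajectory",
    "gen_ring_pair",
    "gen_stacking_trajectory",
]

AMINO_CYCLE = ["ALA", "GLY", "SER", "THR", "LEU", "VAL", "ASN", "GLN", "LYS", "GLU"]


class SpecValidationError(ValueError):
    pass


@dataclass
class HBondPlantSpec:
    """Plan for a planted binary hydrogen-bond feature matrix.

    ``occupancy[c, f]`` is the Bernoulli probability that bond ``f`` is
    present in a frame of class ``c``.  ``planted`` lists the indices meant
    to be class-discriminative; the rest are background.
    """

    class_names: list[str]
    n_frames: int                      # frames per class
    occupancy: np.ndarray              # (n_classes, n_features) in [0, 1]
    planted: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.float64)
        if self.occupancy.ndim != 2 or self.occupancy.shape[0] != len(self.class_names):
            raise SpecValidationError("occupancy must be (n_classes, n_features)")
        if np.any(self.occupancy < 0) or np.any(self.occupancy > 1):
            raise SpecValidationError("occupancy probabilities must lie in [0, 1]")
        if self.n_frames < 1:
            raise SpecValidationError("n_frames must be >= 1")
        if any(j < 0 or j >= self.n_features for j in self.planted):
            raise SpecValidationError("planted index out of range")

    @property
    def n_features(self) -> int:
        return self.occupancy.shape[1]

    @classmethod
    def default(
        cls,
        n_planted: int = 2,
        n_background: int = 50,
        n_frames: int = 5000,
        p_on: float = 0.9,
        p_off: float = 0.05,
        p_background: float = 0.3,
        class_names: tuple[str, ...] = ("Carbo", "Cis", "FdU"),
        seed: int = 0,
    ) -> "HBondPlantSpec":
        """Three damage classes × 5000 frames: ``n_planted`` discriminative
        bonds (0.9 occupancy in their own class, 0.05 elsewhere) among 50
        background bonds at 0.3 — the default study-sized fixture."""
        n_classes = len(class_names)
        occ = np.full((n_classes, n_planted + n_background), p_background)
        for j in range(n_planted):
            occ[:, j] = p_off
            occ[j % n_classes, j] = p_on
        return cls(
            class_names=list(class_names),
            n_frames=n_frames,
            occupancy=occ,
            planted=list(range(n_planted)),
            seed=seed,
        )


def gen_hbond_matrix(spec: HBondPlantSpec):
    """Draw the planted binary matrix; returns ``(FeatureMatrix, labels)``.

    Entry (frame, bond) ~ Bernoulli(occupancy[class(frame), bond]),
    independently, from one generator seeded with ``spec.seed``.
    """
    from .hbonds import FeatureMatrix

    rng = np.random.default_rng(spec.seed)
    blocks, labels = [], []
    for c, name in enumerate(spec.class_names):
        u = rng.random((spec.n_frames, spec.n_features))
        blocks.append((u < spec.occupancy[c]).astype(np.uint8))
        labels.extend([name] * spec.n_frames)
    matrix = np.concatenate(blocks, axis=0)
    descriptors = [f"SYN:Bnd{j:03d}A–SYN:Bnd{j:03d}B" for j in range(spec.n_features)]
    labels = np.asarray(labels, dtype=object)
    return FeatureMatrix(matrix=matrix, descriptors=descriptors, labels=labels), labels


@dataclass
class ConformerPlantSpec:
    """Plan for a planted coordinate trajectory.

    A frame picks a conformational well by its class's occupancy
    distribution, every atom gets isotropic Gaussian displacement (flexible
    atoms inflated by ``flex_scale``), listed atom pairs share a latent
    Gaussian factor giving an exact target Pearson coupling, and each
    donor–hydrogen–acceptor triad is placed in hydrogen-bond geometry with a
    per-class probability.
    """

    n_atoms: int
    well_centers: np.ndarray                 # (n_wells, n_atoms, 3) Å
    well_spreads: np.ndarray                 # (n_wells,) Å, > 0
    class_occupancy: dict                    # class name -> (n_wells,) probs
    n_frames: int = 500                      # frames per class
    flexible_atoms: list[int] = field(default_factory=list)
    flex_scale: float = 3.0
    correlated_pairs: list[tuple] = field(default_factory=list)  # (a, b, rho)
    triads: list[tuple] = field(default_factory=list)            # (D, H, A) atom indices
    triad_bond_prob: dict = field(default_factory=dict)          # class -> prob per triad
    frame_interval: float = 100.0            # ps, mirrors every-tenth-frame resampling
    seed: int = 0

    def __post_init__(self) -> None:
        self.well_centers = np.asarray(self.well_centers, dtype=np.float64)
        self.well_spreads = np.asarray(self.well_spreads, dtype=np.float64)
        if self.well_centers.shape[1:] != (self.n_atoms, 3):
            raise SpecValidationError("well_centers must be (n_wells, n_atoms, 3)")
        if np.any(self.well_spreads < 0):
            raise SpecValidationError("well spreads must be >= 0")
        for cname, occ in self.class_occupancy.items():
            occ = np.asarray(occ, dtype=np.float64)
            if occ.shape != (self.n_wells,) or abs(occ.sum() - 1.0) > 1e-9 or np.any(occ < 0):
                raise SpecValidationError(f"occupancy for class {cname!r} must sum to 1")
        seen_exact = {}
        for a, b, rho in self.correlated_pairs:
            if not -1.0 <= rho <= 1.0:
                raise SpecValidationError("coupling must lie in [-1, 1]")
            if abs(rho) == 1.0:
                for atom in (a, b):
                    if atom in seen_exact:
                        raise SpecValidationError(
                            f"atom {atom} appears in two |coupling| = 1 pairs (singular)"
                        )
                    seen_exact[atom] = rho

    @property
    def n_wells(self) -> int:
        return self.well_centers.shape[0]

    @property
    def class_names(self) -> list[str]:
        return list(self.class_occupancy)

    @classmethod
    def default(
        cls,
        n_atoms: int = 60,
        n_wells: int = 3,
        n_frames: int = 500,
        spread: float = 0.5,
        separation: float = 12.0,
        seed: int = 0,
        **kwargs,
    ) -> "ConformerPlantSpec":
        """Three classes, each dominated by its own well (80/10/10 occupancy),
        wells laid out as a rigid chain shifted by ``separation`` Å."""
        rng = np.random.default_rng(seed)
        base = rng.normal(scale=4.0, size=(n_atoms, 3)) + 20.0
        # Wells are internal rearrangements, not rigid-body moves: every atom
        # is displaced on a circle in its own random plane, so adjacent wells
        # sit exactly 'separation' Å apart at every atom (all pairs, for 3
        # wells), the well vectors are non-collinear in 3N space, and no
        # global rotation/translation can superpose one well onto another.
        if n_wells == 1:
            centers = base[None, :, :].copy()
        else:
            radius = separation / (2.0 * np.sin(np.pi / n_wells))
            e1 = rng.normal(size=(n_atoms, 3))
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            raw = rng.normal(size=(n_atoms, 3))
            e2 = raw - (raw * e1).sum(axis=1, keepdims=True) * e1
            e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
            ang = 2.0 * np.pi * np.arange(n_wells) / n_wells
            centers = np.stack(
                [
                    base + radius * (np.cos(a) * e1 + np.sin(a) * e2)
                    for a in ang
                ]
            )
        names = ["Carbo", "Cis", "FdU"][:n_wells] or ["Carbo"]
        occ = {}
        for c, name in enumerate(names):
            row = np.full(n_wells, 0.1 / max(n_wells - 1, 1))
            row[c] = 0.9 if n_wells > 1 else 1.0
            row /= row.sum()
            occ[name] = row
        return cls(
            n_atoms=n_atoms,
            well_centers=centers,
            well_spreads=np.full(n_wells, spread),
            class_occupancy=occ,
            n_frames=n_frames,
            seed=seed,
            **kwargs,
        )


def _conformer_topology(spec: ConformerPlantSpec) -> Topology:
    n = spec.n_atoms
    names = np.asarray(["CA"] * n, dtype=object)
    elements = np.asarray(["C"] * n, dtype=object)
    resnames = np.asarray([AMINO_CYCLE[i % len(AMINO_CYCLE)] for i in range(n)], dtype=object)
    bonds = []
    for d, h, a in spec.triads:
        names[d], elements[d] = "ND", "N"
        names[h], elements[h] = "HD", "H"
        names[a], elements[a] = "OA", "O"
        bonds.append((d, h))
    return Topology(
        names=names,
        elements=elements,
        resnames=resnames,
        resids=np.arange(1, n + 1, dtype=np.int64),
        segids=np.asarray(["SYN"] * n, dtype=object),
        moltype=np.asarray(["protein"] * n, dtype=object),
        bonds=np.asarray(bonds, dtype=np.intp) if bonds else None,
    )


def gen_trajectory(spec: ConformerPlantSpec):
    """Sample the planted trajectory; returns ``(Trajectory, ground_truth)``.

    ``ground_truth`` holds the well index of every frame, the per-frame
    bonded state of every triad, and the planted atom sets, so recovery
    tests can score clustering, hydrogen-bond detection, RMSF and DCCM
    without re-deriving anything.
    """
    rng = np.random.default_rng(spec.seed)
    classes = spec.class_names
    n_total = spec.n_frames * len(classes)
    n = spec.n_atoms

    labels = np.concatenate([[c] * spec.n_frames for c in classes]).astype(object)
    wells = np.empty(n_total, dtype=np.intp)
    for i, c in enumerate(classes):
        occ = np.asarray(spec.class_occupancy[c], dtype=np.float64)
        wells[i * spec.n_frames:(i + 1) * spec.n_frames] = rng.choice(
            spec.n_wells, size=spec.n_frames, p=occ
        )

    sigma_scale = np.ones(n)
    sigma_scale[np.asarray(spec.flexible_atoms, dtype=int)] = spec.flex_scale
    base_sigma = spec.well_spreads[wells][:, None] * sigma_scale[None, :]  # (F, n)

    z = rng.standard_normal((n_total, n, 3))
    # shared-latent construction: corr(displacement_a, displacement_b) = rho exactly
    for a, b, rho in spec.correlated_pairs:
        z[:, b, :] = rho * z[:, a, :] + np.sqrt(max(0.0, 1.0 - rho * rho)) * z[:, b, :]
    coords = spec.well_centers[wells] + base_sigma[:, :, None] * z

    bonded = np.zeros((n_total, len(spec.triads)), dtype=bool)
    if spec.triads:
        for i, c in enumerate(classes):
            probs = np.atleast_1d(np.asarray(spec.triad_bond_prob.get(c, 0.5), dtype=np.float64))
            if probs.size == 1:
                probs = np.repeat(probs, len(spec.triads))
            sl = slice(i * spec.n_frames, (i + 1) * spec.n_frames)
            bonded[sl] = rng.random((spec.n_frames, len(spec.triads))) < probs[None, :]
        u = np.array([1.0, 0.0, 0.0])
        for t, (d, h, a) in enumerate(spec.triads):
            D = coords[:, d, :]
            coords[:, h, :] = D + 1.0 * u
            dist = np.where(bonded[:, t], 2.9, 5.0)
            coords[:, a, :] = D + dist[:, None] * u

    traj = Trajectory(
        topology=_conformer_topology(spec),
        coords=coords,
        frame_interval=spec.frame_interval,
        labels=labels,
    )
    ground_truth = {
        "well": wells,
        "triad_bonded": bonded,
        "flexible_atoms": np.asarray(spec.flexible_atoms, dtype=int),
        "correlated_pairs": list(spec.correlated_pairs),
    }
    return traj, ground_truth


def _hexagon(radius: float = 1.39) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3.0
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def gen_ring_pair(state: str, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two 6-atom rings: ``'stacked'`` (parallel, centroids 3.5 Å apart along
    the shared normal) or ``'unstacked'`` (centroids >= 8 Å apart, or normals
    tilted >= 60°, branch chosen by the seed).  Both rings are then moved by
    one seeded global rigid transform, which leaves the geometry class
    unchanged."""
    rng = np.random.default_rng(seed)
    ring1 = _hexagon()
    if state == "stacked":
        ring2 = _hexagon() + np.array([0.0, 0.0, 3.5])
    elif state == "unstacked":
        if rng.random() < 0.5:  # distance branch
            sep = 8.0 + 4.0 * rng.random()
            ring2 = _hexagon() + np.array([0.0, 0.0, sep])
        else:                   # angle branch
            tilt = np.deg2rad(60.0 + 30.0 * rng.random())
            ct, st = np.cos(tilt), np.sin(tilt)
            R = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]], dtype=float)
            ring2 = _hexagon() @ R.T + np.array([0.0, 0.0, 3.5])
    else:
        raise ValueError(f"state must be 'stacked' or 'unstacked', got {state!r}")
    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    return ring1 @ R.T + t, ring2 @ R.T + t


def gen_stacking_trajectory(
    state_probs: dict,
    n_frames: int = 500,
    seed: int = 0,
):
    """Trajectory of a probe ring and two candidate base rings with planted
    per-class stacking states.

    ``state_probs`` maps class name -> (p_stacked_damaged,
    p_stacked_complement, p_none).  Returns ``(Trajectory, states)`` where
    ``states`` is the planted per-frame state string.
    """
    rng = np.random.default_rng(seed)
    state_names = np.array(["stacked_damaged", "stacked_complement", "none"], dtype=object)
    hex0 = _hexagon()
    frames, states, labels = [], [], []
    for cname, probs in state_probs.items():
        probs = np.asarray(probs, dtype=np.float64)
        if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-9:
            raise SpecValidationError("state probabilities must be length 3 and sum to 1")
        draw = rng.choice(3, size=n_frames, p=probs)
        for s in draw:
            damaged = hex0 + np.array([15.0, 0.0, 0.0])
            complement = hex0 + np.array([-15.0, 0.0, 0.0])
            if s == 0:
                probe = hex0 + np.array([15.0, 0.0, 3.5])
            elif s == 1:
                probe = hex0 + np.array([-15.0, 0.0, 3.5])
            else:
                probe = hex0 + np.array([0.0, 15.0, 0.0])
            R = _random_rotation(rng)
            t = rng.uniform(-10.0, 10.0, size=3)
            frames.append(np.concatenate([probe, damaged, complement]) @ R.T + t)
            states.append(state_names[s])
            labels.append(cname)
    n_atoms = 18
    top = Topology(
        names=np.asarray([f"C{i}" for i in range(6)] * 3, dtype=object),
        elements=np.asarray(["C"] * n_atoms, dtype=object),
        resnames=np.asarray(["PHE"] * 6 + ["DC"] * 6 + ["DG"] * 6, dtype=object),
        resids=np.asarray([1] * 6 + [2] * 6 + [3] * 6, dtype=np.int64),
        segids=np.asarray(["MSH6"] * 6 + ["DNA"] * 12, dtype=object),
        moltype=np.asarray(["protein"] * 6 + ["nucleic"] * 12, dtype=object),
    )
    traj = Trajectory(
        topology=top,
        coords=np.stack(frames),
        frame_interval=100.0,
        labels=np.asarray(labels, dtype=object),
    )
    return traj, np.asarray(states, dtype=object)
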