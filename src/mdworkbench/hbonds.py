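"""Geometric hydrogen-bond detection and binary residue-pair featurization.

A hydrogen bond is detected between polar heavy atoms (N/O): the donor must
carry a covalently bonded hydrogen, the donor–acceptor heavy-atom distance
must not exceed ``distance_cutoff`` (default 3.2 Å) and the
donor–hydrogen–acceptor angle must be at least ``angle_cutoff`` (default
120°, an intermediate-strength bond).  Atom-level events are then collapsed
to one binary column per unordered residue pair — present/absent per frame —
which is the feature matrix the damage-classification tree consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory import EmptySelectionError, Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondEvent",
    "FeatureMatrix",
    "detect_hbonds",
    "select_pairs",
    "PairFilter",
    "binarize",
    "write_matrix",
    "read_matrix",
]

POLAR_ELEMENTS = ("N", "O")
COVALENT_H_CUTOFF = 1.2  # Å, used when the topology carries no bond list


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs: max donor–acceptor heavy-atom distance (Å) and
    minimum donor–hydrogen–acceptor angle (degrees; straight bonds are 180°,
    so the threshold is a floor, not a ceiling)."""

    distance_cutoff: float = 3.2
    angle_cutoff: float = 120.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass(frozen=True)
class HBondEvent:
    """One frame-level donor→acceptor contact passing both geometric tests."""

    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # D–A heavy-atom distance, Å
    angle: float     # D–H–A angle, degrees


@dataclass
class FeatureMatrix:
    """Binary frames × residue-pair matrix with class labels.

    ``descriptors`` are unordered residue-pair identifiers such as
    ``"MSH6:Thr781–ADP:Adp1"``; each column records presence/absence of any
    hydrogen bond between that pair in each frame.
    """

    matrix: np.ndarray               # (n_frames, n_features) uint8 in {0, 1}
    descriptors: list[str]
    labels: np.ndarray               # str per frame

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        if len(self.descriptors) != self.matrix.shape[1]:
            raise ValueError("descriptor count != column count")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise ValueError("duplicate feature descriptors")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("label count != frame count")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def class_names(self) -> list[str]:
        seen = dict.fromkeys(self.labels.tolist())
        return list(seen)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureMatrix)
            and np.array_equal(self.matrix, other.matrix)
            and self.descriptors == other.descriptors
            and np.array_equal(self.labels, other.labels)
        )


def _donor_hydrogens(top: Topology, frame0: np.ndarray) -> dict[int, list[int]]:
    """Map polar heavy atom -> covalently bonded hydrogens.

    Uses the topology bond list when present, else a < 1.2 Å distance rule
    on the supplied coordinates.
    """
    elements = np.char.upper(top.elements.astype(str))
    polar = np.flatnonzero(np.isin(elements, POLAR_ELEMENTS))
    hydro = np.flatnonzero(elements == "H")
    out: dict[int, list[int]] = {}
    if top.bonds is not None and len(top.bonds):
        hset, pset = set(hydro.tolist()), set(polar.tolist())
        for a, b in top.bonds:
            a, b = int(a), int(b)
            if a in pset and b in hset:
                out.setdefault(a, []).append(b)
            elif b in pset and a in hset:
                out.setdefault(b, []).append(a)
    elif hydro.size and polar.size:
        d = cdist(frame0[polar], frame0[hydro])
        for i, p in enumerate(polar):
            close = hydro[d[i] < COVALENT_H_CUTOFF]
            if close.size:
                out[int(p)] = [int(h) for h in close]
    return {p: sorted(hs) for p, hs in sorted(out.items())}


def detect_hbonds(traj: Trajectory, criteria: HBondCriteria = HBondCriteria()) -> list[HBondEvent]:
    """All (donor, hydrogen, acceptor) triples passing both geometric tests,
    per frame, in (frame, donor, hydrogen, acceptor) order."""
    top = traj.topology
    elements = np.char.upper(top.elements.astype(str))
    donors_h = _donor_hydrogens(top, traj.coords[0])
    donors = np.asarray(sorted(donors_h), dtype=np.intp)
    acceptors = np.flatnonzero(np.isin(elements, POLAR_ELEMENTS))
    if donors.size == 0 or acceptors.size == 0:
        raise EmptySelectionError("no polar donor/acceptor atoms in the selection")

    cos_min = np.cos(np.deg2rad(criteria.angle_cutoff))
    events: list[HBondEvent] = []
    for f in range(traj.n_frames):
        X = traj.coords[f]
        dda = cdist(X[donors], X[acceptors])
        close = np.argwhere(dda <= criteria.distance_cutoff)
        for di, ai in close:
            d, a = int(donors[di]), int(acceptors[ai])
            if d == a:
                continue
            for h in donors_h[d]:
                hd = X[d] - X[h]
                ha = X[a] - X[h]
                denom = np.linalg.norm(hd) * np.linalg.norm(ha)
                if denom == 0:
                    continue
                cos_ang = float(np.dot(hd, ha) / denom)
                # D-H-A angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
                if cos_ang <= cos_min + 1e-12:
                    ang = float(np.degrees(np.arccos(np.clip(cos_ang, -1.0, 1.0))))
                    events.append(
                        HBondEvent(
                            frame=f, donor=d, hydrogen=h, acceptor=a,
                            distance=float(dda[di, ai]), angle=ang,
                        )
                    )
    return events


@dataclass(frozen=True)
class PairFilter:
    """Residue-pair predicate for one of the analysis subsets.

    * ``protein_nucleic`` — protein ↔ nucleic-acid-or-cofactor pairs (the
      bound DNA strand and the ADP molecules).
    * ``inter_monomer`` — protein ↔ protein pairs spanning the two named
      segments (e.g. MSH2 ↔ MSH6).
    * ``protein_any`` — any pair with at least one protein member, excluding
      pure nucleic/cofactor contacts.
    """

    mode: str
    segments: tuple[str, str] | None = None

    def __call__(self, a: tuple[str, str], b: tuple[str, str]) -> bool:
        """a, b are (moltype, segid) for the two residues."""
        (ma, sa), (mb, sb) = a, b
        if self.mode == "protein_nucleic":
            nucleic = ("nucleic", "cofactor")
            return (ma == "protein" and mb in nucleic) or (mb == "protein" and ma in nucleic)
        if self.mode == "inter_monomer":
            if ma != "protein" or mb != "protein":
                return False
            return {sa, sb} == set(self.segments)
        if self.mode == "protein_any":
            return ma == "protein" or mb == "protein"
        raise ValueError(f"unknown pair filter mode {self.mode!r}")


def select_pairs(
    topology: Topology, mode: str, segments: tuple[str, str] | None = None
) -> PairFilter:
    """Build the residue-pair filter for ``mode``; ``inter_monomer`` needs the
    two protein segment names, which must exist in the topology."""
    if mode == "inter_monomer":
        if segments is None:
            prot = np.unique(topology.segids[topology.moltype == "protein"])
            if len(prot) != 2:
                raise ValueError(
                    f"inter_monomer needs exactly 2 protein segments; found {list(prot)}"
                )
            segments = (str(prot[0]), str(prot[1]))
        known = set(np.unique(topology.segids).tolist())
        missing = set(segments) - known
        if missing:
            raise ValueError(f"unknown segment name(s): {sorted(missing)}")
    elif mode not in ("protein_nucleic", "protein_any"):
        raise ValueError(f"unknown pair filter mode {mode!r}")
    return PairFilter(mode=mode, segments=segments)


def binarize(
    events: list[HBondEvent],
    traj: Trajectory,
    pair_filter: PairFilter | None = None,
) -> FeatureMatrix:
    """Collapse atom-level events to the binary residue-pair matrix.

    One column per unordered residue pair that passes the filter and occurs
    at least once; entry (frame, pair) is 1 iff any atom-level event between
    the pair exists in that frame.  Donor/acceptor direction is ignored.
    """
    top = traj.topology
    res_desc = top.residue_descriptors()
    moltype = top.moltype
    segids = top.segids
    n_frames = traj.n_frames

    cols: dict[tuple[str, str], set[int]] = {}
    for ev in events:
        if ev.frame >= n_frames:
            raise ValueError(f"event frame {ev.frame} >= n_frames {n_frames}")
        da, aa = ev.donor, ev.acceptor
        ra, rb = str(res_desc[da]), str(res_desc[aa])
        if ra == rb:
            continue  # intra-residue contact, not a residue-pair feature
        if pair_filter is not None and not pair_filter(
            (str(moltype[da]), str(segids[da])), (str(moltype[aa]), str(segids[aa]))
        ):
            continue
        key = tuple(sorted((ra, rb)))
        cols.setdefault(key, set()).add(ev.frame)
    descriptors = [f"{a}–{b}" for a, b in sorted(cols)]
    matrix = np.zeros((n_frames, len(descriptors)), dtype=np.uint8)
    for j, key in enumerate(sorted(cols)):
        matrix[list(cols[key]), j] = 1
    return FeatureMatrix(matrix=matrix, descriptors=descriptors, labels=traj.labels.copy())


def write_matrix(fm: FeatureMatrix, path) -> None:
    """CSV dialect: frame index, class label, then one 0/1 column per pair."""
    df = pd.DataFrame(fm.matrix, columns=fm.descriptors)
    df.insert(0, "label", fm.labels)
    df.insert(0, "frame", np.arange(fm.n_frames))
    df.to_csv(path, index=False)


def read_matrix(path) -> FeatureMatrix:
    """Lossless inverse of :func:`write_matrix`; rejects non-binary cells."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed feature CSV {path!s}: {exc}") from exc
    if list(df.columns[:2]) != ["frame", "label"]:
        raise ValueError(f"{path!s}: first two columns must be 'frame', 'label'")
    values = df.iloc[:, 2:].to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path!s}: non-binary value {values[r, c]!r} at line {r + 2}, "
            f"column {df.columns[c + 2]!r}"
        )
    return FeatureMatrix(
        matrix=values.astype(np.uint8),
        descriptors=[str(c) for c in df.columns[2:]],
        labels=df["label"].to_numpy(dtype=object),
    )
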