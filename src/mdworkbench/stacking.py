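"""Aromatic-stacking state classification.

Face-to-face (π) stacking of a probe ring — a phenylalanine side chain of
the kind that wedges into damaged DNA during mismatch recognition — against
two candidate nucleic bases (the damaged base and its complement) is scored
geometrically per frame: ring centroid separation, the angle between
least-squares ring-plane normals, and the lateral offset of the candidate
centroid from the probe's normal axis must all pass their thresholds.  When
both candidates qualify the closer one wins.  Per-system state fractions
(stacked-with-damaged / stacked-with-complement / none) summarise each
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "StackingCriteria",
    "ring_geometry",
    "classify_stacking",
    "stacking_states",
    "stacking_fractions",
    "STATES",
]

STATES = ("stacked_damaged", "stacked_complement", "none")


@dataclass(frozen=True)
class StackingCriteria:
    """Geometric thresholds: max centroid separation (Å), max angle between
    ring normals (degrees), max lateral centroid offset (Å)."""

    max_separation: float = 5.0
    max_normal_angle: float = 30.0
    max_offset: float = 2.0

    def __post_init__(self) -> None:
        if min(self.max_separation, self.max_normal_angle, self.max_offset) <= 0:
            raise ValueError("all stacking thresholds must be > 0")


def ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring via its least-squares plane.

    The normal is the singular direction of least coordinate variance;
    raises on degenerate (collinear or < 3 atoms) rings.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("ring needs >= 3 atoms")
    centroid = coords.mean(axis=0)
    _, s, Vt = np.linalg.svd(coords - centroid)
    if s[1] < 1e-8:
        raise ValueError("degenerate (collinear) ring geometry")
    return centroid, Vt[2]


def _passes(probe_c, probe_n, cand_coords, criteria) -> tuple[bool, float]:
    cand_c, cand_n = ring_geometry(cand_coords)
    sep_vec = cand_c - probe_c
    sep = float(np.linalg.norm(sep_vec))
    cosang = abs(float(np.dot(probe_n, cand_n)))      # normals are axial: fold to [0, 90°]
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    offset = float(np.linalg.norm(sep_vec - np.dot(sep_vec, probe_n) * probe_n))
    ok = (
        sep <= criteria.max_separation
        and angle <= criteria.max_normal_angle
        and offset <= criteria.max_offset
    )
    return ok, sep


def classify_stacking(
    frame_coords: np.ndarray,
    probe_ring: np.ndarray,
    damaged_ring: np.ndarray,
    complement_ring: np.ndarray,
    criteria: StackingCriteria = StackingCriteria(),
) -> str:
    """State of one frame: which candidate (if any) the probe ring stacks on.

    Ring arguments are atom-index arrays into ``frame_coords``.  If both
    candidates pass all thresholds the smaller centroid separation decides.
    """
    X = np.asarray(frame_coords, dtype=np.float64)
    probe_c, probe_n = ring_geometry(X[np.asarray(probe_ring, dtype=np.intp)])
    ok_d, sep_d = _passes(probe_c, probe_n, X[np.asarray(damaged_ring, dtype=np.intp)], criteria)
    ok_c, sep_c = _passes(probe_c, probe_n, X[np.asarray(complement_ring, dtype=np.intp)], criteria)
    if ok_d and ok_c:
        return "stacked_damaged" if sep_d <= sep_c else "stacked_complement"
    if ok_d:
        return "stacked_damaged"
    if ok_c:
        return "stacked_complement"
    return "none"


def stacking_states(
    traj: Trajectory,
    probe_ring: np.ndarray,
    damaged_ring: np.ndarray,
    complement_ring: np.ndarray,
    criteria: StackingCriteria = StackingCriteria(),
) -> np.ndarray:
    """Per-frame stacking state series for one trajectory."""
    return np.asarray(
        [
            classify_stacking(traj.coords[f], probe_ring, damaged_ring, complement_ring, criteria)
            for f in range(traj.n_frames)
        ],
        dtype=object,
    )


def stacking_fractions(
    traj: Trajectory,
    probe_ring: np.ndarray,
    damaged_ring: np.ndarray,
    complement_ring: np.ndarray,
    criteria: StackingCriteria = StackingCriteria(),
) -> pd.DataFrame:
    """Per-system fraction of frames in each stacking state (rows sum to 1).

    Systems are the trajectory's per-frame labels, so a concatenated
    multi-damage trajectory reports one row per damage class.
    """
    states = stacking_states(traj, probe_ring, damaged_ring, complement_ring, criteria)
    rows = {}
    for sys_name in dict.fromkeys(traj.labels.tolist()):
        mask = traj.labels == sys_name
        n = int(mask.sum())
        rows[sys_name] = [float((states[mask] == s).sum()) / n for s in STATES]
    return pd.DataFrame(rows, index=list(STATES)).T


def find_ring_atoms(traj: Trajectory, segid: str, resid: int,
                    names: tuple[str, ...] | None = None) -> np.ndarray:
    """Heavy-atom indices of one residue's ring (all heavy atoms by default,
    or an explicit atom-name tuple such as Phe's CG/CD1/CD2/CE1/CE2/CZ)."""
    top = traj.topology
    mask = (top.segids == segid) & (top.resids == resid) & top.heavy
    if names is not None:
        mask &= np.isin(np.char.upper(top.names.astype(str)), [n.upper() for n in names])
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError(f"cannot resolve ring atoms for {segid}:{resid}")
    return idx
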