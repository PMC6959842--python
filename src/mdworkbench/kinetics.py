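"""Ensemble kinetics: RMSF, correlated motions, PCA and ΔG landscapes.

All operations assume the trajectory has already been superposed onto a
single reference (see :mod:`mdworkbench.trajectory`), so displacements
reflect internal motion rather than rigid-body drift.

* RMSF_i = sqrt((1/N) Σ_j |r_i(t_j) − r̄_i|²), r̄ the time-average position.
* DCCM C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) — the Pearson-normalised
  covariance of atomic displacement vectors.
* PCA diagonalises the 3N×3N coordinate covariance of a (typically
  alpha-carbon) subset; projecting per-system trajectories onto one basis
  built from the concatenated trajectory puts all systems in a common
  reduced space.
* The free-energy landscape is the Boltzmann inversion of a 2-D histogram
  over (PC1, PC2): ΔG = −kT ln(P/P₀) with P₀ the most-populated bin, so the
  dominant bin sits at exactly 0 and unvisited bins are masked (unbounded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "BOLTZMANN_KCAL",
    "RMSFProfile",
    "CorrelationMatrix",
    "PCABasis",
    "FreeEnergyLandscape",
    "rmsf",
    "dccm",
    "pca",
    "project",
    "project_fes",
    "mark_reference",
]

BOLTZMANN_KCAL = 0.0019872  # kcal / (mol K)


def _subset_coords(traj: Trajectory, subset) -> np.ndarray:
    if subset is None:
        idx = traj.ca_indices()
        if idx.size == 0:
            idx = np.arange(traj.n_atoms)
    else:
        idx = np.asarray(subset, dtype=np.intp)
    return traj.coords[:, idx, :]


@dataclass
class RMSFProfile:
    values: np.ndarray        # (n_atoms_subset,) Å, >= 0
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("RMSF cannot be negative")


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray        # (m, m), symmetric, unit diagonal, in [−1, 1]
    atom_indices: np.ndarray


@dataclass
class PCABasis:
    """Orthonormal principal axes of the coordinate covariance.

    ``components`` columns are unit 3N-vectors sorted by decreasing
    eigenvalue; ``total_variance`` is the trace of the covariance so the
    explained-variance fractions are eigenvalue / total even when only the
    leading components are kept.
    """

    mean: np.ndarray                 # (3N,)
    components: np.ndarray           # (3N, m), orthonormal columns
    eigenvalues: np.ndarray          # (m,), descending, >= 0
    total_variance: float
    atom_indices: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    def __post_init__(self) -> None:
        G = self.components.T @ self.components
        if not np.allclose(G, np.eye(G.shape[0]), atol=1e-8):
            raise ValueError("principal axes are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")


@dataclass
class FreeEnergyLandscape:
    """ΔG grid (kcal/mol) over binned (PC1, PC2) projections.

    ``dG`` is a masked array: masked cells are unvisited bins (unbounded
    free energy); the most-populated bin is exactly 0.
    """

    dG: np.ma.MaskedArray            # (bins, bins)
    xedges: np.ndarray
    yedges: np.ndarray
    temperature: float               # K
    boltzmann_k: float               # kcal/(mol K)
    reference_population: int        # P0, frames in the fullest bin

    def __post_init__(self) -> None:
        finite = self.dG.compressed()
        if finite.size and (finite.min() < -1e-12 or abs(finite.min()) > 1e-12):
            raise ValueError("minimum finite ΔG must be exactly 0")


def rmsf(traj: Trajectory, subset=None) -> RMSFProfile:
    """Per-atom root mean square fluctuation about the time-average position."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs >= 2 frames")
    idx = traj.ca_indices() if subset is None else np.asarray(subset, dtype=np.intp)
    if subset is None and idx.size == 0:
        idx = np.arange(traj.n_atoms)
    X = traj.coords[:, idx, :]
    disp = X - X.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=0))
    return RMSFProfile(values=values, atom_indices=idx)


def dccm(traj: Trajectory, subset=None, zero_variance: str = "raise") -> CorrelationMatrix:
    """Pearson correlated-motion matrix of atomic displacement vectors.

    ``zero_variance``: 'raise' rejects static atoms; 'nan' flags their
    rows/columns with NaN instead.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs >= 2 frames")
    idx = traj.ca_indices() if subset is None else np.asarray(subset, dtype=np.intp)
    if subset is None and idx.size == 0:
        idx = np.arange(traj.n_atoms)
    X = traj.coords[:, idx, :]
    disp = X - X.mean(axis=0, keepdims=True)          # (N, m, 3)
    cov = np.einsum("nia,nja->ij", disp, disp) / traj.n_frames
    var = np.diag(cov).copy()
    static = var <= 0
    if static.any():
        if zero_variance == "raise":
            raise ValueError(f"zero-variance atoms at subset positions {np.flatnonzero(static)}")
        var[static] = np.nan
    denom = np.sqrt(np.outer(var, var))
    C = cov / denom
    np.fill_diagonal(C, np.where(static, np.nan, 1.0))
    C = np.clip(C, -1.0, 1.0, out=C)
    return CorrelationMatrix(matrix=C, atom_indices=idx)


def pca(traj: Trajectory, subset=None, n_components: int | None = None) -> PCABasis:
    """Principal axes of the 3N coordinate covariance (1/(N−1) normalised).

    The trajectory must be superposed to one global reference; for
    cross-system comparison fit the basis on the concatenated trajectory and
    project each system with :func:`project`.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs >= 2 frames")
    idx = traj.ca_indices() if subset is None else np.asarray(subset, dtype=np.intp)
    if subset is None and idx.size == 0:
        idx = np.arange(traj.n_atoms)
    X = traj.coords[:, idx, :].reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (traj.n_frames - 1)
    total = float(eig.sum())  # == trace of the covariance
    if n_components is not None:
        eig = eig[:n_components]
        Vt = Vt[:n_components]
    return PCABasis(
        mean=mean,
        components=Vt.T,
        eigenvalues=eig,
        total_variance=total,
        atom_indices=idx,
    )


def project(traj: Trajectory, basis: PCABasis, n_components: int = 2) -> np.ndarray:
    """(n_frames, n_components) projection of the basis subset's coordinates."""
    X = traj.coords[:, basis.atom_indices, :].reshape(traj.n_frames, -1)
    if X.shape[1] != basis.mean.shape[0]:
        raise ValueError("trajectory does not carry the basis atom subset")
    return (X - basis.mean) @ basis.components[:, :n_components]


def project_fes(
    traj: Trajectory,
    basis: PCABasis,
    bins: int = 100,
    temperature: float = 300.0,
    extent: tuple | None = None,
) -> FreeEnergyLandscape:
    """Boltzmann-inverted 2-D histogram of the (PC1, PC2) projections.

    ΔG(bin) = −kT ln(P/P₀), k = 0.0019872 kcal/(mol·K); the most-populated
    bin is exactly 0 and empty bins are masked. ``extent`` optionally fixes
    ((xmin, xmax), (ymin, ymax)) so several systems share one grid.
    """
    if basis.components.shape[1] < 2:
        raise ValueError("need >= 2 principal components for a 2-D landscape")
    if bins < 2:
        raise ValueError("need >= 2 bins per axis")
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    proj = project(traj, basis, n_components=2)
    H, xedges, yedges = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins, range=extent)
    P0 = H.max()
    if P0 == 0:
        raise ValueError("no frames fall inside the landscape extent")
    kT = BOLTZMANN_KCAL * temperature
    with np.errstate(divide="ignore"):
        dG = -kT * np.log(H / P0)
    dG = np.ma.masked_array(dG, mask=(H == 0))
    return FreeEnergyLandscape(
        dG=dG,
        xedges=xedges,
        yedges=yedges,
        temperature=temperature,
        boltzmann_k=BOLTZMANN_KCAL,
        reference_population=int(P0),
    )


def mark_reference(basis: PCABasis, reference_coords: np.ndarray) -> tuple[float, float]:
    """(PC1, PC2) coordinates of a single reference structure (e.g. the
    crystal structure) in the landscape's space.  ``reference_coords`` is
    (n_atoms, 3) over the full atom set the basis subset indexes, or already
    restricted to the subset."""
    ref = np.asarray(reference_coords, dtype=np.float64)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference must be (n_atoms, 3)")
    if ref.shape[0] * 3 == basis.mean.shape[0]:
        flat = ref.reshape(-1)
    else:
        try:
            flat = ref[basis.atom_indices].reshape(-1)
        except IndexError as exc:
            raise ValueError("reference does not contain the basis atom subset") from exc
        if flat.shape[0] != basis.mean.shape[0]:
            raise ValueError("reference/basis atom mismatch")
    pc = (flat - basis.mean) @ basis.components[:, :2]
    return float(pc[0]), float(pc[1])
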