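"""RMSF, correlated motions, PCA basis and free-energy landscapes."""

import numpy as np
import pytest

from mdworkbench import kinetics
from mdworkbench.kinetics import BOLTZMANN_KCAL
from mdworkbench.synthetic import ConformerPlantSpec, gen_trajectory
from mdworkbench.trajectory import concatenate, superpose

from conftest import make_trajectory


class TestRMSF:
    def test_static_atom_is_zero(self):
        coords = np.tile(np.arange(9.0).reshape(3, 3), (4, 1, 1))
        prof = kinetics.rmsf(make_trajectory(coords), subset=np.arange(3))
        np.testing.assert_allclose(prof.values, 0.0)

    def test_two_point_alternation_is_one_angstrom(self):
        a, b = np.zeros((1, 3)), np.array([[2.0, 0.0, 0.0]])
        coords = np.stack([a, b, a, b])
        prof = kinetics.rmsf(make_trajectory(coords), subset=[0])
        assert prof.values[0] == pytest.approx(1.0, abs=0)

    def test_isotropic_gaussian_gives_sigma_root_three(self, rng):
        sigma = 0.7
        coords = sigma * rng.standard_normal((1000, 5, 3))
        prof = kinetics.rmsf(make_trajectory(coords), subset=np.arange(5))
        np.testing.assert_allclose(prof.values, sigma * np.sqrt(3.0), rtol=0.05)

    def test_planted_flexible_region_stands_out(self):
        spec = ConformerPlantSpec.default(
            n_atoms=30, n_wells=1, n_frames=2000, seed=21,
            flexible_atoms=[5, 6, 7], flex_scale=2.5,
        )
        traj, _ = gen_trajectory(spec)
        traj = superpose(traj, fit_selection=np.arange(traj.n_atoms))
        prof = kinetics.rmsf(traj, subset=np.arange(30))
        flexible = prof.values[[5, 6, 7]]
        rigid = np.delete(prof.values, [5, 6, 7])
        assert flexible.min() > rigid.max()

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            kinetics.rmsf(make_trajectory(np.zeros((1, 2, 3))), subset=[0])


class TestDCCM:
    def test_rigid_offset_pair_is_plus_one(self, rng):
        base = rng.standard_normal((100, 1, 3))
        coords = np.concatenate([base, base + 5.0], axis=1)
        C = kinetics.dccm(make_trajectory(coords), subset=[0, 1])
        assert C.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair_is_minus_one(self, rng):
        base = rng.standard_normal((100, 1, 3))
        coords = np.concatenate([base, -base], axis=1)
        C = kinetics.dccm(make_trajectory(coords), subset=[0, 1])
        assert C.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_atoms_near_zero(self, rng):
        coords = rng.standard_normal((5000, 4, 3))
        C = kinetics.dccm(make_trajectory(coords), subset=np.arange(4))
        off = C.matrix[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)  # sampling-error bound ~ 1/sqrt(N)

    def test_matrix_contract(self, rng):
        coords = rng.standard_normal((200, 6, 3))
        C = kinetics.dccm(make_trajectory(coords), subset=np.arange(6))
        np.testing.assert_allclose(C.matrix, C.matrix.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C.matrix), 1.0)
        assert np.all(C.matrix >= -1.0) and np.all(C.matrix <= 1.0)

    def test_planted_couplings_recovered(self):
        spec = ConformerPlantSpec.default(
            n_atoms=20, n_wells=1, n_frames=2000, seed=33,
            correlated_pairs=[(3, 4, 1.0), (8, 9, -1.0)],
        )
        traj, _ = gen_trajectory(spec)
        C = kinetics.dccm(traj, subset=np.arange(20))
        assert abs(C.matrix[3, 4] - 1.0) < 0.05
        assert abs(C.matrix[8, 9] + 1.0) < 0.05

    def test_zero_variance_atom_flagged_or_raises(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = np.arange(10.0)
        traj = make_trajectory(coords)
        with pytest.raises(ValueError):
            kinetics.dccm(traj, subset=[0, 1])
        C = kinetics.dccm(traj, subset=[0, 1], zero_variance="nan")
        assert np.isnan(C.matrix[0, 0])


class TestPCA:
    def test_rank_one_data_explained_by_pc1(self, rng):
        direction = rng.standard_normal(12)
        t = rng.standard_normal(50)
        X = np.outer(t, direction).reshape(50, 4, 3)
        basis = kinetics.pca(make_trajectory(X), subset=np.arange(4))
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalue_sum_equals_trace(self, rng):
        coords = rng.standard_normal((40, 5, 3))
        basis = kinetics.pca(make_trajectory(coords), subset=np.arange(5))
        X = coords.reshape(40, -1)
        trace = np.cov(X.T).trace()
        assert abs(basis.eigenvalues.sum() - trace) < 1e-8
        assert abs(basis.total_variance - trace) < 1e-8

    def test_full_basis_reconstruction(self, rng):
        coords = rng.standard_normal((30, 4, 3))
        traj = make_trajectory(coords)
        basis = kinetics.pca(traj, subset=np.arange(4))
        X = coords.reshape(30, -1)
        Z = (X - basis.mean) @ basis.components
        back = Z @ basis.components.T + basis.mean
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_orthonormal_columns(self, rng):
        coords = rng.standard_normal((25, 3, 3))
        basis = kinetics.pca(make_trajectory(coords), subset=np.arange(3))
        G = basis.components.T @ basis.components
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)


class TestFES:
    def _landscape(self, rng, bins=10, T=300.0):
        coords = rng.standard_normal((500, 3, 3))
        traj = make_trajectory(coords)
        basis = kinetics.pca(traj, subset=np.arange(3))
        return traj, basis, kinetics.project_fes(traj, basis, bins=bins, temperature=T)

    def test_most_populated_bin_is_exactly_zero(self, rng):
        _, _, fes = self._landscape(rng)
        assert fes.dG.min() == 0.0

    def test_half_population_bin_value(self):
        """A bin with half the reference population sits at kT ln 2 =
        0.4132 kcal/mol at 300 K."""
        kT = BOLTZMANN_KCAL * 300.0
        assert kT * np.log(2.0) == pytest.approx(0.4132, abs=1e-3)
        # engineered histogram: 2 frames in one bin, 1 in another
        coords = np.zeros((3, 3, 3))
        coords[2, 0, 0] = 5.0  # move frame 2 along one coordinate
        traj = make_trajectory(coords)
        basis = kinetics.pca(traj, subset=np.arange(3))
        fes = kinetics.project_fes(traj, basis, bins=2, temperature=300.0)
        vals = np.sort(fes.dG.compressed())
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(kT * np.log(2.0), abs=1e-9)

    def test_unvisited_bins_masked(self, rng):
        _, _, fes = self._landscape(rng, bins=40)
        assert fes.dG.mask.sum() > 0
        assert np.all(fes.dG.compressed() >= 0.0)

    def test_invariant_under_frame_duplication(self, rng):
        coords = rng.standard_normal((200, 3, 3))
        traj = make_trajectory(coords)
        basis = kinetics.pca(traj, subset=np.arange(3))
        doubled = make_trajectory(np.concatenate([coords, coords]))
        extent = ((-10.0, 10.0), (-10.0, 10.0))
        f1 = kinetics.project_fes(traj, basis, bins=15, extent=extent)
        f2 = kinetics.project_fes(doubled, basis, bins=15, extent=extent)
        np.testing.assert_allclose(f1.dG.filled(np.inf), f2.dG.filled(np.inf), atol=1e-12)

    def test_common_basis_separates_planted_wells(self):
        """Per-system projections onto one concatenated-trajectory basis
        occupy disjoint histogram supports when the wells are class-separated."""
        spec = ConformerPlantSpec.default(n_frames=150, seed=44, spread=0.3)
        # make class->well deterministic so systems are fully separated
        for name, row in spec.class_occupancy.items():
            row[:] = 0.0
            row[list(spec.class_occupancy).index(name)] = 1.0
        traj, _ = gen_trajectory(spec)
        traj = superpose(traj, fit_selection=np.arange(traj.n_atoms))
        basis = kinetics.pca(traj, subset=np.arange(traj.n_atoms))
        proj = kinetics.project(traj, basis)
        extent = (
            (proj[:, 0].min(), proj[:, 0].max()),
            (proj[:, 1].min(), proj[:, 1].max()),
        )
        supports = []
        for name in spec.class_names:
            sub = make_trajectory(traj.coords[traj.labels == name], top=traj.topology)
            fes = kinetics.project_fes(sub, basis, bins=20, extent=extent)
            supports.append(~fes.dG.mask)
        assert not (supports[0] & supports[1]).any()
        assert not (supports[0] & supports[2]).any()
        assert not (supports[1] & supports[2]).any()


class TestMarkReference:
    def test_mean_structure_projects_to_origin(self, rng):
        coords = rng.standard_normal((50, 4, 3))
        traj = make_trajectory(coords)
        basis = kinetics.pca(traj, subset=np.arange(4))
        mean_structure = coords.mean(axis=0)
        pc1, pc2 = kinetics.mark_reference(basis, mean_structure)
        assert abs(pc1) < 1e-10 and abs(pc2) < 1e-10

    def test_frame_matches_its_stored_projection(self, rng):
        coords = rng.standard_normal((50, 4, 3))
        traj = make_trajectory(coords)
        basis = kinetics.pca(traj, subset=np.arange(4))
        proj = kinetics.project(traj, basis)
        pc = kinetics.mark_reference(basis, coords[7])
        np.testing.assert_allclose(pc, proj[7], atol=1e-10)

    def test_shift_along_eigenvector_is_linear(self, rng):
        coords = rng.standard_normal((50, 4, 3))
        traj = make_trajectory(coords)
        basis = kinetics.pca(traj, subset=np.arange(4))
        delta = 2.5
        shifted = (coords[0].reshape(-1) + delta * basis.components[:, 0]).reshape(4, 3)
        pc_before = kinetics.mark_reference(basis, coords[0])
        pc_after = kinetics.mark_reference(basis, shifted)
        assert pc_after[0] - pc_before[0] == pytest.approx(delta, abs=1e-10)
        assert pc_after[1] - pc_before[1] == pytest.approx(0.0, abs=1e-10)

    def test_atom_mismatch_rejected(self, rng):
        coords = rng.standard_normal((10, 4, 3))
        basis = kinetics.pca(make_trajectory(coords), subset=np.arange(4))
        with pytest.raises(ValueError):
            kinetics.mark_reference(basis, rng.standard_normal((2, 3)))
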