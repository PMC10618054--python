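"""Gyration geometry, alignment, fluctuation matrices and landscapes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from chromocycle.metrics import (
    AlignedEnsemble, FluctuationMatrix, align_ensemble, delta_M,
    fluctuation_matrix, free_energy_landscape, geometry, gyration_tensor, msd,
)


OCTAHEDRON = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0],
                       [0, -1.0, 0], [0, 0, 1.0], [0, 0, -1.0]])


class TestGyrationTensor:
    def test_coincident_beads_give_zero_tensor(self):
        assert np.allclose(gyration_tensor(np.ones((5, 3))), 0.0)

    def test_two_point_case(self):
        T = gyration_tensor(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        assert np.allclose(T, np.diag([1.0, 0.0, 0.0]))

    def test_matches_covariance_oracle(self, rng):
        x = rng.standard_normal((20, 3)) * 2
        T = gyration_tensor(x)
        d = x - x.mean(axis=0)
        ref = np.array([[np.mean(d[:, a] * d[:, b]) for b in range(3)]
                        for a in range(3)])
        assert np.allclose(T, ref)
        assert np.allclose(np.sort(np.linalg.eigvalsh(T)),
                           np.sort(np.linalg.eigvalsh(ref)))


class TestGeometry:
    def test_isotropic_configuration_is_a_perfect_sphere(self):
        rec = geometry(OCTAHEDRON)
        assert rec.Delta == pytest.approx(0.0, abs=1e-14)

    def test_collinear_chain_is_a_rod(self):
        x = np.zeros((10, 3))
        x[:, 0] = np.arange(10.0)
        rec = geometry(x)
        assert rec.Delta == pytest.approx(1.0, abs=1e-12)

    def test_two_beads_half_separation(self):
        d = 3.2
        x = np.array([[0.0, 0, 0], [d, 0, 0]])
        assert geometry(x).Rg == pytest.approx(d / 2)

    def test_degenerate_configuration(self):
        rec = geometry(np.zeros((4, 3)))
        assert rec.Rg == 0.0 and np.isnan(rec.Delta)

    @given(st.integers(0, 2**32 - 1))
    def test_identities_and_bounds(self, seed):
        x = np.random.default_rng(seed).standard_normal((12, 3)) * 1.5
        rec = geometry(x)
        assert rec.Rg**2 == pytest.approx(sum(rec.eigenvalues), rel=1e-10)
        assert rec.Rg**2 == pytest.approx(np.trace(gyration_tensor(x)), rel=1e-10)
        assert 0.0 <= rec.Delta <= 1.0


class TestFreeEnergyLandscape:
    def test_unequal_occupancy_closed_form(self):
        from chromocycle.metrics import GeometryRecord
        recs = ([GeometryRecord(1.0, 0.2, (1, 0, 0))] * 3
                + [GeometryRecord(3.0, 0.8, (1, 0, 0))])
        land = free_energy_landscape(recs, bins=2)
        vals = np.sort(land.values[land.defined])
        assert vals[0] == pytest.approx(0.0)
        assert vals[1] == pytest.approx(np.log(3.0))

    def test_matches_histogram_oracle(self, rng):
        from chromocycle.metrics import GeometryRecord
        rg = rng.uniform(1, 3, 200)
        dl = rng.uniform(0, 1, 200)
        recs = [GeometryRecord(r, d, (1, 0, 0)) for r, d in zip(rg, dl)]
        land = free_energy_landscape(recs, bins=5)
        counts, _, _ = np.histogram2d(rg, dl, bins=5)
        p = counts / counts.sum()
        ref = np.full_like(p, np.nan)
        ref[p > 0] = -np.log(p[p > 0])
        ref[p > 0] -= np.nanmin(ref[p > 0])
        assert np.allclose(land.values[land.defined], ref[p > 0])


class TestAlignment:
    def _rigid_copies(self, rng, m=6, n=15):
        base = rng.standard_normal((n, 3)) * 2
        out = []
        for k in range(m):
            R = Rotation.random(random_state=k).as_matrix()
            out.append(base @ R.T + rng.standard_normal(3) * 5)
        return base, np.array(out)

    def test_rigid_copies_collapse_onto_one_structure(self, rng):
        base, ens = self._rigid_copies(rng)
        aligned = align_ensemble(ens)
        for s in aligned.structures:
            assert np.allclose(s, aligned.structures[0], atol=1e-6)
        # and the mean is that structure (up to a global rotation of the frame)
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(gyration_tensor(aligned.mean))),
            np.sort(np.linalg.eigvalsh(gyration_tensor(base))), atol=1e-8)

    def test_idempotent(self, rng):
        ens = rng.standard_normal((5, 10, 3)) * 1.5
        a1 = align_ensemble(ens)
        a2 = align_ensemble(a1.structures)
        assert np.allclose(a1.structures, a2.structures, atol=1e-6)

    def test_alignment_beats_random_rotations(self, rng):
        ens = rng.standard_normal((6, 12, 3))
        aligned = align_ensemble(ens)
        best = np.sum((aligned.structures - aligned.mean) ** 2)
        for k in range(5):
            R = Rotation.random(random_state=100 + k).as_matrix()
            perturbed = aligned.structures.copy()
            perturbed[2] = perturbed[2] @ R.T
            worse = np.sum((perturbed - perturbed.mean(axis=0)) ** 2)
            assert best <= worse + 1e-9


class TestFluctuationMatrix:
    def test_identical_structures_give_zero(self, rng):
        x = rng.standard_normal((8, 3))
        aligned = align_ensemble(np.array([x, x, x]))
        M = fluctuation_matrix(aligned)
        assert np.allclose(M.M, 0.0, atol=1e-10)

    def test_two_member_closed_form(self, rng):
        # structures mean ± u: M_ij = u_i . u_j exactly
        n = 6
        mean = rng.standard_normal((n, 3))
        u = rng.standard_normal((n, 3)) * 0.1
        aligned = AlignedEnsemble(np.array([mean + u, mean - u]), mean, 1)
        M = fluctuation_matrix(aligned).M
        assert np.allclose(M, u @ u.T, atol=1e-12)

    def test_diagonal_is_per_locus_variance(self, rng):
        ens = rng.standard_normal((10, 7, 3))
        aligned = align_ensemble(ens)
        M = fluctuation_matrix(aligned).M
        d = aligned.structures - aligned.structures.mean(axis=0)
        for i in range(7):
            assert M[i, i] == pytest.approx(np.mean(np.sum(d[:, i, :] ** 2, axis=1)))

    def test_refuses_unaligned_input(self, rng):
        with pytest.raises(TypeError, match="align"):
            fluctuation_matrix(rng.standard_normal((4, 6, 3)))

    def test_invariant_under_global_rigid_motion(self, rng):
        ens = rng.standard_normal((8, 10, 3))
        M1 = fluctuation_matrix(align_ensemble(ens)).M
        R = Rotation.random(random_state=1).as_matrix()
        moved = ens @ R.T + np.array([4.0, -2.0, 1.0])
        M2 = fluctuation_matrix(align_ensemble(moved)).M
        assert np.allclose(M1, M2, atol=1e-6)


class TestDeltaM:
    def test_antisymmetric_and_elementwise(self, rng):
        A = rng.standard_normal((5, 5))
        B = rng.standard_normal((5, 5))
        A, B = A @ A.T, B @ B.T  # symmetric PSD
        MA = FluctuationMatrix(A, 4)
        MB = FluctuationMatrix(B, 4)
        assert np.allclose(delta_M(MA, MB), A - B)
        assert np.allclose(delta_M(MA, MB), -delta_M(MB, MA))
        assert np.allclose(delta_M(MA, MA), 0.0)


class TestMSD:
    class _Traj:
        def __init__(self, frames, times):
            self.frames = np.asarray(frames, dtype=float)
            self.frame_times = np.asarray(times, dtype=float)

    def test_static_trajectory_is_zero(self, rng):
        x = rng.standard_normal((6, 3))
        traj = self._Traj([x] * 10, np.arange(10.0))
        assert np.allclose(msd(traj, 3.0), 0.0)

    def test_rigid_translation_removed_by_com_correction(self, rng):
        x = rng.standard_normal((6, 3))
        frames = [x + t * np.array([1.0, 0, 0]) for t in range(10)]
        traj = self._Traj(frames, np.arange(10.0))
        assert np.allclose(msd(traj, 2.0), 0.0, atol=1e-12)

    def test_brownian_frames_are_linear_in_lag(self, rng):
        n, F, D, dt = 50, 400, 0.25, 1.0
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), (F, n, 3))
        frames = np.cumsum(steps, axis=0)
        traj = self._Traj(frames, np.arange(F, dtype=float))
        m1 = msd(traj, 2.0).mean() / (1 - 1 / n)
        m2 = msd(traj, 8.0).mean() / (1 - 1 / n)
        assert m1 == pytest.approx(6 * D * 2.0, rel=0.1)
        assert m2 == pytest.approx(6 * D * 8.0, rel=0.15)

    def test_lag_beyond_span_rejected(self, rng):
        traj = self._Traj(rng.standard_normal((4, 3, 3)), np.arange(4.0))
        with pytest.raises(ValueError, match="lag"):
            msd(traj, 10.0)
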