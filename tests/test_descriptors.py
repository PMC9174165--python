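import numpy as np
import pytest

from conftest import random_rotation, rigid_copy
from vardyn import descriptors, synthdyn
from vardyn.descriptors import (
    BFACTOR_FACTOR,
    kabsch_superpose,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    rmsf_to_bfactor,
    sasa,
)
from vardyn.errors import DegenerateGeometryError
from vardyn.trajio import Trajectory


class TestKabsch:
    def test_identity_fit(self, rng):
        x = rng.uniform(-5, 5, (6, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd_min == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered_exactly(self, rng):
        x = rng.uniform(-5, 5, (6, 3))
        rot = random_rotation(rng)
        moved = x @ rot.T + np.array([3.0, -2.0, 7.5])
        res = kabsch_superpose(moved, x)
        assert res.rmsd_min == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_beats_random_rigid_search(self, rng):
        """Least squares is a lower bound over 10k random rigid motions."""
        mobile = rng.uniform(-3, 3, (4, 3))
        ref = rng.uniform(-3, 3, (4, 3))
        best = kabsch_superpose(mobile, ref).rmsd_min
        cm_m, cm_r = mobile.mean(0), ref.mean(0)
        for _ in range(10_000):
            rot = random_rotation(rng)
            cand = (mobile - cm_m) @ rot.T + cm_r
            rmsd = np.sqrt(((cand - ref) ** 2).sum(1).mean())
            assert best <= rmsd + 1e-12

    def test_collinear_reference_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line + 0.0, line)


class TestRmsdSeries:
    def test_constant_trajectory_is_zero(self, rng):
        ref = rng.uniform(-5, 5, (5, 3))
        traj = synthdyn.gen_gaussian_ensemble(
            synthdyn.EnsembleSpec(ref, np.zeros((15, 15)), 4, 0)
        )
        assert np.allclose(rmsd_series(traj).values, 0.0, atol=1e-9)

    def test_rigid_motions_give_zero(self, rng, small_gaussian_traj):
        base = small_gaussian_traj.coords[0]
        frames = [base]
        for _ in range(4):
            frames.append(base @ random_rotation(rng).T + rng.uniform(-9, 9, 3))
        traj = Trajectory(
            small_gaussian_traj.topology, np.array(frames), np.arange(5) * 0.1
        )
        assert np.allclose(rmsd_series(traj).values, 0.0, atol=1e-9)

    def test_single_displaced_atom_without_superposition(self, rng):
        """One atom moved 1 A among N fixed gives RMSD = 1/sqrt(N)."""
        n = 8
        base = rng.uniform(-5, 5, (n, 3))
        moved = base.copy()
        moved[0, 0] += 1.0
        traj = Trajectory(
            synthdyn.ca_topology(n), np.array([base, moved]), [0.0, 0.1]
        )
        vals = rmsd_series(traj, superpose=False).values
        assert vals[1] == pytest.approx(1.0 / np.sqrt(n), abs=1e-12)


class TestRadiusOfGyration:
    def test_two_points_two_angstrom_apart(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pts) == pytest.approx(1.0, abs=1e-12)

    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2, 3]])) == 0.0

    def test_matches_direct_sum_oracle(self, rng):
        pts = rng.uniform(-10, 10, (100, 3))
        com = pts.mean(0)
        direct = np.sqrt(sum(((p - com) ** 2).sum() for p in pts) / 100)
        assert radius_of_gyration(pts) == pytest.approx(direct, abs=1e-10)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(-10, 10, (20, 3))
        moved = pts @ random_rotation(rng).T + np.array([5.0, -1, 2])
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(pts), abs=1e-9
        )


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        per_atom, total = sasa(np.zeros((1, 3)), np.array([1.9]), probe=1.4)
        assert total == pytest.approx(4 * np.pi * 3.3**2, rel=1e-6)

    def test_symmetric_pair_splits_area_equally(self):
        """Two identical overlapping atoms expose equal areas by symmetry,
        jointly less than two free spheres."""
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        per_atom, total = sasa(coords, np.array([1.9, 1.9]), probe=1.4)
        one_sphere = 4 * np.pi * 3.3**2
        assert per_atom[0] == pytest.approx(per_atom[1], rel=0.02)
        assert total < 2 * one_sphere
        # analytic spherical-cap area of the buried lune: h = r - d/2
        cap = 2 * np.pi * 3.3 * (3.3 - 1.0)
        assert per_atom[0] == pytest.approx(one_sphere - cap, rel=0.02)

    def test_three_atom_toy_matches_monte_carlo_oracle(self, rng):
        coords = np.array([[0.0, 0, 0], [2.5, 0, 0], [1.2, 2.0, 0]])
        radii = np.array([1.7, 1.55, 1.52])
        _, total = sasa(coords, radii, probe=1.4, n_points=960)
        # independent seeded Monte-Carlo surface integration
        expanded = radii + 1.4
        mc_total = 0.0
        for i in range(3):
            z = rng.standard_normal((200_000, 3))
            pts = coords[i] + expanded[i] * z / np.linalg.norm(z, axis=1)[:, None]
            others = [j for j in range(3) if j != i]
            d = np.stack(
                [np.linalg.norm(pts - coords[j], axis=1) for j in others], axis=1
            )
            frac = (d >= expanded[others]).all(axis=1).mean()
            mc_total += frac * 4 * np.pi * expanded[i] ** 2
        assert total == pytest.approx(mc_total, rel=0.01)

    def test_rotation_invariance_within_sampling_error(self, rng):
        coords = rng.uniform(-3, 3, (5, 3))
        radii = np.full(5, 1.7)
        _, t1 = sasa(coords, radii)
        _, t2 = sasa(coords @ random_rotation(rng).T + 4.0, radii)
        assert t2 == pytest.approx(t1, rel=0.02)

    def test_accuracy_floor_enforced(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([1.7]), n_points=16)


class TestRmsf:
    def test_constant_trajectory_is_zero(self, rng):
        ref = rng.uniform(-5, 5, (5, 3))
        traj = synthdyn.gen_gaussian_ensemble(
            synthdyn.EnsembleSpec(ref, np.zeros((15, 15)), 4, 0)
        )
        assert np.allclose(rmsf(traj), 0.0, atol=1e-9)

    def test_two_mirrored_frames(self, rng):
        """Two frames symmetric about the mean: RMSF = half the displacement."""
        base = rng.uniform(-5, 5, (6, 3))
        delta = np.zeros_like(base)
        delta[2] = [0.8, 0.0, 0.0]
        traj = Trajectory(
            synthdyn.ca_topology(6),
            np.array([base - delta / 2, base + delta / 2]),
            [0.0, 0.1],
        )
        vals = rmsf(traj, superpose=False)
        assert vals[2] == pytest.approx(0.4, abs=1e-12)
        assert np.allclose(np.delete(vals, 2), 0.0, atol=1e-12)

    def test_frame_order_invariance(self, small_gaussian_traj):
        fwd = rmsf(small_gaussian_traj)
        rev = Trajectory(
            small_gaussian_traj.topology,
            small_gaussian_traj.coords[::-1].copy(),
            small_gaussian_traj.times.copy(),
        )
        np.testing.assert_allclose(rmsf(rev), fwd, atol=1e-6)

    def test_single_frame_rejected(self, rng):
        traj = Trajectory(synthdyn.ca_topology(4), rng.uniform(-1, 1, (1, 4, 3)), [0.0])
        with pytest.raises(ValueError):
            rmsf(traj)


class TestBfactor:
    def test_unit_rmsf_value_and_monotonicity(self):
        assert rmsf_to_bfactor(0.0) == 0.0
        assert float(rmsf_to_bfactor(1.0)) == pytest.approx(8 * np.pi**2 / 3, abs=1e-9)
        assert BFACTOR_FACTOR == pytest.approx(26.3189, abs=1e-3)
        vals = rmsf_to_bfactor(np.linspace(0, 2, 10))
        assert np.all(np.diff(vals) > 0)

    def test_negative_rmsf_rejected(self):
        with pytest.raises(ValueError):
            rmsf_to_bfactor(-0.1)


class TestSeriesSummary:
    def test_density_normalised_and_covers_support(self, rng):
        s = descriptors.SeriesSummary(rng.normal(3.0, 0.5, 400))
        grid, pdf = s.density
        assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-3)
        assert grid[0] < s.values.min() and grid[-1] > s.values.max()
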