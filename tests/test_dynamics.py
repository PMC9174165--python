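import numpy as np
import pytest

from conftest import random_rotation
from vardyn import synthdyn
from vardyn.dynamics import (
    cosine_content,
    dccm,
    dccm_edges,
    mode_fluctuation,
    pca,
    porcupine,
    rmsip,
)
from vardyn.trajio import Trajectory
from vardyn.synthdyn import ca_topology


def displacement_traj(series_per_atom, seed=0):
    """Trajectory with prescribed per-frame displacements (no rigid motion)."""
    n = len(series_per_atom)
    t = len(series_per_atom[0])
    rng = np.random.default_rng(seed)
    ref = rng.uniform(-8, 8, (n, 3))
    coords = np.repeat(ref[None], t, axis=0)
    for i, disp in enumerate(series_per_atom):
        coords[:, i, :] += np.asarray(disp)
    return Trajectory(ca_topology(n), coords, np.arange(t) * 0.1)


class TestDCCM:
    def test_in_phase_and_anti_phase(self, rng):
        t = 200
        d = rng.standard_normal((t, 3))
        jitter = [0.01 * rng.standard_normal((t, 3)) for _ in range(2)]
        traj = displacement_traj([d, d, -d, jitter[0] + 0.5 * rng.standard_normal((t, 3))])
        c = dccm(traj, superpose=False).c
        assert c[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert c[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_null_and_two_pass_oracle(self, rng):
        n, t = 6, 10_000
        series = [rng.standard_normal((t, 3)) for _ in range(n)]
        traj = displacement_traj(series)
        c = dccm(traj, superpose=False).c
        off = c.copy()
        np.fill_diagonal(off, 0.0)
        assert np.abs(off).max() < 0.05
        # independent two-pass covariance oracle
        coords = traj.coords
        mean = coords.mean(axis=0)
        dr = coords - mean
        oracle = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                num = (dr[:, i, :] * dr[:, j, :]).sum(axis=1).mean()
                den = np.sqrt(
                    (dr[:, i, :] ** 2).sum(axis=1).mean()
                    * (dr[:, j, :] ** 2).sum(axis=1).mean()
                )
                oracle[i, j] = num / den
        np.testing.assert_allclose(c, oracle, atol=1e-10)

    def test_bounded_symmetric_unit_diagonal(self, small_gaussian_traj):
        c = dccm(small_gaussian_traj).c
        assert np.nanmax(np.abs(c)) <= 1.0 + 1e-9
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)

    def test_invariant_under_global_rigid_motion(self, rng, small_gaussian_traj):
        c1 = dccm(small_gaussian_traj).c
        rot = random_rotation(rng)
        moved = Trajectory(
            small_gaussian_traj.topology,
            small_gaussian_traj.coords @ rot.T + np.array([4.0, -7, 1]),
            small_gaussian_traj.times.copy(),
        )
        c2 = dccm(moved).c
        np.testing.assert_allclose(c1, c2, atol=1e-6)

    def test_zero_variance_atom_flagged_nan(self, rng):
        t = 50
        series = [rng.standard_normal((t, 3)), np.zeros((t, 3))]
        c = dccm(displacement_traj(series), superpose=False).c
        assert np.isnan(c[1, :]).all() and np.isnan(c[:, 1]).all()


class TestDccmEdges:
    def test_thresholds(self, rng):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.9
        c[0, 2] = c[2, 0] = 0.3
        c[1, 2] = c[2, 1] = -0.5
        from vardyn.dynamics import DCCM
        d = DCCM([("A", i) for i in range(3)], c)
        assert dccm_edges(d, 1.01) == []
        assert len(dccm_edges(d, 0.0)) == 3  # R(R-1)/2
        strong = dccm_edges(d, 0.8)
        assert strong == [(0, 1, pytest.approx(0.9))]


class TestPCA:
    def test_planar_harmonic_motion_single_mode(self, rng):
        t = 400
        amp = np.sin(np.linspace(0, 6 * np.pi, t))
        disp = np.zeros((t, 3))
        disp[:, 0] = amp
        series = [disp * (i + 1) for i in range(4)]  # common 1-D mode
        p = pca(displacement_traj(series), superpose=False)
        assert p.eigenvalues[0] / p.trace > 0.99

    def test_trace_equals_total_variance_oracle(self, small_gaussian_traj):
        p = pca(small_gaussian_traj, superpose=False)
        x = small_gaussian_traj.coords.reshape(small_gaussian_traj.n_frames, -1)
        direct = x.var(axis=0, ddof=1).sum()
        assert p.trace == pytest.approx(direct, rel=1e-10)
        assert p.eigenvalues.sum() == pytest.approx(p.trace, rel=1e-10)

    def test_projection_statistics(self, small_gaussian_traj):
        p = pca(small_gaussian_traj)
        assert np.abs(p.projections.mean(axis=0)).max() < 1e-10
        cov = np.cov(p.projections, rowvar=False)
        np.testing.assert_allclose(np.diag(cov), p.eigenvalues, atol=1e-8)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_eigenvector_orthonormality(self, small_gaussian_traj):
        p = pca(small_gaussian_traj)
        gram = p.eigenvectors.T @ p.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_planted_low_rank_recovery(self, rng):
        n = 8
        u = rng.standard_normal(3 * n)
        u /= np.linalg.norm(u)
        cov = 4.0 * np.outer(u, u) + 0.01 * np.eye(3 * n)
        traj = synthdyn.gen_gaussian_ensemble(
            synthdyn.EnsembleSpec(rng.uniform(-8, 8, (n, 3)), cov, 50_000, 5)
        )
        p = pca(traj, superpose=False)
        assert abs(p.eigenvectors[:, 0] @ u) > 0.99


class TestRMSIP:
    def test_self_is_one_and_symmetric(self, small_gaussian_traj):
        p = pca(small_gaussian_traj)
        assert rmsip(p, p, 10) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_subspaces_are_zero(self):
        dim = 12
        eye = np.eye(dim)
        a = pca_like(eye[:, :3])
        b = pca_like(eye[:, 3:6])
        assert rmsip(a, b, 3) == pytest.approx(0.0, abs=1e-15)

    def test_matches_double_sum_oracle(self, rng):
        dim = 18
        qa, _ = np.linalg.qr(rng.standard_normal((dim, 6)))
        qb, _ = np.linalg.qr(rng.standard_normal((dim, 6)))
        a, b = pca_like(qa), pca_like(qb)
        val = rmsip(a, b, 6)
        acc = 0.0
        for i in range(6):
            for j in range(6):
                acc += float(qa[:, i] @ qb[:, j]) ** 2
        assert val == pytest.approx(np.sqrt(acc / 6), abs=1e-12)
        assert rmsip(b, a, 6) == pytest.approx(val, abs=1e-12)

    def test_too_many_modes_rejected(self, small_gaussian_traj):
        p = pca(small_gaussian_traj)
        with pytest.raises(ValueError):
            rmsip(p, p, p.n_modes + 1)


def pca_like(vectors: np.ndarray):
    """Wrap an orthonormal column set as a minimal PCAResult."""
    from vardyn.dynamics import PCAResult

    dim, m = vectors.shape
    return PCAResult(
        mean_structure=np.zeros((dim // 3, 3)),
        eigenvectors=vectors,
        eigenvalues=np.linspace(2.0, 1.0, m),
        projections=np.zeros((4, m)),
        trace=float(np.linspace(2.0, 1.0, m).sum()),
    )


class TestCosineContent:
    def test_half_period_cosine_is_one(self):
        t = np.arange(2000)
        p = np.cos(np.pi * t / 2000)
        assert cosine_content(p, 1) == pytest.approx(1.0, abs=1e-3)

    def test_full_period_orthogonal_to_mode_one(self):
        t = np.arange(2000)
        p = np.cos(2 * np.pi * t / 2000)
        assert cosine_content(p, 1) == pytest.approx(0.0, abs=1e-3)

    def test_zero_projection_is_nan(self):
        assert np.isnan(cosine_content(np.zeros(100), 1))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            cosine_content(np.ones(3), 1)

    def test_drift_trajectory_flags_unconverged_sampling(self, rng):
        drift = 0.01 * rng.standard_normal((10, 3))
        traj = synthdyn.gen_drift_ensemble(
            rng.uniform(-5, 5, (10, 3)), drift, 0.02, 500, 4
        )
        p = pca(traj, superpose=False)
        assert cosine_content(p.projections[:, 0], 1) > 0.9


class TestPorcupine:
    def test_zero_scale_tips_equal_bases(self, small_gaussian_traj):
        p = pca(small_gaussian_traj)
        base, tip = porcupine(p, mode=0, scale=0.0)
        np.testing.assert_array_equal(base, tip)

    def test_single_mode_amplitude_pattern(self, rng):
        t = 300
        amp = np.sin(np.linspace(0, 4 * np.pi, t))
        pattern = np.array([1.0, 2.0, 0.5, 3.0])
        series = []
        for w in pattern:
            disp = np.zeros((t, 3))
            disp[:, 1] = w * amp
            series.append(disp)
        p = pca(displacement_traj(series), superpose=False)
        fluct = mode_fluctuation(p, 0)
        cos_sim = (fluct @ pattern) / (
            np.linalg.norm(fluct) * np.linalg.norm(pattern)
        )
        assert cos_sim > 0.99

    def test_amplitude_normalisation(self, small_gaussian_traj):
        p = pca(small_gaussian_traj)
        fluct = mode_fluctuation(p, 1)
        assert (fluct**2).sum() == pytest.approx(p.eigenvalues[1], rel=1e-10)
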