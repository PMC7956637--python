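"""Structural-metric tests: Kabsch, RMSD, RMSF, PCA, helix bend profiles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import memtraj as mt
from memtraj.metrics import bend_bin_label, helix_bend_angles, kabsch_superpose
from memtraj.synthetic import ideal_helix_ca, make_kinked_helix

from conftest import make_system


def _oracle_min_rmsd(P, Q):
    """Numeric-optimization oracle: minimum RMSD over rotations (translations analytic)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def f(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((Pc @ R.T - Qc) ** 2).sum(axis=1).mean())

    best = np.inf
    for x0 in ([0, 0, 0], [1, 0.5, -0.7], [-2, 1, 2], [0.5, -2, 0.2]):
        res = minimize(f, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        sup = kabsch_superpose(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        R = Rotation.random(random_state=2).as_matrix()
        t = np.array([3.0, -1.0, 2.0])
        sup = kabsch_superpose(P, P @ R.T + t)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, R, atol=1e-8)
        assert np.allclose(sup.translation, t, atol=1e-8)

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirror image: naive SVD solution would reflect
        sup = kabsch_superpose(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_numeric_optimization_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            P = rng.normal(size=(10, 3)) * 3
            Q = rng.normal(size=(10, 3)) * 3
            assert kabsch_superpose(P, Q).rmsd == pytest.approx(
                _oracle_min_rmsd(P, Q), abs=1e-6
            )

    def test_matches_closed_form_library_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            P = rng.normal(size=(15, 3))
            Q = rng.normal(size=(15, 3))
            rot, rssd = Rotation.align_vectors(
                Q - Q.mean(axis=0), P - P.mean(axis=0)
            )
            assert kabsch_superpose(P, Q).rmsd == pytest.approx(
                rssd / np.sqrt(len(P)), abs=1e-9
            )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def _system(self, frames):
        return make_system(np.asarray(frames, dtype=float))

    def test_identical_frames_zero(self):
        base = np.random.default_rng(7).normal(size=(10, 3))
        system = self._system([base] * 5)
        r = mt.rmsd_series(system, np.arange(10))
        assert np.allclose(r, 0.0, atol=1e-12)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(10, 3))
        frames = [base]
        for k in range(4):
            R = Rotation.random(random_state=10 + k).as_matrix()
            frames.append(base @ R.T + rng.normal(size=3))
        r = mt.rmsd_series(self._system(frames), np.arange(10))
        assert np.allclose(r, 0.0, atol=1e-9)

    def test_superposed_rmsd_never_exceeds_raw(self):
        rng = np.random.default_rng(13)
        frames = rng.normal(size=(6, 12, 3)) + np.arange(6)[:, None, None]
        system = self._system(frames)
        fitted = mt.rmsd_series(system, np.arange(12))
        raw = mt.rmsd_series(system, np.arange(12), superpose=False)
        assert np.all(fitted <= raw + 1e-12)

    def test_gaussian_noise_level_and_oracle(self):
        """Noisy trajectory: matches independent per-frame recomputation and
        the sqrt(6) * sigma level (both reference and frame carry noise)."""
        sigma = 0.1
        spec = mt.SyntheticSpec(n_frames=150, n_chol=0, n_popc=0, n_pope=0,
                                sigma=sigma, noise_clip=0.45)
        system, _ = mt.synthesize_trajectory(spec, seed=17)
        sel = mt.select_atoms(system, backbone=True, molecule_class="protein")
        r = mt.rmsd_series(system, sel)
        X = system.coords[:, sel, :]
        oracle = []
        for f in range(system.n_frames):
            rot, rssd = Rotation.align_vectors(
                X[0] - X[0].mean(axis=0), X[f] - X[f].mean(axis=0)
            )
            oracle.append(rssd / np.sqrt(len(sel)))
        assert np.allclose(r, oracle, atol=1e-9)
        assert r[1:].mean() == pytest.approx(sigma * np.sqrt(6.0), rel=0.10)

    def test_empty_selection(self):
        with pytest.raises(ValueError):
            mt.rmsd_series(self._system(np.zeros((2, 4, 3))), np.array([], dtype=int))


class TestRmsfProfile:
    def test_static_trajectory_zero(self):
        base = np.random.default_rng(19).normal(size=(8, 3))
        system = make_system(np.array([base] * 4))
        assert np.allclose(mt.rmsf_profile(system, np.arange(8)), 0.0, atol=1e-12)

    def test_oscillating_atom_closed_form(self):
        # one atom at +-a along x (superposition disabled): RMSF exactly a
        a = 0.8
        base = np.zeros((6, 3))
        base[:, 0] = np.arange(6) * 10.0
        frames = []
        for f in range(10):
            x = base.copy()
            x[2, 0] += a if f % 2 == 0 else -a
            frames.append(x)
        system = make_system(np.array(frames))
        rmsf = mt.rmsf_profile(system, np.arange(6), superpose=False)
        assert rmsf[2] == pytest.approx(a)
        assert np.allclose(np.delete(rmsf, 2), 0.0, atol=1e-12)

    def test_recovers_per_residue_sigma(self):
        """Per-residue noise sigma_i recovered as RMSF_i ~ sigma_i * sqrt(3)."""
        sigmas = {r: s for r, s in zip(range(134, 158), np.linspace(0.05, 0.12, 24))}
        spec = mt.SyntheticSpec(
            helices=(mt.HelixSpec(134, 24, +1, 0.0),),
            n_frames=400, n_chol=0, n_popc=0, n_pope=0, sigma=sigmas,
            drift_translation=(0, 0, 0), drift_rotation_deg=0.0,
        )
        system, truth = mt.synthesize_trajectory(spec, seed=23)
        ca = mt.select_atoms(system, names=("CA",), molecule_class="protein")
        # fluctuation about the window mean, no rigid-body fit to confound it
        rmsf = mt.rmsf_profile(system, ca, superpose=False)
        resids = system.resids[ca]
        n = system.n_frames
        for i, res in enumerate(resids):
            expected = truth.rmsf_sigma[int(res)] * np.sqrt(3.0)
            se = expected / np.sqrt(2 * 3 * n)  # chi-distribution standard error
            assert abs(rmsf[i] - expected) < 3 * se + 0.01 * expected

    def test_superposed_rmsf_preserves_profile_shape(self):
        """With superposition the fitted profile tracks sigma_i (6 rigid DOF
        remove a few percent of variance but not the per-residue shape)."""
        sigmas = {r: s for r, s in zip(range(134, 158), np.linspace(0.05, 0.12, 24))}
        spec = mt.SyntheticSpec(
            helices=(mt.HelixSpec(134, 24, +1, 0.0),),
            n_frames=300, n_chol=0, n_popc=0, n_pope=0, sigma=sigmas,
        )
        system, truth = mt.synthesize_trajectory(spec, seed=29)
        ca = mt.select_atoms(system, names=("CA",), molecule_class="protein")
        fitted = mt.rmsf_profile(system, ca)
        expected = np.array([truth.rmsf_sigma[int(r)] for r in system.resids[ca]])
        assert np.corrcoef(fitted, expected)[0, 1] > 0.95
        raw = mt.rmsf_profile(system, ca, superpose=False)
        # drift is rigid: removed by the fit, so fitted <= raw fluctuation
        assert fitted.mean() <= raw.mean()

    def test_window_too_small(self):
        system = make_system(np.zeros((3, 4, 3)), times=[0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            mt.rmsf_profile(system, np.arange(4), window=(2.0, 2.0))


class TestPcaModes:
    def test_static_trajectory_zero_eigenvalues(self):
        base = np.random.default_rng(29).normal(size=(10, 3))
        system = make_system(np.array([base] * 5))
        pca = mt.pca_modes(system, np.arange(10))
        assert np.allclose(pca.eigenvalues, 0.0, atol=1e-12)

    def test_rank_one_mode_recovered(self):
        from conftest import rigid_free_mode

        rng = np.random.default_rng(31)
        base = rng.normal(size=(30, 3)) * 5
        raw = np.zeros((30, 3))
        raw[0, 0] = 1.0  # one atom moving along x, rigid components removed
        mode = rigid_free_mode(base, raw)
        amps = rng.normal(size=40) * 0.6
        frames = np.array([base + a * mode for a in amps])
        system = make_system(frames)
        pca = mt.pca_modes(system, np.arange(30))
        assert pca.eigenvalues[0] > 100 * abs(pca.eigenvalues[1])
        cos = abs(pca.eigenvectors[:, 0] @ mode.ravel())
        assert cos > 0.99

    def test_trace_identity_against_independent_superposition(self):
        rng = np.random.default_rng(37)
        frames = rng.normal(size=(25, 12, 3))
        system = make_system(frames)
        pca = mt.pca_modes(system, np.arange(12))
        # independent route: superpose with the library closed form, then sum
        # per-coordinate variances
        X = frames.copy()
        ref = X[0]
        for _ in range(2):
            out = np.empty_like(X)
            for f in range(len(X)):
                rot, _ = Rotation.align_vectors(
                    ref - ref.mean(axis=0), X[f] - X[f].mean(axis=0)
                )
                out[f] = (X[f] - X[f].mean(axis=0)) @ rot.as_matrix().T + ref.mean(axis=0)
            X = out
            ref = X.mean(axis=0)
        flat = X.reshape(len(X), -1)
        total_var = flat.var(axis=0, ddof=1).sum()
        assert pca.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_eigenvectors_orthonormal_eigenvalues_nonnegative(self):
        rng = np.random.default_rng(41)
        system = make_system(rng.normal(size=(15, 8, 3)))
        pca = mt.pca_modes(system, np.arange(8))
        V = pca.eigenvectors
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        assert np.all(pca.eigenvalues >= -1e-8)

    def test_truncation_warns(self):
        rng = np.random.default_rng(43)
        system = make_system(rng.normal(size=(4, 6, 3)))
        with pytest.warns(UserWarning, match="truncating"):
            mt.pca_modes(system, np.arange(6), n_components=10)


class TestBendProfile:
    @pytest.mark.parametrize("axis_window", [3, 4, 5, 6])
    def test_ideal_helix_all_blue(self, axis_window):
        _, angles = helix_bend_angles(ideal_helix_ca(32), axis_window=axis_window)
        assert np.all(angles < 6.0)

    def test_kink_51_recovered_and_red(self):
        _, angles = helix_bend_angles(make_kinked_helix(24, 11, 51.0))
        assert abs(angles.max() - 51.0) <= 3.0
        assert bend_bin_label(angles.max()) == "red"

    @pytest.mark.parametrize(
        "kink,label",
        [(5.0, "blue"), (10.0, "cyan"), (15.0, "green"), (20.0, "yellow"), (30.0, "red")],
    )
    def test_bin_edges(self, kink, label):
        _, angles = helix_bend_angles(make_kinked_helix(30, 14, kink))
        assert bend_bin_label(angles.max()) == label

    def test_zero_kink_equals_ideal(self):
        assert np.abs(make_kinked_helix(24, 11, 0.0) - ideal_helix_ca(24)).max() < 1e-6

    def test_too_short_helix_errors(self):
        with pytest.raises(ValueError, match="too short"):
            helix_bend_angles(ideal_helix_ca(15))

    def test_trajectory_profile_on_kinked_bundle(self):
        spec = mt.demo_apo_spec(30)
        system, truth = mt.synthesize_trajectory(spec, seed=47)
        prof = mt.bend_profile(system, (5, 25))
        assert abs(prof.max_angle() - 51.0) <= 4.0  # 51-degree kink + thermal noise
        f, p = np.unravel_index(np.argmax(prof.angles), prof.angles.shape)
        assert prof.labels[f, p] == "red"
        straight = mt.bend_profile(system, (110, 133))
        assert np.all(straight.angles < 12.0)
        assert prof.delta_from_first.shape == prof.angles.shape
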