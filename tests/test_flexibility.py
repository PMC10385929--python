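"""Bead coarse-graining, covariance PCA, vibrational weighting and the
rocking-bundle projected flexibilities."""

import warnings

import numpy as np
import pytest

from hydroflex.core import ConsistencyError, KB_KCAL, SelectionError, Topology, Trajectory, assign_domains
from hydroflex.flexibility import (
    FOUR_BEAD_LABELS,
    Bead,
    BeadModel,
    PCAResult,
    ProjectionVector,
    bead_trajectory,
    build_beads,
    fit_series,
    overall_flexibility,
    pca,
    projected_flexibility,
    rigid_body_basis,
    rocking_bundle_projections,
    segment_analysis,
    vibrational_weights,
)
from hydroflex.synthetic import (
    DEFAULT_TM_RANGES,
    GaussianBeadSpec,
    _default_mean,
    make_channel_system,
    make_gaussian_beads,
    vibrational_covariance,
)

KBT = KB_KCAL * 303.15


def _rotz(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@pytest.fixture(scope="module")
def domain_system():
    top, traj, _ = make_channel_system(n_complete_out=0, n_complete_in=0,
                                       n_partial=0, n_interface=0, n_wrap=0,
                                       n_bulk=5, n_frames=80, seed=5)
    return assign_domains(top, DEFAULT_TM_RANGES), traj


class TestBuildBeads:
    def test_four_beads_conserve_domain_mass(self, domain_system):
        top, traj = domain_system
        traj = Trajectory(top, traj.frames)
        model = build_beads(top, traj, "four_bead_domain")
        assert [b.label for b in model.beads] == list(FOUR_BEAD_LABELS)
        dom_mass = sum(top.masses[top.atom_indices_with_domain("bundle", "hash")])
        assert model.masses.sum() == pytest.approx(dom_mass)
        # each domain contributes exactly its atoms, split in two
        bundle_atoms = set(top.atom_indices_with_domain("bundle"))
        got = set(model.beads[0].atom_indices) | set(model.beads[1].atom_indices)
        assert got == bundle_atoms

    def test_binding_site_picks_nearest_residues(self, domain_system):
        top, traj = domain_system
        traj = Trajectory(top, traj.frames)
        center = np.array([0.0, 0.0, 0.0])
        model = build_beads(top, traj, "binding_site_residues",
                            binding_site_center=center, n_residues=8)
        assert model.n_beads == 8
        # brute-force oracle: sort residues by mean CoM distance to centre
        from hydroflex.permeation import group_com_series
        res = top.residues_with_domain("bundle", "hash", "gating", "other")
        coms = group_com_series(traj, [r.atom_indices for r in res]).mean(axis=0)
        d = np.linalg.norm(coms - center, axis=1)
        nearest = {res[i].residue_id for i in np.argsort(d)[:8]}
        assert {int(b.label.split("_")[1]) for b in model.beads} == nearest

    def test_too_few_residues_rejected(self, domain_system):
        top, traj = domain_system
        with pytest.raises(SelectionError):
            build_beads(top, Trajectory(top, traj.frames),
                        "binding_site_residues",
                        binding_site_center=np.zeros(3), n_residues=99)

    def test_unassigned_domains_rejected(self):
        top, traj, _ = make_channel_system(n_bulk=2, n_complete_out=0,
                                           n_complete_in=0, n_partial=0,
                                           n_interface=0, n_wrap=0,
                                           n_frames=60, seed=1)
        with pytest.raises(SelectionError, match="assign_domains"):
            build_beads(top, traj, "four_bead_domain")


class TestBeadTrajectory:
    def _drifting_series(self, rigid="translate"):
        mean = _default_mean(4)
        masses = np.full(4, 100.0)
        frames, times = 50, np.arange(50.0)
        pos = np.tile(mean, (frames, 1, 1))
        if rigid == "translate":
            pos = pos + np.linspace(0, 10, frames)[:, None, None] * np.array([1.0, 0, 0])
        else:
            for f in range(frames):
                R = _rotz(np.deg2rad(f))
                com = mean.mean(axis=0)
                pos[f] = (mean - com) @ R.T + com
        return pos, masses

    def test_fit_removes_translation(self):
        pos, masses = self._drifting_series("translate")
        fitted = fit_series(pos, masses)
        assert np.ptp(fitted, axis=0).max() < 1e-10

    def test_fit_removes_rotation(self):
        pos, masses = self._drifting_series("rotate")
        fitted = fit_series(pos, masses)
        rmsd = np.sqrt(((fitted - fitted.mean(axis=0)) ** 2).sum(axis=(1, 2)))
        assert rmsd.max() < 1e-6

    def test_unfitted_series_keeps_raw_motion(self, domain_system):
        top, traj = domain_system
        traj = Trajectory(top, traj.frames)
        model = build_beads(top, traj, "four_bead_domain")
        raw = bead_trajectory(traj, model, fit=False)
        from hydroflex.permeation import group_com_series
        expected = group_com_series(traj, [b.atom_indices for b in model.beads])
        np.testing.assert_allclose(raw.positions, expected)


class TestPCA:
    def test_frozen_trajectory_has_zero_eigenvalues(self):
        pos = np.tile(_default_mean(4), (100, 1, 1))
        res = pca(pos)
        assert res.eigenvalues.max() < 1e-12
        assert res.flexibility.sum() == 0.0
        assert np.isinf(res.stiffness).all()

    def test_trace_identity(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        res = pca(fix.series)
        X = fix.series.positions.reshape(fix.series.n_frames, -1)
        total_var = ((X - X.mean(axis=0)) ** 2).mean(axis=0).sum()
        assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-8)

    def test_eigenvectors_orthonormal(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        res = pca(fix.series)
        V = res.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[0]), atol=1e-8)

    def test_gaussian_eigenvalue_recovery(self, gauss_vibrational):
        fix, lams = gauss_vibrational
        res = pca(fix.series)
        np.testing.assert_allclose(res.eigenvalues[:3], lams, rtol=0.05)

    def test_scale_law(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        r1 = vibrational_weights(pca(fix.series.positions[:2000]))
        r2 = vibrational_weights(pca(2.0 * fix.series.positions[:2000]))
        np.testing.assert_allclose(r2.eigenvalues, 4.0 * r1.eigenvalues,
                                   atol=1e-10)
        assert overall_flexibility(r2) == pytest.approx(
            4.0 * overall_flexibility(r1), rel=1e-6)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ConsistencyError):
            pca(np.zeros((1, 4, 3)))


class TestVibrationalWeights:
    def test_pure_rotation_mode_scores_zero(self):
        mean = _default_mean(4)
        masses = np.full(4, 100.0)
        Q = rigid_body_basis(mean, masses)
        res = PCAResult(eigenvalues=np.ones(12), eigenvectors=np.eye(12),
                        mean_structure=mean, kBT=KBT, n_frames=100,
                        masses=masses)
        # replace first eigenvector by a rigid rotation direction
        res.eigenvectors[:, 0] = Q[5]
        res = vibrational_weights(res)
        assert res.vibrational_weights[0] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_mode_scores_one(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        res = vibrational_weights(pca(fix.series))
        active = res.eigenvalues > 1e-6
        assert res.vibrational_weights[active].min() > 0.999

    def test_matches_gram_schmidt_oracle(self):
        rng = np.random.default_rng(9)
        mean = _default_mean(4)
        masses = np.full(4, 100.0)
        # explicit Gram-Schmidt of the 6 raw rigid vectors
        com = masses @ mean / masses.sum()
        rel = mean - com
        raw = []
        for k in range(3):
            t = np.zeros((4, 3))
            t[:, k] = 1.0
            raw.append(t.ravel())
        for k in range(3):
            ax = np.zeros(3)
            ax[k] = 1.0
            raw.append(np.cross(ax, rel).ravel())
        basis = []
        for v in raw:
            for b in basis:
                v = v - (v @ b) * b
            basis.append(v / np.linalg.norm(v))
        for _ in range(10):
            e = rng.normal(size=12)
            e /= np.linalg.norm(e)
            expected = 1.0 - sum((e @ b) ** 2 for b in basis)
            res = PCAResult(eigenvalues=np.ones(12), eigenvectors=np.eye(12),
                            mean_structure=mean, kBT=KBT, n_frames=100,
                            masses=masses)
            res.eigenvectors[:, 0] = e
            res = vibrational_weights(res)
            assert res.vibrational_weights[0] == pytest.approx(expected, abs=1e-8)


class TestFlexibilityScalars:
    def _result(self, lams, weights, dim=6):
        lam = np.zeros(dim)
        lam[:len(lams)] = lams
        res = PCAResult(eigenvalues=lam, eigenvectors=np.eye(dim),
                        mean_structure=_default_mean(dim // 3), kBT=KBT,
                        n_frames=100, masses=np.ones(dim // 3))
        w = np.zeros(dim)
        w[:len(weights)] = weights
        res.vibrational_weights = w
        return res

    def test_hand_value(self):
        # lambda = (2, 1) A^2, w = (1, 0.5), T = 303.15 K
        res = self._result([2.0, 1.0], [1.0, 0.5])
        assert overall_flexibility(res) == pytest.approx(2.5 / KBT)
        assert overall_flexibility(res) == pytest.approx(4.150, abs=2e-3)

    def test_all_weights_one_gives_trace_over_kbt(self):
        res = self._result([3.0, 2.0, 1.0], [1.0, 1.0, 1.0])
        assert overall_flexibility(res) == pytest.approx(6.0 / KBT)

    def test_all_weights_zero_gives_zero(self):
        res = self._result([3.0, 2.0], [0.0, 0.0])
        assert overall_flexibility(res) == 0.0

    def test_missing_weights_rejected(self):
        res = self._result([1.0], [1.0])
        res.vibrational_weights = None
        with pytest.raises(ConsistencyError):
            overall_flexibility(res)


def _four_bead_model():
    beads = [Bead(lbl, np.array([i]), 100.0)
             for i, lbl in enumerate(FOUR_BEAD_LABELS)]
    return BeadModel(beads=beads, representation="four_bead_domain")


def _four_bead_mean():
    # bundle at +x, hash at -x, upper/lower split in z
    return np.array([
        [5.0, 0.0, 6.0],    # bundle_upper
        [5.0, 0.0, -6.0],   # bundle_lower
        [-5.0, 0.0, 6.0],   # hash_upper
        [-5.0, 0.0, -6.0],  # hash_lower
    ])


class TestRockingBundleProjections:
    def test_unit_norm_and_orthogonality(self):
        projs = rocking_bundle_projections(_four_bead_model(), _four_bead_mean())
        A, B, C = (p.P for p in projs)
        for v in (A, B, C):
            assert np.linalg.norm(v) == pytest.approx(1.0)
        assert A @ B == pytest.approx(0.0, abs=1e-12)
        assert A @ C == pytest.approx(0.0, abs=1e-12)
        assert B @ C == pytest.approx(0.0, abs=1e-12)

    def test_requires_four_bead_model(self):
        model = BeadModel(beads=[Bead("res_1", np.array([0]), 1.0)] , representation="binding_site_residues")
        with pytest.raises(ConsistencyError):
            rocking_bundle_projections(model, np.zeros((1, 3)))

    def test_rotation_equivariance_of_projected_flexibility(self):
        model = _four_bead_model()
        mean = _four_bead_mean()
        C = vibrational_covariance(mean, model.masses, [4.0, 1.0, 0.25])
        fix = make_gaussian_beads(GaussianBeadSpec(
            covariance=C, n_frames=4000, seed=3, mean_structure=mean,
            masses=model.masses))
        res = vibrational_weights(pca(fix.series))
        base = {p.label: projected_flexibility(res, p)
                for p in rocking_bundle_projections(model, res.mean_structure)}
        R = _rotz(np.deg2rad(35.0))
        rot = fix.series.positions @ R.T
        res_r = vibrational_weights(pca(rot))
        rotated = {p.label: projected_flexibility(res_r, p)
                   for p in rocking_bundle_projections(model, res_r.mean_structure)}
        for lbl in base:
            assert rotated[lbl] == pytest.approx(base[lbl], rel=1e-6)


class TestProjectedFlexibility:
    def test_projection_on_first_eigenvector(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        res = vibrational_weights(pca(fix.series))
        P = ProjectionVector(P=res.eigenvectors[:, 0].copy(), label="custom")
        assert projected_flexibility(res, P) == pytest.approx(
            res.eigenvalues[0] * res.vibrational_weights[0] / res.kBT)

    def test_orthogonal_projection_is_zero(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        res = vibrational_weights(pca(fix.series))
        # a vector orthogonal to every mode with non-negligible eigenvalue
        lam = res.eigenvalues
        null = res.eigenvectors[:, lam < 1e-12]
        P = ProjectionVector(P=null[:, 0].copy(), label="custom")
        assert projected_flexibility(res, P) == pytest.approx(0.0, abs=1e-10)

    def test_matches_quadratic_form_oracle(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        res = vibrational_weights(pca(fix.series))
        Cw = (res.eigenvectors * res.eigenvalues * res.vibrational_weights) \
            @ res.eigenvectors.T
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = rng.normal(size=12)
            p /= np.linalg.norm(p)
            expected = p @ Cw @ p / res.kBT
            got = projected_flexibility(res, ProjectionVector(P=p, label="custom"))
            assert got == pytest.approx(expected, rel=1e-10)

    def test_basis_sum_equals_overall_with_unit_weights(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        res = pca(fix.series)
        res.vibrational_weights = np.ones(12)
        total = sum(
            projected_flexibility(
                res, ProjectionVector(P=np.eye(12)[i], label="custom"))
            for i in range(12)
        )
        assert total == pytest.approx(res.eigenvalues.sum() / res.kBT, rel=1e-8)

    def test_dimension_mismatch_rejected(self, gauss_vibrational):
        fix, _ = gauss_vibrational
        res = vibrational_weights(pca(fix.series))
        with pytest.raises(ConsistencyError):
            projected_flexibility(
                res, ProjectionVector(P=np.array([1.0, 0, 0]), label="custom"))


class TestSegmentAnalysis:
    def _series(self, lam_scale=1.0, n=2500, seed=21):
        mean = _four_bead_mean()
        masses = np.full(4, 100.0)
        C = lam_scale * vibrational_covariance(mean, masses, [4.0, 1.0, 0.25])
        fix = make_gaussian_beads(GaussianBeadSpec(
            covariance=C, n_frames=n, dt_ns=0.4, seed=seed,
            mean_structure=mean, masses=masses))
        fix.series.model = _four_bead_model()
        return fix.series

    def test_row_count(self):
        series = self._series()  # 2500 frames x 0.4 ns = 1000 ns span
        table = segment_analysis(series, _four_bead_model(), segment_ns=200.0)
        assert len(table) == 5
        assert list(table["segment"]) == [0, 1, 2, 3, 4]

    def test_stationary_segments_agree(self):
        table = segment_analysis(self._series(), _four_bead_model(),
                                 segment_ns=200.0)
        s = table["sigma"].to_numpy()
        assert s.std() / s.mean() < 0.15

    def test_stiffened_fixture_is_everywhere_less_flexible(self):
        soft = segment_analysis(self._series(1.0), _four_bead_model(), 200.0)
        stiff = segment_analysis(self._series(0.5), _four_bead_model(), 200.0)
        assert (stiff["sigma"].to_numpy() < soft["sigma"].to_numpy()).all()
        assert (stiff["sigma_ABC"].to_numpy() <= soft["sigma_ABC"].to_numpy() + 1e-12).all()

    def test_short_span_warns_single_segment(self):
        series = self._series(n=100)  # 40 ns < 200 ns
        with pytest.warns(UserWarning, match="shorter"):
            table = segment_analysis(series, _four_bead_model(), 200.0)
        assert len(table) == 1

    def test_rigid_drift_insensitivity_with_fitting(self):
        mean = _four_bead_mean()
        masses = np.full(4, 100.0)
        C = vibrational_covariance(mean, masses, [4.0, 1.0, 0.25])
        clean = make_gaussian_beads(GaussianBeadSpec(
            covariance=C, n_frames=4000, dt_ns=0.1, seed=13,
            mean_structure=mean, masses=masses))
        drifted = make_gaussian_beads(GaussianBeadSpec(
            covariance=C, n_frames=4000, dt_ns=0.1, seed=13,
            mean_structure=mean, masses=masses, rigid_drift_deg_per_ns=0.2))
        s_clean = overall_flexibility(vibrational_weights(pca(
            fit_series(clean.series.positions, masses))))
        s_drift = overall_flexibility(vibrational_weights(pca(
            fit_series(drifted.series.positions, masses))))
        assert s_drift == pytest.approx(s_clean, rel=0.10)
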