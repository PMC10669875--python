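"""Deployment pose recovery, hologram chaining, freeze/unfreeze drift model."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from crosshairsim.lasers import project_crosshair
from crosshairsim.registration import (
    DeployOptions,
    DeploymentError,
    Mode,
    RegistrationState,
    current_transform,
    deploy_simulator,
    deployment_hessian,
    drift_step,
    freeze,
    register_holograms,
    unfreeze,
)
from crosshairsim.phantoms import make_frame_graph
from crosshairsim.transforms import (
    CHAIN_FACTORS,
    Frame,
    FrameGraph,
    RigidTransform,
    compose,
    random_rigid_transform,
)


def true_rig_pose(fixture):
    return RigidTransform.from_rotvec(
        Frame.SCS, Frame.WORLD,
        fixture.scanner_pose.rotvec, fixture.scanner_pose.translation,
    )


def perturbed(pose, mm, deg, seed=7):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    shift = rng.normal(size=3)
    shift = shift / np.linalg.norm(shift) * mm
    return compose(
        pose,
        RigidTransform.from_rotvec(Frame.WORLD, Frame.WORLD, np.deg2rad(deg) * axis, shift),
    )


class TestDeploy:
    def test_truth_start_stays_at_truth(self, small_fixture, nominal_rig):
        truth = true_rig_pose(small_fixture)
        res = deploy_simulator(
            small_fixture.marked_lines, small_fixture.mesh, nominal_rig, truth,
            DeployOptions(n_starts=1, maxiter=300, seed=0),
        )
        assert res.misfit_mm < 0.05
        assert np.linalg.norm(res.pose.translation - truth.translation) < 0.1

    def test_recovery_from_perturbed_start(self, small_fixture, nominal_rig):
        truth = true_rig_pose(small_fixture)
        init = perturbed(truth, 3.0, 3.0)
        res = deploy_simulator(
            small_fixture.marked_lines, small_fixture.mesh, nominal_rig, init,
            DeployOptions(n_starts=1, seed=1),
        )
        rot_err = Rotation.from_matrix(res.pose.rotation @ truth.rotation.T).magnitude()
        assert np.rad2deg(rot_err) < 0.1
        assert np.linalg.norm(res.pose.translation - truth.translation) < 0.1
        assert res.t_ssc.is_close(RigidTransform.identity(Frame.SCS, Frame.SCANNER))

    def test_multi_start_determinism(self, small_fixture, nominal_rig):
        truth = true_rig_pose(small_fixture)
        init = perturbed(truth, 2.0, 2.0)
        opts = DeployOptions(n_starts=2, seed=5, maxiter=150, fail_threshold_mm=np.inf)
        a = deploy_simulator(
            small_fixture.marked_lines, small_fixture.mesh, nominal_rig, init, opts
        )
        b = deploy_simulator(
            small_fixture.marked_lines, small_fixture.mesh, nominal_rig, init, opts
        )
        assert np.array_equal(a.pose.matrix, b.pose.matrix)

    def test_failure_reports_best_misfit(self, small_fixture, nominal_rig):
        truth = true_rig_pose(small_fixture)
        with pytest.raises(DeploymentError) as exc:
            deploy_simulator(
                small_fixture.marked_lines, small_fixture.mesh, nominal_rig,
                perturbed(truth, 5.0, 5.0),
                DeployOptions(n_starts=1, maxiter=3, fail_threshold_mm=1e-6),
            )
        assert exc.value.best_misfit_mm > 1e-6


class TestDegreeOfFreedomConstraints:
    def test_flat_plate_single_crosshair_leaves_boresight_free(self, nominal_rig):
        """On a plane, one crosshair cannot constrain translation along the
        surface normal: the misfit Hessian has a null direction along it."""
        plate = trimesh.creation.box(extents=[200.0, 200.0, 2.0])
        plate.apply_translation([0.0, 0.0, -1.0])  # top face at z = 0
        pose = RigidTransform.identity(Frame.SCS, Frame.WORLD)
        labels = ("sagittal", "coronal")
        marked = project_crosshair(nominal_rig, plate, labels=labels)
        H = deployment_hessian(marked, plate, nominal_rig, pose, labels=labels)
        w, V = np.linalg.eigh(H)
        assert abs(w[0]) < 1e-6 * abs(w[-1])            # rank-deficient
        null = V[:, 0]
        assert abs(null[5]) > 0.99                      # along t_z (the boresight)

    def test_head_surface_constrains_all_six_dof(self, small_fixture, nominal_rig):
        pose = true_rig_pose(small_fixture)
        H = deployment_hessian(
            small_fixture.marked_lines, small_fixture.mesh, nominal_rig, pose
        )
        w = np.linalg.eigvalsh(H)
        # mixed rad/mm parameterization spreads the spectrum; full rank means the
        # smallest eigenvalue is positive and far above the flat-plate null level
        assert w[0] > 0
        assert w[0] > 1e-6 * w[-1]


class TestRegisterHolograms:
    def test_identity_chain_keeps_points(self):
        g = FrameGraph(RigidTransform.identity(s, t) for s, t, _ in CHAIN_FACTORS)
        pts = np.array([[1.0, 2.0, 3.0], [-4.0, 5.0, -6.0]])
        mapped = register_holograms(g, pts)
        np.testing.assert_allclose(mapped[Frame.WORLD], pts, atol=1e-12)
        np.testing.assert_allclose(mapped[Frame.SCANNER], pts, atol=1e-12)

    def test_zero_noise_pipeline_closes(self, small_fixture):
        graph = make_frame_graph(small_fixture, seed=0)
        fid_rics = small_fixture.scanner_pose.invert().apply(
            small_fixture.fiducials.points
        )
        mapped = register_holograms(graph, fid_rics)
        err = np.linalg.norm(
            mapped[Frame.WORLD] - small_fixture.fiducials.points, axis=1
        )
        assert err.max() < 1e-6

    def test_t_ssc_error_propagates_rigidly(self, small_fixture):
        """A 3 mm translation error in the simulator-to-scanner link shifts every
        mapped point by exactly 3 mm in the scanner frame."""
        graph = make_frame_graph(small_fixture, seed=0)
        fid_rics = small_fixture.scanner_pose.invert().apply(
            small_fixture.fiducials.points
        )
        clean = register_holograms(graph, fid_rics)
        bad = FrameGraph(
            t for t in graph.transforms()
            if not (t.source is Frame.SCS and t.target is Frame.SCANNER)
        )
        bad.add(
            RigidTransform.from_rotation_translation(
                Frame.SCS, Frame.SCANNER, translation=[3.0, 0.0, 0.0]
            )
        )
        shifted = register_holograms(bad, fid_rics)
        delta = np.linalg.norm(
            shifted[Frame.SCANNER] - clean[Frame.SCANNER], axis=1
        )
        np.testing.assert_allclose(delta, 3.0, atol=1e-9)


class TestFreezeUnfreeze:
    def make_state(self, sigma=0.0, seed=0):
        live = RigidTransform.from_rotation_translation(
            Frame.RICS, Frame.WORLD, translation=[1.0, 2.0, 3.0]
        )
        return RegistrationState(live, drift_sigma_mm=sigma, seed=seed)

    def test_freeze_snapshots_current_transform(self):
        st = freeze(self.make_state())
        assert st.mode is Mode.FROZEN
        assert current_transform(st).is_close(st.live, atol=0)

    def test_unfreeze_discards_drift(self):
        st = freeze(self.make_state(sigma=0.05, seed=1))
        drift_step(st, 100)
        assert not np.allclose(current_transform(st).translation, st.live.translation)
        unfreeze(st)
        assert np.array_equal(current_transform(st).translation, st.live.translation)

    def test_drift_rms_matches_isotropic_random_walk(self):
        """Displacement RMS after n steps of a 3D walk is sigma * sqrt(3 n)."""
        sigma, n, reps = 0.05, 50, 400
        sq = []
        for seed in range(reps):
            st = freeze(self.make_state(sigma=sigma, seed=seed))
            drift_step(st, n)
            d = current_transform(st).translation - st.live.translation
            sq.append(d @ d)
        rms = np.sqrt(np.mean(sq))
        assert rms == pytest.approx(sigma * np.sqrt(3 * n), rel=0.08)

    def test_live_mode_ignores_drift_steps(self):
        st = self.make_state(sigma=0.5, seed=2)
        drift_step(st, 10)
        assert current_transform(st).is_close(st.live, atol=0)
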