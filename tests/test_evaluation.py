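"""TRE computation, measurement protocol, rigid least squares, summaries, ANOVA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crosshairsim.evaluation import (
    FiducialSet,
    MeasurementSession,
    anova_oneway,
    fit_rigid_lsq,
    model_to_model_distance,
    run_protocol,
    summarize,
    tre,
)
from crosshairsim.phantoms import make_head_mesh
from crosshairsim.transforms import Frame, RigidTransform, random_rigid_transform

LABELS = ("A", "B", "C", "D", "E", "F")


@pytest.fixture()
def fiducials(rng):
    return FiducialSet(LABELS, rng.normal(scale=60.0, size=(6, 3)), Frame.RICS)


def session(P, probed, reg=1, ses=1):
    return MeasurementSession(reg, ses, P.labels, np.asarray(probed, dtype=float))


class TestTRE:
    def test_zero_when_probed_equals_reference(self, fiducials):
        out = tre(fiducials, session(fiducials, fiducials.points))
        assert np.all(out["distance"] == 0.0)

    def test_hand_computed_distance(self):
        P = FiducialSet(("A", "B", "C"), [[1, 1, 1], [0, 0, 0], [1, 0, 0]])
        Q = np.array([[2.0, 3.0, 3.0], [0, 0, 0], [1, 0, 0]])
        out = tre(P, session(P, Q))
        assert out["distance"].iloc[0] == pytest.approx(3.0)  # sqrt(1+4+4)

    def test_label_permutation_leaves_multiset_unchanged(self, fiducials, rng):
        probed = fiducials.points + rng.normal(size=(6, 3))
        base = tre(fiducials, session(fiducials, probed))
        perm = rng.permutation(6)
        out = tre(
            fiducials,
            MeasurementSession(1, 1, tuple(np.array(fiducials.labels)[perm]), probed[perm]),
        )
        assert sorted(out["distance"]) == pytest.approx(sorted(base["distance"]))

    def test_unknown_label_rejected(self, fiducials):
        with pytest.raises(ValueError, match="not in fiducial set"):
            tre(fiducials, MeasurementSession(1, 1, ("Z",) * 6, np.zeros((6, 3))))

    def test_invariant_under_common_rigid_transform(self, fiducials, rng):
        probed = fiducials.points + rng.normal(size=(6, 3))
        base = tre(fiducials, session(fiducials, probed))["distance"]
        T = random_rigid_transform(rng, Frame.RICS, Frame.RICS)
        moved = FiducialSet(fiducials.labels, T.apply(fiducials.points))
        out = tre(moved, session(moved, T.apply(probed)))["distance"]
        np.testing.assert_allclose(out, base, atol=1e-9)


class TestProtocol:
    def test_protocol_shape_three_by_three_by_six(self, fiducials):
        report = run_protocol(fiducials, 3, 3, noise_sigma=1.0, seed=0)
        assert len(report.data) == 54
        assert report.data.groupby(["registration", "session"]).size().eq(6).all()

    def test_noiseless_protocol_is_exact(self, fiducials):
        report = run_protocol(fiducials, 3, 3, noise_sigma=0.0, seed=0)
        assert report.distances.max() < 1e-6

    def test_isotropic_noise_gives_chi3_mean(self, fiducials):
        """Per-point TRE under isotropic N(0, sigma^2) noise follows a chi
        distribution with 3 dof: mean = 2 sigma sqrt(2/pi)."""
        sigma = 2.32
        report = run_protocol(fiducials, 1, 600, noise_sigma=sigma, seed=1)
        expected = 2.0 * sigma * np.sqrt(2.0 / np.pi)
        assert report.distances.mean() == pytest.approx(expected, rel=0.05)

    def test_axis_components_are_zero_mean_with_sd_sigma(self, fiducials):
        sigma = 1.5
        report = run_protocol(fiducials, 1, 800, noise_sigma=sigma, seed=2)
        for ax in ("dx", "dy", "dz"):
            vals = report.data[ax].to_numpy()
            assert abs(vals.mean()) < 5 * sigma / np.sqrt(len(vals))
            assert vals.std(ddof=1) == pytest.approx(sigma, rel=0.06)

    def test_deployment_bias_is_shared_within_registration(self, fiducials):
        report = run_protocol(
            fiducials, 2, 3, noise_sigma=0.0, seed=3, deployment_sigma_mm=2.0
        )
        for _reg, grp in report.data.groupby("registration"):
            per_marker = grp.groupby("marker")["distance"].nunique()
            assert per_marker.eq(1).all()   # no per-session scatter without noise


class TestFitRigidLsq:
    def test_identity_when_q_equals_p(self, fiducials):
        T = fit_rigid_lsq(fiducials, fiducials.points)
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-12)

    def test_exact_recovery_of_known_transform(self, fiducials):
        T = RigidTransform.from_rotvec(Frame.RICS, Frame.RICS, [0.2, -0.1, 0.4], [5, -2, 9])
        rec = fit_rigid_lsq(fiducials, T.apply(fiducials.points))
        np.testing.assert_allclose(rec.matrix, T.matrix, atol=1e-9)

    def test_reflected_data_returns_proper_rotation(self, fiducials):
        rec = fit_rigid_lsq(fiducials, fiducials.points * np.array([1.0, 1.0, -1.0]))
        assert np.linalg.det(rec.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_configuration_rejected(self):
        P = FiducialSet(("A", "B", "C"), [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            fit_rigid_lsq(P, P.points)

    def test_agrees_with_scipy_align_vectors_on_noisy_data(self, fiducials, rng):
        """Independent route: scipy's Wahba solver must give the same rotation."""
        T = RigidTransform.from_rotvec(Frame.RICS, Frame.RICS, [0.3, 0.1, -0.2], [4, 4, 4])
        Q = T.apply(fiducials.points) + rng.normal(0.0, 0.5, (6, 3))
        rec = fit_rigid_lsq(fiducials, Q)
        pc, qc = fiducials.points.mean(axis=0), Q.mean(axis=0)
        R_ref, _ = Rotation.align_vectors(Q - qc, fiducials.points - pc)
        np.testing.assert_allclose(rec.rotation, R_ref.as_matrix(), atol=1e-8)

    def test_residual_no_worse_than_identity(self, fiducials, rng):
        Q = fiducials.points + rng.normal(0.0, 2.0, (6, 3))
        rec = fit_rigid_lsq(fiducials, Q)
        res_fit = np.linalg.norm(rec.apply(fiducials.points) - Q)
        res_id = np.linalg.norm(fiducials.points - Q)
        assert res_fit <= res_id + 1e-12


class TestModelToModelDistance:
    def test_identity_and_translation(self):
        mesh = make_head_mesh(seed=0, subdivisions=2)
        I = RigidTransform.identity(Frame.RICS)
        assert model_to_model_distance(mesh, I).max() == 0.0
        T = RigidTransform.from_rotation_translation(
            Frame.RICS, Frame.RICS, translation=[0.0, 4.0, 0.0]
        )
        np.testing.assert_allclose(model_to_model_distance(mesh, T), 4.0)

    def test_rotation_matches_closed_form(self):
        mesh = make_head_mesh(seed=0, subdivisions=2)
        T = RigidTransform.from_rotvec(Frame.RICS, Frame.RICS, [0.0, 0.0, 0.05])
        d = model_to_model_distance(mesh, T)
        expected = np.linalg.norm(
            mesh.vertices @ (T.rotation - np.eye(3)).T, axis=1
        )
        np.testing.assert_allclose(d, expected, atol=1e-12)


class TestSummarize:
    def make_report(self, values):
        P = FiducialSet(("A", "B", "C"), np.eye(3) * 40.0)
        report = run_protocol(P, 1, 1, seed=0)
        report.data["distance"] = values
        return report

    def test_hand_arithmetic(self):
        s = summarize(self.make_report([3.0, 4.0, 5.0]), cutoff_mm=4.5)
        assert s["overall"]["mean"] == pytest.approx(4.0)
        assert s["overall"]["min"] == 3.0 and s["overall"]["max"] == 5.0
        assert s["overall"]["fraction_below_cutoff"] == pytest.approx(2 / 3)

    def test_cutoff_extremes(self):
        s_low = summarize(self.make_report([3.0, 4.0, 5.0]), cutoff_mm=1.0)
        s_high = summarize(self.make_report([3.0, 4.0, 5.0]), cutoff_mm=100.0)
        assert s_low["overall"]["fraction_below_cutoff"] == 0.0
        assert s_high["overall"]["fraction_below_cutoff"] == 1.0

    def test_grand_mean_equals_mean_of_equal_size_group_means(self, fiducials):
        report = run_protocol(fiducials, 3, 3, noise_sigma=1.0, seed=4)
        s = summarize(report)
        group_means = [v["mean"] for v in s["per_registration"].values()]
        assert s["overall"]["mean"] == pytest.approx(np.mean(group_means))


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        assert anova_oneway([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]]) == (0.0, 1.0)

    def test_hand_computed_f_statistic(self):
        # SSB = 4, SSW = 1 on df (1, 2)  ->  F = (4/1) / (1/2) = 8
        F, p = anova_oneway([[1.0, 2.0], [3.0, 4.0]])
        assert F == pytest.approx(8.0)
        assert 0.0 < p < 1.0

    def test_location_invariance(self, rng):
        groups = [rng.normal(size=10), rng.normal(size=10), rng.normal(size=10)]
        F0, _ = anova_oneway(groups)
        F1, _ = anova_oneway([g + 17.3 for g in groups])
        assert F1 == pytest.approx(F0, rel=1e-9)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])
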