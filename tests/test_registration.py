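import numpy as np
import pytest
import trimesh
from scipy import optimize

from ctsa.kinematics import (MigrationResult, compose, decompose, invert,
                             random_transform, recompose)
from ctsa.registration import (MeasureConfig, coarse_align, fit_rigid_paired,
                               fit_sphere_centre, icp, measure_migration)
from ctsa.synthetic_phantom import MotionStep, render_pair
from ctsa.validation_stats import expected_measurement
from ctsa.volume_io import SurfaceMesh


def _as_mesh(tm):
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _asymmetric_mesh():
    """A blob with three distinct principal axes and non-zero skewness."""
    tm = trimesh.creation.icosphere(subdivisions=3)
    v = np.asarray(tm.vertices) * [14.0, 8.0, 5.0]
    # break the reflection symmetry along the two strongest axes
    v[:, 0] += 0.04 * v[:, 0] ** 2
    v[:, 1] += 0.06 * v[:, 1] ** 2
    return SurfaceMesh(v, np.asarray(tm.faces))


def _brute_force_fit(ref, tgt):
    """Random-restart numerical least-squares rigid fit (independent oracle)."""

    def cost(params):
        t = recompose(MigrationResult(*params[:3], *params[3:]))
        return (t.apply(ref) - tgt).ravel()

    best, best_cost = None, np.inf
    rng = np.random.default_rng(0)
    starts = [np.zeros(6)] + [np.concatenate([rng.uniform(-5, 5, 3),
                                              rng.uniform(-30, 30, 3)])
                              for _ in range(7)]
    for x0 in starts:
        sol = optimize.least_squares(cost, x0, method="lm", xtol=1e-15,
                                     ftol=1e-15)
        c = 2 * sol.cost
        if c < best_cost:
            best, best_cost = sol.x, c
    return recompose(MigrationResult(*best[:3], *best[3:])), best_cost


class TestFitRigidPaired:
    def test_identical_sets_give_identity(self, rng):
        pts = rng.uniform(-20, 20, (9, 3))
        assert fit_rigid_paired(pts, pts).is_identity(tol=1e-12)

    def test_exact_rotation_about_stated_centre(self, rng):
        pts = rng.uniform(-20, 20, (9, 3))
        truth = recompose(MigrationResult(0, 0, 0, 2.0, 0, 0,
                                          reference_point=(5.0, -3.0, 1.0)))
        fit = fit_rigid_paired(pts, truth.apply(pts))
        np.testing.assert_allclose(fit.rotation, truth.rotation, atol=1e-9)
        np.testing.assert_allclose(fit.translation, truth.translation,
                                   atol=1e-9)

    def test_matches_random_restart_optimiser_on_noisy_sets(self, rng):
        for n in (3, 4, 5, 6):
            pts = rng.uniform(-15, 15, (n, 3))
            truth = random_transform(rng, max_angle_deg=25)
            noisy = truth.apply(pts) + rng.normal(0, 0.3, (n, 3))
            fit = fit_rigid_paired(pts, noisy)
            oracle, oracle_cost = _brute_force_fit(pts, noisy)
            fit_cost = np.sum((fit.apply(pts) - noisy) ** 2)
            assert fit_cost <= oracle_cost + 1e-6
            np.testing.assert_allclose(fit.apply(pts), oracle.apply(pts),
                                       atol=1e-5)

    def test_beats_random_perturbations(self, rng):
        pts = rng.uniform(-15, 15, (9, 3))
        truth = random_transform(rng)
        noisy = truth.apply(pts) + rng.normal(0, 0.2, (9, 3))
        fit = fit_rigid_paired(pts, noisy)
        fit_cost = np.sum((fit.apply(pts) - noisy) ** 2)
        for _ in range(1000):
            jitter = random_transform(rng, max_translation=0.3,
                                      max_angle_deg=1.0)
            cand = compose(jitter, fit)
            assert fit_cost <= np.sum((cand.apply(pts) - noisy) ** 2) + 1e-12

    def test_weighted_fit_downweights_outlier(self, rng):
        pts = rng.uniform(-15, 15, (6, 3))
        truth = random_transform(rng, max_angle_deg=10)
        tgt = truth.apply(pts)
        tgt[0] += [5.0, 5.0, 5.0]
        w = np.array([1e-6, 1, 1, 1, 1, 1])
        fit = fit_rigid_paired(pts, tgt, weights=w)
        np.testing.assert_allclose(fit.rotation, truth.rotation, atol=1e-4)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                       dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_paired(pts, pts + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_rigid_paired(np.zeros((2, 3)), np.ones((2, 3)))


class TestFitSphereCentre:
    def test_exact_on_single_sphere(self, rng):
        d = rng.normal(size=(400, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        centre = np.array([3.0, -1.0, 2.0])
        np.testing.assert_allclose(fit_sphere_centre(centre + 23.5 * d),
                                   centre, atol=1e-9)

    def test_near_central_on_concentric_shells(self, rng):
        d1 = rng.normal(size=(400, 3))
        d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
        d2 = rng.normal(size=(400, 3))
        d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
        centre = np.array([3.0, -1.0, 2.0])
        pts = np.vstack([centre + 20.0 * d1, centre + 23.5 * d2])
        assert np.linalg.norm(fit_sphere_centre(pts) - centre) < 0.5


class TestCoarseAlign:
    def test_mesh_vs_itself_is_identity(self):
        mesh = _asymmetric_mesh()
        t, flags = coarse_align(mesh, mesh)
        assert flags == ()
        assert t.is_identity(tol=1e-6)

    def test_pure_translation_recovered(self):
        mesh = _asymmetric_mesh()
        moved = SurfaceMesh(mesh.vertices + [5.0, 0, 0], mesh.faces)
        t, _ = coarse_align(moved, mesh)
        np.testing.assert_allclose(t.translation, [-5.0, 0, 0], atol=1e-6)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-6)

    def test_rotation_recovered_via_principal_axes(self, rng):
        mesh = _asymmetric_mesh()
        truth = random_transform(rng, max_angle_deg=25)
        moved = SurfaceMesh(truth.apply(mesh.vertices), mesh.faces)
        t, flags = coarse_align(moved, mesh)
        assert flags == ()
        # coarse only: within a degree or so is plenty for an ICP start
        err = decompose(compose(t, truth), (0, 0, 0))
        assert np.abs(err.rotations).max() < 2.0

    def test_degenerate_symmetry_falls_back_flagged(self):
        tm = trimesh.creation.icosphere(subdivisions=3)
        sphere = _as_mesh(tm)
        moved = SurfaceMesh(sphere.vertices + [3.0, 0, 0], sphere.faces)
        t, flags = coarse_align(moved, sphere)
        assert "coarse_align_degenerate_axes" in flags
        np.testing.assert_allclose(t.translation, [-3.0, 0, 0], atol=1e-6)


class TestICP:
    def test_identical_meshes_converge_to_identity(self):
        mesh = _asymmetric_mesh()
        res = icp(mesh, mesh)
        assert res.converged
        assert res.rms_residual < 1e-9
        assert res.transform.is_identity(tol=1e-9)

    def test_exact_correspondence_recovery(self, rng):
        mesh = _asymmetric_mesh()
        truth = random_transform(rng, max_translation=3.0, max_angle_deg=8.0)
        moving = SurfaceMesh(truth.apply(mesh.vertices), mesh.faces)
        init, _ = coarse_align(moving, mesh)
        res = icp(moving, mesh, init, tol=1e-7, max_iter=200)
        err = decompose(compose(res.transform, truth), (0, 0, 0))
        assert np.abs(err.translations).max() < 1e-4
        assert np.abs(err.rotations).max() < 1e-4

    def test_cost_trace_non_increasing(self, rng):
        mesh = _asymmetric_mesh()
        truth = random_transform(rng, max_translation=2.0, max_angle_deg=10.0)
        moving = SurfaceMesh(truth.apply(mesh.vertices), mesh.faces)
        for trim in (0.0, 0.2):
            res = icp(moving, mesh, None, trim=trim)
            trace = np.asarray(res.cost_trace)
            assert np.all(np.diff(trace) <= 1e-12)

    def test_non_convergence_reported_with_best_transform(self, rng):
        mesh = _asymmetric_mesh()
        truth = random_transform(rng, max_angle_deg=10.0)
        moving = SurfaceMesh(truth.apply(mesh.vertices), mesh.faces)
        res = icp(moving, mesh, None, tol=0.0, max_iter=5)
        assert not res.converged
        assert res.iterations == 5
        assert np.isfinite(res.rms_residual)

    def test_partially_overlapping_cap_recovered(self, quiet_spec):
        # occluded-head scenario from the phantom: measure the head implant
        step = MotionStep("zero", MigrationResult(0, 0, 0, 0, 0, 0))
        ref, tgt, _ = render_pair(quiet_spec, step)
        cfg = MeasureConfig.for_phantom(quiet_spec, analysed="head")
        report = measure_migration(ref, tgt, cfg)
        assert np.abs(report.result.translations).max() < 0.05
        assert np.abs(report.result.rotations).max() < 0.1


class TestMeasureMigration:
    def test_null_migration_noiseless(self, quiet_spec):
        step = MotionStep("zero", MigrationResult(0, 0, 0, 0, 0, 0))
        ref, tgt, _ = render_pair(quiet_spec, step)
        report = measure_migration(ref, tgt,
                                   MeasureConfig.for_phantom(quiet_spec))
        assert np.abs(report.result.translations).max() < 0.02
        assert np.abs(report.result.rotations).max() < 0.05
        assert report.qc.acceptable
        assert report.qc.bead_pairs == 9

    def test_one_mm_translation_recovered(self, compact_spec):
        step = MotionStep("tx", MigrationResult(1.0, 0, 0, 0, 0, 0))
        ref, tgt, truth = render_pair(compact_spec, step, seed=11)
        report = measure_migration(ref, tgt,
                                   MeasureConfig.for_phantom(compact_spec))
        expected = expected_measurement(truth, report.result.reference_point)
        assert report.result.tx == pytest.approx(expected.tx, abs=0.2)

    def test_two_degree_rotation_recovered(self, compact_spec):
        step = MotionStep("rx", MigrationResult(0, 0, 0, 2.0, 0, 0))
        ref, tgt, truth = render_pair(compact_spec, step, seed=12)
        report = measure_migration(ref, tgt,
                                   MeasureConfig.for_phantom(compact_spec))
        expected = expected_measurement(truth, report.result.reference_point)
        assert report.result.rx == pytest.approx(expected.rx, abs=0.5)

    def test_swapping_scans_negates_measurement(self, quiet_spec):
        step = MotionStep("ty", MigrationResult(0, 0.6, 0, 0, 0, 0))
        ref, tgt, _ = render_pair(quiet_spec, step)
        cfg = MeasureConfig.for_phantom(quiet_spec,
                                        reference_point=(0.0, 0.0, 0.0))
        fwd = measure_migration(ref, tgt, cfg)
        rev = measure_migration(tgt, ref, cfg)
        np.testing.assert_allclose(rev.result.as_array(),
                                   -fwd.result.as_array(), atol=0.05)

    def test_single_bead_dropout_barely_moves_result(self, quiet_spec):
        step = MotionStep("tz", MigrationResult(0, 0, 0.5, 0, 0, 0))
        ref, tgt, _ = render_pair(quiet_spec, step)
        report = measure_migration(ref, tgt,
                                   MeasureConfig.for_phantom(quiet_spec))
        pairing = report.pairing
        full = report.result.as_array()
        for leave_out in range(pairing.n_pairs):
            keep = np.arange(pairing.n_pairs) != leave_out
            fit = fit_rigid_paired(pairing.reference.centres[keep],
                                   pairing.target.centres[keep])
            sub = decompose(invert(fit), report.result.reference_point)
            diff = np.abs(sub.as_array() - full)
            assert diff[:3].max() < 0.05
            assert diff[3:].max() < 0.1

    def test_icp_trace_monotone_in_pipeline(self, quiet_spec):
        from ctsa.registration import _extract_features, coarse_align as ca

        step = MotionStep("zero", MigrationResult(0, 0, 0, 0, 0, 0))
        ref, tgt, _ = render_pair(quiet_spec, step)
        cfg = MeasureConfig.for_phantom(quiet_spec)
        rf = _extract_features(ref, cfg)
        tf = _extract_features(tgt, cfg)
        init, _ = ca(tf.mesh, rf.mesh)
        res = icp(tf.mesh, rf.mesh, init, sample=cfg.icp_sample)
        assert np.all(np.diff(res.cost_trace) <= 1e-12)
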