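import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cartstrain import kinematics as kin
from cartstrain.mesh import sphere_cap
from cartstrain.synthetic import GaitSpec, make_gait

TRIAD = kin.MarkerTriad(np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0], [0.0, 25.0, 5.0]]))


# ---------------------------------------------------------------------------
# estimate_rigid_pose


def test_identity_pose():
    pose = kin.estimate_rigid_pose(TRIAD, TRIAD.body_frame_points)
    assert np.allclose(pose.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(pose.translation, 0.0, atol=1e-12)
    assert pose.residual_rms == pytest.approx(0.0, abs=1e-12)


def test_ninety_degree_rotation_and_shift():
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    obs = TRIAD.body_frame_points @ R.T + np.array([5.0, 0.0, 0.0])
    pose = kin.estimate_rigid_pose(TRIAD, obs)
    angle = np.degrees(np.arccos((np.trace(pose.rotation) - 1) / 2))
    assert angle == pytest.approx(90.0, abs=1e-9)
    assert np.allclose(pose.translation, [5.0, 0.0, 0.0], atol=1e-9)


def test_collinear_markers_rejected():
    with pytest.raises(kin.DegenerateConfigurationError):
        kin.MarkerTriad(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
    with pytest.raises(kin.DegenerateConfigurationError):
        kin.estimate_rigid_pose(
            TRIAD, np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        )


def test_noisy_pose_error_matches_resimulation_oracle(rng):
    """DERIVED: mean translation error vs an independent estimator (scipy
    align_vectors) on the same replicates, within 10%."""
    sigma = 0.1
    n_rep = 1000
    R = Rotation.from_euler("zyx", [20, -35, 10], degrees=True).as_matrix()
    t = np.array([3.0, -7.0, 12.0])
    body = TRIAD.body_frame_points
    clean = body @ R.T + t
    errs_ours, errs_oracle = [], []
    for _ in range(n_rep):
        obs = clean + rng.normal(0, sigma, size=body.shape)
        pose = kin.estimate_rigid_pose(TRIAD, obs)
        errs_ours.append(np.linalg.norm(pose.translation - t))
        # oracle: independent Kabsch route via scipy
        rot, _ = Rotation.align_vectors(obs - obs.mean(axis=0), body - body.mean(axis=0))
        t_o = obs.mean(axis=0) - rot.as_matrix() @ body.mean(axis=0)
        errs_oracle.append(np.linalg.norm(t_o - t))
    assert np.mean(errs_ours) == pytest.approx(np.mean(errs_oracle), rel=0.10)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_noiseless_recovery_exact_property(seed):
    rng = np.random.default_rng(seed)
    body = rng.uniform(-50, 50, size=(3, 3))
    area = 0.5 * np.linalg.norm(np.cross(body[1] - body[0], body[2] - body[0]))
    if area < 1.0:
        return  # skip near-degenerate draws
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-100, 100, size=3)
    pose = kin.estimate_rigid_pose(kin.MarkerTriad(body), body @ R.T + t)
    assert np.abs(pose.rotation - R).max() < 1e-9
    assert np.abs(pose.translation - t).max() < 1e-9


# ---------------------------------------------------------------------------
# register_model_to_frame


def test_register_identity():
    surf = sphere_cap(10.0, 40.0, n_polar=4, n_azimuth=8)
    out = kin.register_model_to_frame(surf, kin.RigidPose.identity())
    assert np.allclose(out.vertices, surf.vertices)


def test_register_pure_translation():
    surf = sphere_cap(10.0, 40.0, n_polar=4, n_azimuth=8)
    out = kin.register_model_to_frame(surf, kin.RigidPose(np.eye(3), [0.0, 0.0, 10.0]))
    assert np.allclose(out.vertices[:, 2] - surf.vertices[:, 2], 10.0)
    assert np.allclose(out.vertices[:, :2], surf.vertices[:, :2])


def test_register_inverse_roundtrip(rng):
    surf = sphere_cap(10.0, 40.0, n_polar=4, n_azimuth=8)
    pose = kin.RigidPose(
        Rotation.random(random_state=rng).as_matrix(), rng.uniform(-20, 20, 3)
    )
    back = kin.register_model_to_frame(
        kin.register_model_to_frame(surf, pose), pose.inverse()
    )
    assert np.abs(back.vertices - surf.vertices).max() < 1e-9


# ---------------------------------------------------------------------------
# align_by_subchondral (ICP)


def test_icp_identical_surfaces():
    surf = sphere_cap(10.0, 50.0, n_polar=10, n_azimuth=20)
    pose = kin.align_by_subchondral(surf, surf)
    assert pose.final_rms < 1e-9
    assert np.allclose(pose.rotation, np.eye(3), atol=1e-9)


def test_icp_recovers_small_known_motion():
    surf = sphere_cap(10.0, 50.0, n_polar=16, n_azimuth=32)
    # make it asymmetric so rotation is observable
    surf = surf.copy()
    surf.vertices[:, 2] *= 1.15
    R = Rotation.from_euler("y", 2.0, degrees=True).as_matrix()
    t = np.array([0.5, 0.0, 0.0])
    moved = surf.transformed(R, t)
    pose = kin.align_by_subchondral(surf, moved)
    ang = np.degrees(
        np.arccos(np.clip((np.trace(pose.rotation.T @ R) - 1) / 2, -1, 1))
    )
    assert ang < 0.05
    assert np.linalg.norm(pose.translation - t) < 0.01


def test_icp_decimated_target_rms_below_edge_length():
    surf = sphere_cap(10.0, 50.0, n_polar=16, n_azimuth=32)
    deci = sphere_cap(10.0, 50.0, n_polar=8, n_azimuth=16)
    pose = kin.align_by_subchondral(surf, deci)
    assert pose.final_rms < deci.mean_edge_length()


# ---------------------------------------------------------------------------
# relative_dof


IDF = kin.AnatomicalFrame(np.zeros(3), np.eye(3))


def test_relative_dof_identity():
    dof = kin.relative_dof(kin.RigidPose.identity(), kin.RigidPose.identity(), IDF, IDF)
    assert np.allclose(dof, 0.0, atol=1e-12)


def test_relative_dof_translation():
    hum = kin.RigidPose(np.eye(3), [1.0, 2.0, 3.0])
    dof = kin.relative_dof(kin.RigidPose.identity(), hum, IDF, IDF)
    assert np.allclose(dof[:3], [1.0, 2.0, 3.0], atol=1e-12)
    assert np.allclose(dof[3:], 0.0, atol=1e-12)


def test_relative_dof_rotation_about_y():
    R = Rotation.from_euler("y", 30, degrees=True).as_matrix()
    dof = kin.relative_dof(
        kin.RigidPose.identity(), kin.RigidPose(R, np.zeros(3)), IDF, IDF
    )
    assert dof[4] == pytest.approx(30.0, abs=1e-9)
    assert dof[3] == pytest.approx(0.0, abs=1e-9)
    assert dof[5] == pytest.approx(0.0, abs=1e-9)


def test_relative_dof_lab_frame_invariance(rng):
    scap = kin.RigidPose(Rotation.random(random_state=rng).as_matrix(), rng.uniform(-5, 5, 3))
    hum = kin.RigidPose(Rotation.random(random_state=rng).as_matrix(), rng.uniform(-5, 5, 3))
    common = kin.RigidPose(Rotation.random(random_state=rng).as_matrix(), rng.uniform(-50, 50, 3))
    d0 = kin.relative_dof(scap, hum, IDF, IDF)
    d1 = kin.relative_dof(common.compose(scap), common.compose(hum), IDF, IDF)
    assert np.abs(d0 - d1).max() < 1e-9


def test_relative_dof_gimbal_warning():
    R = Rotation.from_euler("ZYX", [0, 89.5, 0], degrees=True).as_matrix()
    with pytest.warns(UserWarning, match="gimbal"):
        kin.relative_dof(kin.RigidPose.identity(), kin.RigidPose(R, np.zeros(3)), IDF, IDF)


# ---------------------------------------------------------------------------
# segment_cycles


def _sin_trace(n_periods=10, frames=60, amp=10.0):
    t = np.arange(n_periods * frames) / frames
    vals = np.zeros((len(t), 6))
    vals[:, 4] = amp * np.sin(2 * np.pi * t)
    vals[:, 0] = 0.3 * np.sin(2 * np.pi * t)
    return kin.DofTrace(vals, frame_rate=120.0)


def test_pure_sinusoid_cycle_count_and_length():
    cycles, bounds = kin.segment_cycles(_sin_trace())
    assert len(cycles) in (9, 10)
    assert cycles.shape[1:] == (101, 6)


def test_constant_trace_raises():
    with pytest.raises(ValueError, match="constant"):
        kin.segment_cycles(kin.DofTrace(np.ones((300, 6))))


def test_boundaries_match_generator_truth(shoulder):
    gait = make_gait(GaitSpec(n_cycles=8, frames_per_cycle=60, seed=5), shoulder)
    _, bounds = kin.segment_cycles(kin.DofTrace(gait.truth_dof))
    starts = np.array([s for s, _ in bounds])
    truth = gait.cycle_starts
    for s in starts:
        assert np.min(np.abs(truth - s)) <= 2.0


def test_resample_preserves_range():
    trace = _sin_trace()
    cycles, _ = kin.segment_cycles(trace)
    for k in (0, 4):
        assert np.ptp(cycles[:, :, k].ravel()) == pytest.approx(
            np.ptp(trace.values[:, k]), rel=0.02
        )


# ---------------------------------------------------------------------------
# reject_outlier_cycles


def test_identical_cycles_all_retained():
    one = np.tile(np.sin(np.linspace(0, 2 * np.pi, 101))[:, None], (1, 6))
    cycles = np.tile(one, (10, 1, 1))
    cs = kin.reject_outlier_cycles(cycles)
    assert cs.retained_mask.all()
    assert np.allclose(cs.representative, one)


def test_averaging_idempotence():
    one = np.random.default_rng(0).normal(size=(101, 6))
    cs = kin.reject_outlier_cycles(np.tile(one, (5, 1, 1)))
    assert np.allclose(cs.representative, one, atol=1e-12)


def test_injected_outlier_removed_exactly(shoulder):
    gait = make_gait(
        GaitSpec(
            n_cycles=10, frames_per_cycle=60, marker_noise_sd=0.0,
            outlier_cycle=4, outlier_scale=5.0, seed=13,
        ),
        shoulder,
    )
    cycles, bounds = kin.segment_cycles(kin.DofTrace(gait.truth_dof))
    cs = kin.reject_outlier_cycles(cycles)
    rejected = np.nonzero(~cs.retained_mask)[0]
    assert len(rejected) == 1
    s, e = bounds[rejected[0]]
    assert s <= 4 * 60 + 30 <= e  # the injected cycle's midpoint


def test_all_rejected_raises():
    # no single DOF can reject every cycle (Chebyshev), but different DOFs
    # can each reject a different pair
    cycles = np.zeros((4, 101, 6))
    cycles[:, :, 0] = np.array([3.0, -3.0, 0.1, -0.1])[:, None]
    cycles[:, :, 1] = np.array([0.1, -0.1, 3.0, -3.0])[:, None]
    with pytest.raises(ValueError, match="tolerance"):
        kin.reject_outlier_cycles(cycles, band_tolerance=0.0)


def test_too_few_cycles_raises():
    with pytest.raises(ValueError):
        kin.reject_outlier_cycles(np.zeros((2, 101, 6)))
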