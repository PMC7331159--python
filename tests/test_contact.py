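import numpy as np
import pytest

from cartstrain import contact
from cartstrain.kinematics import RigidPose
from cartstrain.mesh import TriSurface, sphere_cap
from cartstrain.synthetic import ShoulderSpec, make_shoulder


def sphere_overlap_analytic(theta, a, delta):
    """Penetration of conforming spheres (radius a) approached by delta,
    at polar angle theta from the approach axis."""
    return a - np.sqrt(a**2 - 2 * a * delta * np.cos(theta) + delta**2)


def _flat_grid(z, n=12, extent=20.0):
    xs = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + n, a + n + 1])
            faces.append([a, a + n + 1, a + 1])
    return TriSurface(verts, np.asarray(faces))


# ---------------------------------------------------------------------------
# thickness_map


def test_thickness_concentric_caps():
    sub = sphere_cap(10.0, 55.0)
    cart = sphere_cap(10.8, 55.0)
    tm = contact.thickness_map(sub, cart)
    assert np.all(np.abs(tm.values[tm.mask] - 0.8) < 1e-3)


def test_thickness_parallel_plates():
    tm = contact.thickness_map(_flat_grid(0.0), _flat_grid(1.2))
    assert np.allclose(tm.values[tm.mask], 1.2, atol=1e-9)


def test_thickness_matches_generator_field(shoulder):
    tm = contact.thickness_map(
        shoulder.surfaces["humerus"]["subchondral"], shoulder.surfaces["humerus"]["cartilage"]
    )
    truth = shoulder.thickness_truth["humerus"]
    rms = np.sqrt(np.mean((tm.values[tm.mask] - truth[tm.mask]) ** 2))
    assert rms < 0.02 * truth.mean()


def test_thickness_misaligned_surfaces_error():
    sub = sphere_cap(10.0, 55.0)
    far = sphere_cap(10.8, 55.0, center=(50.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="misaligned"):
        contact.thickness_map(sub, far)


# ---------------------------------------------------------------------------
# overlap_depth


def test_overlap_neutral_pose_zero(uniform_shoulder):
    solid = uniform_shoulder.cartilage_solid("humerus")
    gle = uniform_shoulder.surfaces["scapula"]["cartilage"]
    assert contact.overlap_depth(gle, solid).max() == 0.0


def test_overlap_max_at_pole_matches_delta(uniform_shoulder):
    solid = uniform_shoulder.cartilage_solid("humerus").transformed(
        np.eye(3), np.array([0.0, 0.0, 0.30])
    )
    gle = uniform_shoulder.surfaces["scapula"]["cartilage"]
    overlap = contact.overlap_depth(gle, solid)
    assert overlap.max() == pytest.approx(0.300, rel=0.02)


def test_overlap_profile_matches_analytic(uniform_shoulder):
    delta = 0.30
    a = 10.8  # conforming radius
    solid = uniform_shoulder.cartilage_solid("humerus").transformed(
        np.eye(3), np.array([0.0, 0.0, delta])
    )
    gle = uniform_shoulder.surfaces["scapula"]["cartilage"]
    overlap = contact.overlap_depth(gle, solid)
    dirs = gle.vertices / np.linalg.norm(gle.vertices, axis=1, keepdims=True)
    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
    expected = np.maximum(sphere_overlap_analytic(theta, a, delta), 0.0)
    # rim vertices leave the finite humeral cap under the translation, so
    # the full-sphere formula only applies in the cap interior
    sel = (expected > 0.05) & (theta < np.deg2rad(45.0))
    rms = np.sqrt(np.mean((overlap[sel] - expected[sel]) ** 2))
    assert rms < 0.03 * expected[sel].mean()


def test_overlap_open_mesh_error(uniform_shoulder):
    open_surface = uniform_shoulder.surfaces["humerus"]["cartilage"]
    gle = uniform_shoulder.surfaces["scapula"]["cartilage"]
    with pytest.raises(ValueError, match="open"):
        contact.overlap_depth(gle, open_surface)


# ---------------------------------------------------------------------------
# contact_strain


def test_strain_arithmetic():
    sm = contact.contact_strain(
        np.array([0.30]), np.array([0.8]), np.array([0.8]), threshold=0.25
    )
    assert sm.strain_pct[0] == pytest.approx(18.75)
    assert sm.contact_mask[0]


def test_uniform_overlap_below_threshold_no_contact():
    sm = contact.contact_strain(
        np.full(50, 0.20), np.full(50, 0.8), np.full(50, 0.8), threshold=0.25
    )
    assert not sm.contact_mask.any()
    assert np.all(sm.strain_pct == 0.0)


def test_zero_overlap_all_zero():
    sm = contact.contact_strain(np.zeros(10), np.ones(10), np.ones(10))
    assert np.all(sm.strain_pct == 0.0)
    assert not sm.contact_mask.any()


def test_zero_thickness_masked_with_warning():
    with pytest.warns(UserWarning, match="zero thickness"):
        sm = contact.contact_strain(
            np.array([0.3, 0.3]), np.array([0.8, 0.0]), np.array([0.8, 0.0])
        )
    assert sm.contact_mask.tolist() == [True, False]


def test_own_layer_denominator():
    sm = contact.contact_strain(
        np.array([0.30]), np.array([0.8]), np.array([0.8]), denominator="own-layer"
    )
    assert sm.strain_pct[0] == pytest.approx(37.5)


# ---------------------------------------------------------------------------
# cumulate / mean_cumulative_strain


def _fake_map(surface, mask, strain_value):
    strain = np.where(mask, strain_value, 0.0)
    overlap = np.where(mask, 0.3, 0.0)
    return contact.StrainMap(strain, overlap, mask.astype(bool))


def test_cumulate_single_frame_identity(uniform_shoulder):
    surf = uniform_shoulder.surfaces["scapula"]["cartilage"]
    mask = surf.vertices[:, 2] > 10.5
    cmap = contact.cumulate([_fake_map(surf, mask, 12.0)], surf)
    assert np.array_equal(cmap.contact_mask, mask)
    assert np.allclose(cmap.strain_pct, np.where(mask, 12.0, 0.0))


def test_cumulate_disjoint_patches_additive(uniform_shoulder):
    surf = uniform_shoulder.surfaces["scapula"]["cartilage"]
    m1 = surf.vertices[:, 0] > 4.0
    m2 = surf.vertices[:, 0] < -4.0
    c1 = contact.cumulate([_fake_map(surf, m1, 10.0)], surf)
    c2 = contact.cumulate([_fake_map(surf, m2, 10.0)], surf)
    both = contact.cumulate([_fake_map(surf, m1, 10.0), _fake_map(surf, m2, 10.0)], surf)
    assert both.contact_area_mm2 == pytest.approx(c1.contact_area_mm2 + c2.contact_area_mm2, rel=1e-9)


def test_cumulate_frame_order_invariant(uniform_shoulder):
    surf = uniform_shoulder.surfaces["scapula"]["cartilage"]
    rng = np.random.default_rng(2)
    frames = [
        _fake_map(surf, rng.random(surf.n_vertices) > 0.7, float(v)) for v in (5.0, 10.0, 15.0)
    ]
    a = contact.cumulate(frames, surf)
    b = contact.cumulate(frames[::-1], surf)
    assert np.array_equal(a.contact_mask, b.contact_mask)
    assert np.allclose(a.strain_pct, b.strain_pct)


def test_cumulate_empty_list_raises(uniform_shoulder):
    with pytest.raises(ValueError, match="empty"):
        contact.cumulate([], uniform_shoulder.surfaces["scapula"]["cartilage"])


def test_mean_strain_uniform(uniform_shoulder):
    surf = uniform_shoulder.surfaces["scapula"]["cartilage"]
    mask = surf.vertices[:, 2] > 10.5
    cmap = contact.cumulate([_fake_map(surf, mask, 10.0)], surf)
    assert contact.mean_cumulative_strain(cmap) == pytest.approx(10.0)


def test_mean_strain_two_patch_weighting(uniform_shoulder):
    surf = uniform_shoulder.surfaces["scapula"]["cartilage"]
    m1 = surf.vertices[:, 0] > 4.0
    m2 = surf.vertices[:, 0] < -4.0
    frames = [_fake_map(surf, m1, 10.0), _fake_map(surf, m2, 20.0)]
    cmap = contact.cumulate(frames, surf)
    va = surf.vertex_areas()
    expected = (10.0 * va[m1].sum() + 20.0 * va[m2].sum()) / (va[m1].sum() + va[m2].sum())
    assert contact.mean_cumulative_strain(cmap) == pytest.approx(expected, rel=1e-9)


def test_mean_strain_empty_mask_zero_with_warning(uniform_shoulder):
    surf = uniform_shoulder.surfaces["scapula"]["cartilage"]
    cmap = contact.cumulate([_fake_map(surf, np.zeros(surf.n_vertices, bool), 0.0)], surf)
    with pytest.warns(UserWarning, match="empty"):
        assert contact.mean_cumulative_strain(cmap) == 0.0


def test_mean_strain_matches_quadrature_oracle(uniform_shoulder):
    """DERIVED: area-weighted mean strain on conforming spheres vs a
    surface-integral (quadrature) oracle."""
    from scipy.integrate import quad

    delta, a, t_comb, thr = 0.35, 10.8, 1.6, 0.25
    sh = uniform_shoulder
    sm = contact.posed_frame_strain(
        sh.surfaces["scapula"]["cartilage"],
        sh.thickness_truth["scapula"],
        sh.surfaces["humerus"]["cartilage"],
        sh.thickness_truth["humerus"],
        sh.cartilage_solid("humerus"),
        RigidPose(np.eye(3), [0.0, 0.0, delta]),
        threshold=thr,
    )
    cmap = contact.cumulate([sm], sh.surfaces["scapula"]["cartilage"])
    measured = contact.mean_cumulative_strain(cmap)

    def ov(theta):
        return sphere_overlap_analytic(theta, a, delta)

    theta_max = None
    for th in np.linspace(0, np.pi / 2, 20001):
        if ov(th) <= thr:
            theta_max = th
            break
    num = quad(lambda th: 100.0 * ov(th) / t_comb * np.sin(th), 0, theta_max)[0]
    den = quad(lambda th: np.sin(th), 0, theta_max)[0]
    assert measured == pytest.approx(num / den, rel=0.01)


# ---------------------------------------------------------------------------
# properties


def test_overlap_monotone_in_approach(coarse_shoulder):
    sh = coarse_shoulder
    gle = sh.surfaces["scapula"]["cartilage"]
    solid0 = sh.cartilage_solid("humerus")
    prev_max, prev_mean, prev_area = -1.0, -1.0, -1.0
    for delta in (0.1, 0.2, 0.3, 0.45):
        sm = contact.posed_frame_strain(
            gle, sh.thickness_truth["scapula"], sh.surfaces["humerus"]["cartilage"],
            sh.thickness_truth["humerus"], solid0,
            RigidPose(np.eye(3), [0.0, 0.0, delta]),
        )
        cmap = contact.cumulate([sm], gle)
        assert sm.overlap_mm.max() >= prev_max
        assert contact.mean_cumulative_strain(cmap) >= prev_mean
        assert cmap.contact_area_mm2 >= prev_area
        prev_max = sm.overlap_mm.max()
        prev_mean = contact.mean_cumulative_strain(cmap)
        prev_area = cmap.contact_area_mm2


def test_contact_area_non_increasing_in_threshold(coarse_shoulder):
    sh = coarse_shoulder
    gle = sh.surfaces["scapula"]["cartilage"]
    solid = sh.cartilage_solid("humerus")
    overlap = contact.overlap_depth(
        gle, solid.transformed(np.eye(3), np.array([0.0, 0.0, 0.35])),
        check_watertight=False,
    )
    areas = []
    va = gle.vertex_areas()
    for thr in (0.1, 0.25, 0.3, 0.5):
        sm = contact.contact_strain(
            overlap, sh.thickness_truth["scapula"], sh.thickness_truth["humerus"], threshold=thr
        )
        areas.append(va[sm.contact_mask].sum())
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_strain_rigid_invariance(coarse_shoulder, rng):
    from scipy.spatial.transform import Rotation

    sh = coarse_shoulder
    gle = sh.surfaces["scapula"]["cartilage"]
    solid = sh.cartilage_solid("humerus").transformed(np.eye(3), np.array([0.0, 0.0, 0.3]))
    normals = gle.vertex_normals()
    o0 = contact.overlap_depth(gle, solid, normals, check_watertight=False)

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-30, 30, 3)
    gle_m = gle.transformed(R, t)
    o1 = contact.overlap_depth(gle_m, solid.transformed(R, t), normals @ R.T, check_watertight=False)
    assert np.abs(o0 - o1).max() < 1e-6


def test_adding_frames_never_shrinks(uniform_shoulder):
    surf = uniform_shoulder.surfaces["scapula"]["cartilage"]
    rng = np.random.default_rng(5)
    frames = [_fake_map(surf, rng.random(surf.n_vertices) > 0.8, float(5 + k)) for k in range(4)]
    prev = contact.cumulate(frames[:1], surf)
    for k in range(2, 5):
        cur = contact.cumulate(frames[:k], surf)
        assert np.all(cur.contact_mask >= prev.contact_mask)
        assert np.all(cur.strain_pct >= prev.strain_pct - 1e-12)
        prev = cur
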