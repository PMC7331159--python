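import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cartstrain import relaxometry as rx
from cartstrain.mesh import sphere_cap
from cartstrain.synthetic import EchoSpec, PAPER_ECHO_TIMES_MS, make_multiecho_volume

TE = np.array(PAPER_ECHO_TIMES_MS)


def grid_search_oracle(signals, te, tau_grid=None):
    """Brute-force 1-D grid search over T2* with S0 profiled out."""
    if tau_grid is None:
        tau_grid = np.arange(5.0, 100.0, 0.05)
    S = np.atleast_2d(signals)
    E = np.exp(-te[None, :] / tau_grid[:, None])  # (ntau, ne)
    num = S @ E.T  # (n, ntau)
    den = (E**2).sum(axis=1)  # (ntau,)
    score = num**2 / den
    best = np.argmax(score, axis=1)
    tau0 = tau_grid[best]
    # local refinement
    fine = np.linspace(-0.5, 0.5, 201)
    tau_local = tau0[:, None] + fine[None, :]
    out = np.empty(len(S))
    for i in range(len(S)):
        El = np.exp(-te[None, :] / tau_local[i][:, None])
        num_l = El @ S[i]
        sc = num_l**2 / (El**2).sum(axis=1)
        out[i] = tau_local[i][np.argmax(sc)]
    return out


# ---------------------------------------------------------------------------
# fit_t2star


@pytest.mark.parametrize("t2", [10.0, 25.0, 40.0, 60.0])
def test_noiseless_fit_exact(t2):
    s0, t2_hat, r2 = rx.fit_t2star(1000.0 * np.exp(-TE / t2), TE)
    assert t2_hat == pytest.approx(t2, abs=1e-6)
    assert s0 == pytest.approx(1000.0, rel=1e-6)
    assert r2 == pytest.approx(1.0, abs=1e-9)


def test_loglinear_mode_exact_noiseless():
    s0, t2_hat, _ = rx.fit_t2star(500.0 * np.exp(-TE / 30.0), TE, method="loglinear")
    assert t2_hat == pytest.approx(30.0, rel=1e-9)


def test_too_few_positive_echoes_raises():
    with pytest.raises(ValueError, match="fit_failed"):
        rx.fit_t2star(np.array([100.0, 50.0, 0.0, 0.0, 0.0]), TE)


def test_noisy_bias_sd_match_grid_oracle(rng):
    """DERIVED: nonlinear estimator vs brute-force grid search, 2000 reps."""
    n = 2000
    S = 1000.0 * np.exp(-TE / 30.0) + rng.normal(0, 20.0, size=(n, len(TE)))
    S = np.maximum(S, 0.0)
    s0, t2, r2, _ = rx.fit_signals(S, TE)
    oracle = grid_search_oracle(S, TE)
    assert abs(t2.mean() - oracle.mean()) < 0.1 * max(abs(oracle.mean() - 30.0), 0.05)
    assert t2.std() == pytest.approx(oracle.std(), rel=0.10)


@settings(max_examples=40, deadline=None)
@given(
    st.floats(min_value=5.0, max_value=100.0),
    st.floats(min_value=10.0, max_value=5000.0),
)
def test_fit_consistency_property(t2, s0):
    s0_hat, t2_hat, _ = rx.fit_t2star(s0 * np.exp(-TE / t2), TE)
    assert t2_hat == pytest.approx(t2, rel=1e-5)
    assert s0_hat == pytest.approx(s0, rel=1e-5)


def test_scale_equivariance():
    sig = 800.0 * np.exp(-TE / 22.0)
    s0a, t2a, _ = rx.fit_t2star(sig, TE)
    s0b, t2b, _ = rx.fit_t2star(3.7 * sig, TE)
    assert t2b == pytest.approx(t2a, rel=1e-9)
    assert s0b == pytest.approx(3.7 * s0a, rel=1e-9)


# ---------------------------------------------------------------------------
# map_volume


def _two_tissue_volume(uniform_shoulder, noise=0.0):
    spec = EchoSpec(
        voxel_size=(0.8, 0.8, 0.8),
        tissue_t2star={"cartilage": (25.0, 0.0), "fluid": (55.0, 0.0), "bone": (8.0, 0.0)},
        tissue_s0={"cartilage": 800.0, "fluid": 1000.0, "bone": 0.0},
        noise_sd=noise,
        seed=8,
    )
    return make_multiecho_volume(spec, uniform_shoulder)


def test_two_tissue_valid_mask_equals_cartilage(uniform_shoulder):
    vol, truth = _two_tissue_volume(uniform_shoulder)
    t2map = rx.map_volume(vol)
    cart = truth["labels"] == truth["label_codes"]["cartilage"]
    assert np.array_equal(t2map.valid, cart)
    assert np.allclose(t2map.t2star[cart], 25.0, atol=1e-6)
    fluid = truth["labels"] == truth["label_codes"]["fluid"]
    assert np.all(t2map.reason[fluid] == rx.REASON_CODES["cutoff_exceeded"])


def test_all_zero_volume_fit_failed():
    grid = np.zeros((4, 4, 4, 5))
    vol = rx.EchoVolume(grid, TE, np.eye(4))
    t2map = rx.map_volume(vol)
    assert np.all(t2map.reason == rx.REASON_CODES["fit_failed"])
    assert not t2map.valid.any()


def test_noisy_volume_mean_within_one_sd(uniform_shoulder):
    spec = EchoSpec(
        voxel_size=(0.8, 0.8, 0.8),
        tissue_t2star={"cartilage": (25.0, 2.0), "fluid": (55.0, 2.0), "bone": (8.0, 1.0)},
        noise_sd=8.0,
        seed=9,
    )
    vol, truth = make_multiecho_volume(spec, uniform_shoulder)
    t2map = rx.map_volume(vol)
    cart = truth["labels"] == truth["label_codes"]["cartilage"]
    mean_valid = t2map.t2star[t2map.valid & cart].mean()
    assert abs(mean_valid - 25.0) < 2.0


def test_lower_cutoff_never_adds_valid_voxels(uniform_shoulder):
    vol, _ = _two_tissue_volume(uniform_shoulder, noise=5.0)
    m50 = rx.map_volume(vol, cutoff_ms=50.0)
    m40 = rx.map_volume(vol, cutoff_ms=40.0)
    assert not np.any(m40.valid & ~m50.valid)


def test_echo_count_mismatch_rejected():
    with pytest.raises(ValueError, match="echo count"):
        rx.EchoVolume(np.zeros((3, 3, 3, 5)), np.array([1.0, 2.0, 3.0]), np.eye(4))


def test_negative_intensity_rejected():
    with pytest.raises(ValueError):
        rx.EchoVolume(-np.ones((3, 3, 3, 3)), np.array([1.0, 2.0, 3.0]), np.eye(4))


# ---------------------------------------------------------------------------
# project_to_surface


def _uniform_map(value=25.0, n=40, voxel=1.0):
    shape = (n, n, n)
    affine = np.eye(4)
    affine[:3, 3] = -n * voxel / 2.0
    return rx.T2StarMap(
        t2star=np.full(shape, value),
        s0=np.ones(shape),
        r2=np.ones(shape),
        valid=np.ones(shape, bool),
        reason=np.zeros(shape, np.uint8),
        cutoff_ms=50.0,
        affine=affine,
    )


def test_projection_uniform_field(uniform_shoulder):
    t2map = _uniform_map(25.0)
    vals, mask = rx.project_to_surface(
        t2map,
        uniform_shoulder.surfaces["humerus"]["cartilage"],
        uniform_shoulder.surfaces["humerus"]["subchondral"],
    )
    assert mask.all()
    assert np.allclose(vals, 25.0, atol=1e-9)


def test_projection_ignores_invalid_fluid_shell(uniform_shoulder):
    t2map = _uniform_map(25.0)
    # poison a shell beyond the cartilage surface with an invalid 55 ms region
    n = t2map.t2star.shape[0]
    idx = np.indices((n, n, n)).reshape(3, -1).T
    world = idx + t2map.affine[:3, 3]
    r = np.linalg.norm(world, axis=1).reshape(n, n, n)
    shell = r > 10.85
    t2map.t2star[shell] = 55.0
    t2map.valid[shell] = False
    vals, mask = rx.project_to_surface(
        t2map,
        uniform_shoulder.surfaces["humerus"]["cartilage"],
        uniform_shoulder.surfaces["humerus"]["subchondral"],
    )
    assert np.allclose(vals[mask], 25.0, atol=1e-9)


def test_projection_gradient_returns_midvalue(uniform_shoulder):
    """DERIVED: linear 20->30 ms through-thickness gradient projects to the
    mid value (line-integral oracle)."""
    t2map = _uniform_map(0.0)
    n = t2map.t2star.shape[0]
    idx = np.indices((n, n, n)).reshape(3, -1).T
    world = idx + t2map.affine[:3, 3]
    r = np.linalg.norm(world, axis=1).reshape(n, n, n)
    t2map.t2star[:] = 20.0 + 10.0 * np.clip((r - 10.0) / 0.8, -2, 3)
    vals, mask = rx.project_to_surface(
        t2map,
        uniform_shoulder.surfaces["humerus"]["cartilage"],
        uniform_shoulder.surfaces["humerus"]["subchondral"],
    )
    assert abs(np.nanmean(vals[mask]) - 25.0) < 1.0  # voxel-quantization tolerance


def test_projection_constant_across_mesh_resolution():
    t2map = _uniform_map(30.0)
    for n_polar, n_az in ((8, 16), (24, 48)):
        cart = sphere_cap(10.8, 55.0, n_polar=n_polar, n_azimuth=n_az)
        sub = sphere_cap(10.0, 55.0, n_polar=n_polar, n_azimuth=n_az)
        vals, mask = rx.project_to_surface(t2map, cart, sub)
        assert np.allclose(vals[mask], 30.0, atol=1e-9)


# ---------------------------------------------------------------------------
# t2star_thickness_sensitivity


def test_sensitivity_uniform_field_zero(uniform_shoulder):
    t2map = _uniform_map(25.0)
    s = rx.t2star_thickness_sensitivity(
        t2map,
        uniform_shoulder.surfaces["humerus"]["cartilage"],
        uniform_shoulder.surfaces["humerus"]["subchondral"],
        delta=0.125,
    )
    assert s == pytest.approx(0.0, abs=1e-9)


def test_sensitivity_zero_delta_is_zero(uniform_shoulder):
    t2map = _uniform_map(25.0)
    s = rx.t2star_thickness_sensitivity(
        t2map,
        uniform_shoulder.surfaces["humerus"]["cartilage"],
        uniform_shoulder.surfaces["humerus"]["subchondral"],
        delta=0.0,
    )
    assert s == 0.0


def test_sensitivity_gradient_first_order(uniform_shoulder):
    """DERIVED: gradient g, offset d -> sensitivity ~ |g| d / 2."""
    g, d = 12.5, 0.125  # ms/mm, mm
    t2map = _uniform_map(0.0)
    n = t2map.t2star.shape[0]
    idx = np.indices((n, n, n)).reshape(3, -1).T
    world = idx + t2map.affine[:3, 3]
    r = np.linalg.norm(world, axis=1).reshape(n, n, n)
    t2map.t2star[:] = 25.0 + g * (r - 10.4)  # gradient continues past the layer
    s = rx.t2star_thickness_sensitivity(
        t2map,
        uniform_shoulder.surfaces["humerus"]["cartilage"],
        uniform_shoulder.surfaces["humerus"]["subchondral"],
        delta=d,
    )
    assert s == pytest.approx(g * d / 2.0, rel=0.35)
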