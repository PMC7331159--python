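"""Synthetic ground-truth generators for every pipeline input.

An idealised conforming ball-and-socket joint (sphere caps with smooth
per-direction cartilage thickness fields), periodic 6-DOF gait with
cycle-to-cycle variability, multi-echo MR volumes with tissue-dependent
T2*, a two-block accuracy phantom, and linearly coupled regional
delta-strain / delta-T2* scenarios.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .kinematics import MarkerTriad, RigidPose
from .mesh import TriSurface, sphere_cap, cap_directions, stitch_cap_solid
from .relaxometry import EchoVolume

__all__ = [
    "ShoulderSpec",
    "GaitSpec",
    "EchoSpec",
    "CoupledScenarioSpec",
    "Shoulder",
    "Gait",
    "Phantom",
    "CoupledScenario",
    "make_shoulder",
    "make_gait",
    "make_multiecho_volume",
    "make_phantom",
    "make_coupled_scenario",
    "PAPER_ECHO_TIMES_MS",
]

PAPER_ECHO_TIMES_MS = (3.83, 9.37, 14.91, 20.46, 26.01)

# Fig-2b-like DOF amplitudes: (tx, ty, tz) mm, (rx, ry, rz) deg
DEFAULT_DOF_AMPLITUDES = (0.25, 0.25, 0.18, 4.0, 10.0, 3.0)


# ---------------------------------------------------------------------------
# specs


@dataclass
class ShoulderSpec:
    """Geometry of the idealised conforming ball-and-socket shoulder."""

    humeral_head_radius: float = 10.0  # mm
    glenoid_radius: float | None = None  # articular (inner) radius; None => conforming
    cartilage_thickness_mean: float = 0.819  # mm
    cartilage_thickness_sd: float = 0.086  # mm; 0 => uniform layer
    cap_half_angle: float = 55.0  # deg, humeral cartilage cap
    glenoid_cap_half_angle: float | None = None  # deg, defaults to cap_half_angle
    n_polar: int = 24
    n_azimuth: int = 48
    marker_offsets: dict | None = None  # side -> list of triad centers (body frame)
    seed: int = 0

    def __post_init__(self):
        if self.humeral_head_radius <= 0:
            raise ValueError("humeral_head_radius must be positive")
        if self.cartilage_thickness_mean <= 0:
            raise ValueError("cartilage thickness mean must be positive")
        if self.cartilage_thickness_sd < 0:
            raise ValueError("cartilage thickness sd must be >= 0")
        if self.glenoid_cap_half_angle is None:
            self.glenoid_cap_half_angle = self.cap_half_angle
        if not (0 < self.cap_half_angle < 90):
            raise ValueError("cap_half_angle must be in (0, 90) degrees")


@dataclass
class GaitSpec:
    """Periodic 6-DOF gait sampled at 120 frames/s."""

    n_cycles: int = 10
    frames_per_cycle: int = 120
    dof_amplitudes: tuple = DEFAULT_DOF_AMPLITUDES
    dof_offsets: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    cycle_noise_sd: tuple = (0.0,) * 6
    marker_noise_sd: float = 0.0  # mm, isotropic lab-frame Gaussian
    frame_rate: float = 120.0
    outlier_cycle: int | None = None  # inject an amplitude excursion into this cycle
    outlier_scale: float = 5.0
    abnormal_fraction: float = 0.0  # fraction of cycles with a heavy-tailed factor
    abnormal_scale: float = 9.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.frames_per_cycle < 4:
            raise ValueError("frames_per_cycle must be >= 4")
        if self.marker_noise_sd < 0 or any(s < 0 for s in self.cycle_noise_sd):
            raise ValueError("noise SDs must be >= 0")
        if len(self.dof_amplitudes) != 6 or len(self.cycle_noise_sd) != 6:
            raise ValueError("DOF vectors must have 6 components")


@dataclass
class EchoSpec:
    """Multi-echo acquisition model."""

    echo_times: tuple = PAPER_ECHO_TIMES_MS  # ms
    voxel_size: tuple = (0.5, 0.5, 0.5)  # mm
    tissue_t2star: dict = field(
        default_factory=lambda: {"cartilage": (25.0, 2.0), "fluid": (55.0, 2.0), "bone": (8.0, 1.0)}
    )
    tissue_s0: dict = field(
        default_factory=lambda: {"cartilage": 800.0, "fluid": 1000.0, "bone": 300.0}
    )
    noise_sd: float = 0.0  # signal units
    noise_model: str = "gaussian"  # or "rician"
    fluid_thickness: float = 1.5  # mm shell outside the cartilage band
    margin: float = 3.0  # mm padding around the joint
    seed: int = 0

    def __post_init__(self):
        te = np.asarray(self.echo_times, dtype=float)
        if te.size == 0:
            raise ValueError("echo_times must be nonempty")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing and positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class CoupledScenarioSpec:
    """Paired regional delta-strain / delta-T2* generator."""

    n_regions: int = 54
    delta_strain_range: tuple = (-4.0, 4.0)  # %
    coupling_slope: float = 1.0  # ms per % strain
    coupling_noise_sd: float = 0.0  # ms
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        if self.coupling_noise_sd < 0:
            raise ValueError("coupling_noise_sd must be >= 0")

    @property
    def population_r(self) -> float:
        """Analytic population Pearson correlation of the generated pairs."""
        lo, hi = self.delta_strain_range
        sx = (hi - lo) / np.sqrt(12.0)
        num = self.coupling_slope * sx
        return float(num / np.hypot(num, self.coupling_noise_sd))

    @classmethod
    def for_population_r(
        cls, r: float, n_regions: int = 54, slope: float = 1.0, seed: int = 0
    ) -> "CoupledScenarioSpec":
        """Choose the noise SD so that the population correlation equals ``r``."""
        if not 0 < abs(r) <= 1:
            raise ValueError("r must be in (0, 1]")
        lo, hi = (-4.0, 4.0)
        sx = (hi - lo) / np.sqrt(12.0)
        noise = abs(slope) * sx * np.sqrt(1.0 / r**2 - 1.0)
        return cls(
            n_regions=n_regions,
            delta_strain_range=(lo, hi),
            coupling_slope=slope if r > 0 else -abs(slope),
            coupling_noise_sd=float(noise),
            seed=seed,
        )


# ---------------------------------------------------------------------------
# shoulder


def _smooth_field(rng: np.random.Generator, n_waves: int = 5):
    """Smooth zero-ish random scalar field on the unit sphere."""
    axes = rng.normal(size=(n_waves, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    freqs = rng.uniform(1.5, 4.0, size=n_waves)
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    amps = rng.normal(size=n_waves)

    def f(dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        out = np.zeros(len(dirs))
        for a, fr, ph, am in zip(axes, freqs, phases, amps):
            out += am * np.sin(fr * (dirs @ a) * np.pi + ph)
        return out

    return f


def _thickness_fn(spec: ShoulderSpec, rng: np.random.Generator, ref_dirs: np.ndarray):
    """Strictly positive smooth thickness field standardised on ``ref_dirs``."""
    mean, sd = spec.cartilage_thickness_mean, spec.cartilage_thickness_sd
    if sd == 0:
        return lambda dirs: np.full(len(np.atleast_2d(dirs)), mean)
    raw = _smooth_field(rng)
    ref = raw(ref_dirs)
    mu, sigma = ref.mean(), ref.std()
    if sigma < 1e-12:
        return lambda dirs: np.full(len(np.atleast_2d(dirs)), mean)

    def t(dirs: np.ndarray) -> np.ndarray:
        return np.maximum(mean + sd * (raw(dirs) - mu) / sigma, 0.1 * mean)

    return t


def _default_marker_offsets() -> dict:
    # triad cluster centers in each bone's body frame (mm); head center at origin,
    # humeral shaft along -z, scapular body along +z
    return {
        "humerus": [(28.0, 6.0, -35.0), (22.0, -8.0, -70.0)],
        "scapula": [(-5.0, 26.0, 38.0), (8.0, 30.0, 72.0)],
    }


def _triad_at(center, rng: np.random.Generator, side_len: float = 20.0) -> MarkerTriad:
    """Equilateral marker triangle with a deterministic random orientation."""
    basis = Rotation.random(random_state=rng).as_matrix()
    r = side_len / np.sqrt(3.0)
    local = np.array(
        [
            [r, 0.0, 0.0],
            [-r / 2.0, r * np.sqrt(3) / 2.0, 0.0],
            [-r / 2.0, -r * np.sqrt(3) / 2.0, 0.0],
        ]
    )
    pts = np.asarray(center, dtype=float) + local @ basis.T
    return MarkerTriad(pts)


@dataclass
class Shoulder:
    """Generated joint model: six surfaces, thickness truth, marker triads.

    Both bones share one neutral frame: head and socket concentric at the
    origin, cap axes along +z.  ``clearance`` is the uniform radial gap of
    the glenoid articular surface over the conforming radius (0 by default).
    """

    spec: ShoulderSpec
    surfaces: dict  # side -> {"bone"|"subchondral"|"cartilage": TriSurface}
    thickness_truth: dict  # side -> per-vertex mm on the cap parameterization
    thickness_fn: dict  # side -> callable(dirs) -> mm
    triads: dict  # side -> [MarkerTriad, MarkerTriad]
    clearance: float

    @property
    def humeral_outer_radius_fn(self):
        R = self.spec.humeral_head_radius
        th = self.thickness_fn["humerus"]
        return lambda dirs: R + th(dirs)

    def marker_points(self, side: str) -> np.ndarray:
        """All marker body-frame points of one bone, stacked (6, 3)."""
        return np.vstack([t.body_frame_points for t in self.triads[side]])

    def cartilage_solid(self, side: str) -> TriSurface:
        """Watertight cartilage layer solid (outer + inner caps + rim wall)."""
        spec = self.spec
        if side == "humerus":
            outer = sphere_cap(
                self.humeral_outer_radius_fn, spec.cap_half_angle,
                n_polar=spec.n_polar, n_azimuth=spec.n_azimuth,
            )
            inner = sphere_cap(
                spec.humeral_head_radius, spec.cap_half_angle,
                n_polar=spec.n_polar, n_azimuth=spec.n_azimuth,
            )
        else:
            a_fn = self._glenoid_inner_radius_fn()
            tg = self.thickness_fn["scapula"]
            outer = sphere_cap(
                lambda d: a_fn(d) + tg(d), spec.glenoid_cap_half_angle,
                n_polar=spec.n_polar, n_azimuth=spec.n_azimuth,
            )
            inner = sphere_cap(
                a_fn, spec.glenoid_cap_half_angle,
                n_polar=spec.n_polar, n_azimuth=spec.n_azimuth,
            )
        return stitch_cap_solid(outer, inner, spec.n_polar, spec.n_azimuth)

    def _glenoid_inner_radius_fn(self):
        th = self.thickness_fn["humerus"]
        R = self.spec.humeral_head_radius
        c = self.clearance
        return lambda dirs: R + th(dirs) + c

    def mean_thickness(self) -> float:
        return float(np.mean(np.concatenate(list(self.thickness_truth.values()))))


def make_shoulder(spec: ShoulderSpec) -> Shoulder:
    """Build the six joint surfaces plus ground truth from a spec.

    The glenoid articular surface conforms pointwise to the humeral
    cartilage outer surface (plus a uniform non-negative clearance), so the
    neutral pose has zero interpenetration by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rng_hum = np.random.default_rng(rng.integers(2**63))
    rng_sca = np.random.default_rng(rng.integers(2**63))
    rng_markers = np.random.default_rng(rng.integers(2**63))

    hum_dirs = cap_directions(spec.cap_half_angle, spec.n_polar, spec.n_azimuth)
    gle_dirs = cap_directions(spec.glenoid_cap_half_angle, spec.n_polar, spec.n_azimuth)
    t_hum = _thickness_fn(spec, rng_hum, hum_dirs)
    t_gle = _thickness_fn(spec, rng_sca, gle_dirs)

    R = spec.humeral_head_radius
    conforming_mean = R + float(np.mean(t_hum(gle_dirs)))
    if spec.glenoid_radius is None:
        clearance = 0.0
    else:
        clearance = spec.glenoid_radius - conforming_mean
        if clearance < -1e-9:
            raise ValueError(
                "non-conforming spec: glenoid_radius "
                f"{spec.glenoid_radius:.4f} mm is smaller than the conforming "
                f"radius {conforming_mean:.4f} mm (negative clearance)"
            )
        clearance = max(clearance, 0.0)

    mk = dict(n_polar=spec.n_polar, n_azimuth=spec.n_azimuth)
    hum_sub = sphere_cap(R, spec.cap_half_angle, role="subchondral", **mk)
    hum_cart = sphere_cap(
        lambda d: R + t_hum(d), spec.cap_half_angle, role="cartilage", **mk
    )
    hum_bone = sphere_cap(0.999 * R, min(2 * spec.cap_half_angle, 150.0), role="bone", **mk)

    a_fn = lambda d: R + t_hum(d) + clearance
    gle_cart = sphere_cap(
        a_fn, spec.glenoid_cap_half_angle, concave=True, role="cartilage", **mk
    )
    gle_sub = sphere_cap(
        lambda d: a_fn(d) + t_gle(d), spec.glenoid_cap_half_angle,
        concave=True, role="subchondral", **mk,
    )
    gle_bone = sphere_cap(
        lambda d: a_fn(d) + t_gle(d) + 0.02 * R,
        min(spec.glenoid_cap_half_angle * 1.2, 85.0),
        concave=True, role="bone", **mk,
    )

    offsets = spec.marker_offsets or _default_marker_offsets()
    triads = {
        side: [_triad_at(c, rng_markers) for c in offsets[side]]
        for side in ("humerus", "scapula")
    }

    shoulder = Shoulder(
        spec=spec,
        surfaces={
            "humerus": {"bone": hum_bone, "subchondral": hum_sub, "cartilage": hum_cart},
            "scapula": {"bone": gle_bone, "subchondral": gle_sub, "cartilage": gle_cart},
        },
        thickness_truth={"humerus": t_hum(hum_dirs), "scapula": t_gle(gle_dirs)},
        thickness_fn={"humerus": t_hum, "scapula": t_gle},
        triads=triads,
        clearance=clearance,
    )
    return shoulder


# ---------------------------------------------------------------------------
# gait


@dataclass
class Gait:
    """Tracked marker frames plus full ground truth."""

    spec: GaitSpec
    times: np.ndarray  # (n_frames,) s
    marker_tracks: dict  # side -> (n_frames, n_markers, 3) lab mm
    truth_poses: dict  # side -> list[RigidPose]
    truth_dof: np.ndarray  # (n_frames, 6) humerus-in-glenoid
    cycle_starts: np.ndarray  # frame index of each cycle start

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _dof_trajectory(spec: GaitSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_cycles * spec.frames_per_cycle
    phase = np.arange(n) / spec.frames_per_cycle  # cycle phase, cycles at integers
    cycle_idx = np.minimum((phase).astype(int), spec.n_cycles - 1)
    amp = np.asarray(spec.dof_amplitudes, dtype=float)
    off = np.asarray(spec.dof_offsets, dtype=float)
    second_amp = rng.uniform(0.15, 0.35, size=6)
    # zero-phase harmonics: every DOF waveform vanishes at cycle starts, so
    # mean-crossing segmentation boundaries coincide with generator cycles
    second_phase = np.zeros(6)
    # Per-cycle DOF offsets with independent factors per DOF; a fixed
    # fraction of cycles is "abnormal" (heavy-tailed factors in every DOF
    # at once), which is what the mean +/- 1 SD filter is meant to remove.
    # Independence matters: a common factor would leave a mixed direction
    # with zero cycle-level variance after any anatomical-frame rotation.
    w = rng.normal(0.0, 1.0, size=(spec.n_cycles, 6))
    n_ab = int(round(spec.abnormal_fraction * spec.n_cycles))
    if n_ab > 0:
        idx = rng.choice(spec.n_cycles, size=n_ab, replace=False)
        w[idx, :] = np.sign(w[idx, :]) * spec.abnormal_scale * (0.5 + np.abs(w[idx, :]))
    cyc_pert = w * np.asarray(spec.cycle_noise_sd, dtype=float)
    # optional injected outlier: the whole cycle's waveform is scaled by
    # outlier_scale; scaling preserves the waveform zeros, so the boundary
    # crossings of neighbouring cycles are untouched
    amp_scale = np.ones(spec.n_cycles)
    if spec.outlier_cycle is not None:
        amp_scale[spec.outlier_cycle] = spec.outlier_scale
    vals = np.empty((n, 6))
    for k in range(6):
        base = np.sin(2 * np.pi * phase) + second_amp[k] * np.sin(
            4 * np.pi * phase + second_phase[k]
        )
        vals[:, k] = off[k] + amp[k] * amp_scale[cycle_idx] * base + cyc_pert[cycle_idx, k]
    return vals


def _scapula_poses(n: int, frame_rate: float) -> list[RigidPose]:
    """Slow global trunk motion: forward drift plus a gentle sway."""
    t = np.arange(n) / frame_rate
    poses = []
    for ti in t:
        ang = np.deg2rad(2.0 * np.sin(2 * np.pi * 0.5 * ti))
        Rz = Rotation.from_euler("z", ang).as_matrix()
        trans = np.array([250.0 * ti, 8.0 * np.sin(2 * np.pi * 0.7 * ti), 0.0])
        poses.append(RigidPose(Rz, trans, frame_index=len(poses)))
    return poses


def dof_to_pose(dof: np.ndarray, euler_seq: str = "ZYX") -> RigidPose:
    """Relative pose (humerus in glenoid frame) from a 6-DOF vector."""
    t = np.asarray(dof[:3], dtype=float)
    rx, ry, rz = dof[3], dof[4], dof[5]
    order = {"X": rx, "Y": ry, "Z": rz}
    ang = [order[c] for c in euler_seq]
    R = Rotation.from_euler(euler_seq, ang, degrees=True).as_matrix()
    return RigidPose(R, t)


def make_gait(spec: GaitSpec, shoulder: Shoulder) -> Gait:
    """Simulate tracked marker trajectories for one gait recording."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rng_traj = np.random.default_rng(rng.integers(2**63))
    rng_noise = np.random.default_rng(rng.integers(2**63))

    dof = _dof_trajectory(spec, rng_traj)
    n = len(dof)
    times = np.arange(n) / spec.frame_rate

    scap_poses = _scapula_poses(n, spec.frame_rate)
    hum_poses = [scap_poses[i].compose(dof_to_pose(dof[i])) for i in range(n)]
    hum_poses = [
        RigidPose(p.rotation, p.translation, frame_index=i) for i, p in enumerate(hum_poses)
    ]

    tracks = {}
    for side, poses in (("scapula", scap_poses), ("humerus", hum_poses)):
        body = shoulder.marker_points(side)
        lab = np.stack([p.apply(body) for p in poses])
        if spec.marker_noise_sd > 0:
            lab = lab + rng_noise.normal(0.0, spec.marker_noise_sd, size=lab.shape)
        tracks[side] = lab

    return Gait(
        spec=spec,
        times=times,
        marker_tracks=tracks,
        truth_poses={"scapula": scap_poses, "humerus": hum_poses},
        truth_dof=dof,
        cycle_starts=np.arange(spec.n_cycles) * spec.frames_per_cycle,
    )


# ---------------------------------------------------------------------------
# multi-echo volume


def make_multiecho_volume(
    spec: EchoSpec,
    shoulder: Shoulder,
    pose: RigidPose | None = None,
    t2star_offset_fn=None,
):
    """Simulate a multi-echo volume around the (optionally posed) joint.

    Voxels are labelled bone / cartilage / fluid / background from the
    analytic joint geometry; each tissue voxel draws T2* from its tissue
    distribution and decays mono-exponentially: S = S0 exp(-TE / T2*).
    ``t2star_offset_fn(points_mm) -> ms`` adds a spatial offset to
    cartilage voxels (used for coupled pre/post scenarios).

    Returns ``(EchoVolume, truth)`` where truth carries the label grid and
    the per-voxel ground-truth T2*.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    pose = pose or RigidPose.identity()
    sspec = shoulder.spec
    R = sspec.humeral_head_radius
    t_hum, t_gle = shoulder.thickness_fn["humerus"], shoulder.thickness_fn["scapula"]
    t_max = (
        shoulder.thickness_truth["humerus"].max()
        + shoulder.thickness_truth["scapula"].max()
        + shoulder.clearance
    )
    extent = R + t_max + spec.fluid_thickness + spec.margin
    vs = np.asarray(spec.voxel_size, dtype=float)
    n_vox = np.ceil(2 * extent / vs).astype(int)
    origin = -extent + 0.5 * vs
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = origin

    ii = [np.arange(n_vox[k]) * vs[k] + origin[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*ii, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    # humerus-frame coordinates
    inv = pose.inverse()
    pts_h = pts @ inv.rotation.T + inv.translation
    r_h = np.linalg.norm(pts_h, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u_h = pts_h / np.where(r_h[:, None] > 1e-12, r_h[:, None], 1.0)
    in_hum_cap = u_h[:, 2] >= np.cos(np.deg2rad(sspec.cap_half_angle))
    th = t_hum(u_h)

    r_g = np.linalg.norm(pts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u_g = pts / np.where(r_g[:, None] > 1e-12, r_g[:, None], 1.0)
    in_gle_cap = u_g[:, 2] >= np.cos(np.deg2rad(sspec.glenoid_cap_half_angle))
    a_g = R + t_hum(u_g) + shoulder.clearance
    tg = t_gle(u_g)

    labels = np.zeros(len(pts), dtype=np.uint8)  # 0 background
    BONE, CART, FLUID = 1, 2, 3
    labels[(r_h <= R) & in_hum_cap] = BONE
    hum_cart = in_hum_cap & (r_h > R) & (r_h <= R + th)
    gle_cart = in_gle_cap & (r_g > a_g) & (r_g <= a_g + tg)
    labels[hum_cart | gle_cart] = CART
    fluid = (
        in_gle_cap
        & (r_g > a_g + tg)
        & (r_g <= a_g + tg + spec.fluid_thickness)
        & ~(hum_cart | gle_cart)
    )
    labels[fluid] = FLUID

    t2 = np.zeros(len(pts))
    s0 = np.zeros(len(pts))
    for name, lab in (("bone", BONE), ("cartilage", CART), ("fluid", FLUID)):
        m = labels == lab
        mu, sd = spec.tissue_t2star.get(name, (10.0, 0.0))
        t2[m] = np.maximum(rng.normal(mu, sd, size=int(m.sum())), 1.0) if sd > 0 else mu
        s0[m] = spec.tissue_s0.get(name, 500.0)
    if t2star_offset_fn is not None:
        m = labels == CART
        t2[m] = np.maximum(t2[m] + t2star_offset_fn(pts[m]), 1.0)

    te = np.asarray(spec.echo_times, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-te[None, :] / np.where(t2[:, None] > 0, t2[:, None], np.inf))
    signal = s0[:, None] * decay
    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
        else:  # rician magnitude
            n1 = rng.normal(0.0, spec.noise_sd, size=signal.shape)
            n2 = rng.normal(0.0, spec.noise_sd, size=signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
    signal = np.maximum(signal, 0.0)

    grid = signal.reshape(*n_vox, len(te))
    volume = EchoVolume(grid, echo_times=te, affine=affine, voxel_size=tuple(vs))
    truth = {
        "labels": labels.reshape(tuple(n_vox)),
        "t2star": t2.reshape(tuple(n_vox)),
        "label_codes": {"background": 0, "bone": BONE, "cartilage": CART, "fluid": FLUID},
    }
    return volume, truth


# ---------------------------------------------------------------------------
# phantom


@dataclass
class Phantom:
    """Two-block phantom with tracked frames and constant ground truth."""

    angle_deg: float
    ball_gap: float
    blocks: list  # per block: dict(markers_body, ball_center_body, axis_body, triads)
    frames: np.ndarray  # (n_frames, 12, 3) tracked marker coords
    truth_center_distance: float
    truth_block_angle: float
    noise_sd: float


def make_phantom(
    angle: float,
    ball_gap: float = 100.0,
    noise_sd: float = 0.0,
    n_frames: int = 100,
    seed: int = 0,
) -> Phantom:
    """Two rigid blocks at a relative angle, moved rigidly as one assembly.

    Each block carries two marker triads and one ball; ground truth is the
    ball-center distance (= ``ball_gap``) and the angle between block axes.
    """
    if angle not in (0.0, 30.0, 60.0):
        warnings.warn(f"phantom angle {angle} deg outside the standard set {{0, 30, 60}}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rng_layout = np.random.default_rng(rng.integers(2**63))
    rng_motion = np.random.default_rng(rng.integers(2**63))
    rng_noise = np.random.default_rng(rng.integers(2**63))

    axis_a = np.array([1.0, 0.0, 0.0])
    rot_b = Rotation.from_euler("z", angle, degrees=True).as_matrix()
    axis_b = rot_b @ axis_a
    ball_a = np.zeros(3)
    ball_b = np.array([ball_gap, 0.0, 0.0])

    def block(ball, axis):
        perp = np.array([0.0, 1.0, 0.0]) if abs(axis[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
        perp = perp - (perp @ axis) * axis
        perp /= np.linalg.norm(perp)
        centers = [ball - 60.0 * axis + 12.0 * perp, ball - 120.0 * axis - 12.0 * perp]
        triads = [_triad_at(c, rng_layout) for c in centers]
        return {
            "triads": triads,
            "markers_body": np.vstack([t.body_frame_points for t in triads]),
            "ball_center_body": ball,
            "axis_body": axis / np.linalg.norm(axis),
        }

    blocks = [block(ball_a, axis_a), block(ball_b, axis_b)]
    all_body = np.vstack([b["markers_body"] for b in blocks])

    frames = np.empty((n_frames, len(all_body), 3))
    for i in range(n_frames):
        Rm = Rotation.random(random_state=rng_motion).as_matrix()
        t = rng_motion.uniform(-300.0, 300.0, size=3)
        frames[i] = all_body @ Rm.T + t
    if noise_sd > 0:
        frames = frames + rng_noise.normal(0.0, noise_sd, size=frames.shape)

    return Phantom(
        angle_deg=float(angle),
        ball_gap=float(ball_gap),
        blocks=blocks,
        frames=frames,
        truth_center_distance=float(ball_gap),
        truth_block_angle=float(angle),
        noise_sd=float(noise_sd),
    )


# ---------------------------------------------------------------------------
# coupled regional scenario


@dataclass
class CoupledScenario:
    delta_strain: np.ndarray  # %
    delta_t2star: np.ndarray  # ms
    slope: float
    population_r: float
    sample_r: float


def make_coupled_scenario(spec: CoupledScenarioSpec) -> CoupledScenario:
    """Draw paired regional (delta strain, delta T2*) with a linear coupling."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    lo, hi = spec.delta_strain_range
    x = rng.uniform(lo, hi, size=spec.n_regions)
    eps = (
        rng.normal(0.0, spec.coupling_noise_sd, size=spec.n_regions)
        if spec.coupling_noise_sd > 0
        else np.zeros(spec.n_regions)
    )
    y = spec.coupling_slope * x + eps
    sx, sy = x.std(), y.std()
    if sx > 0 and sy > 0:
        sample_r = float(np.corrcoef(x, y)[0, 1])
    else:
        sample_r = np.nan
    pop_r = spec.population_r
    return CoupledScenario(
        delta_strain=x,
        delta_t2star=y,
        slope=spec.coupling_slope,
        population_r=pop_r,
        sample_r=sample_r,
    )
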