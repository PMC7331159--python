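"""Rigid-body kinematics from marker triads.

Pose estimation (least-squares rigid fit), surface registration, iterative
closest point alignment of subchondral profiles, 6-DOF decomposition of the
ball-in-socket motion, gait-cycle segmentation, and the mean +/- 1 SD
outlier-rejection rule used to build a representative cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .mesh import TriSurface, fit_sphere

__all__ = [
    "MarkerTriad",
    "RigidPose",
    "DofTrace",
    "GaitCycleSet",
    "AnatomicalFrame",
    "DegenerateConfigurationError",
    "estimate_rigid_pose",
    "register_model_to_frame",
    "align_by_subchondral",
    "anatomical_frame_from_cap",
    "relative_dof",
    "segment_cycles",
    "reject_outlier_cycles",
]

DOF_NAMES = ("tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg")


class DegenerateConfigurationError(ValueError):
    """Raised when marker geometry cannot constrain a rigid pose."""


@dataclass
class MarkerTriad:
    """A rigid cluster of reflective markers expressed in the body frame."""

    body_frame_points: np.ndarray  # (k, 3) mm, k >= 3
    labels: tuple = ()

    def __post_init__(self):
        self.body_frame_points = np.asarray(self.body_frame_points, dtype=np.float64)
        p = self.body_frame_points
        if p.shape[0] < 3:
            raise DegenerateConfigurationError("triad needs at least 3 markers")
        if _max_triangle_area(p) < 1e-9:
            raise DegenerateConfigurationError("markers are collinear or duplicated")
        if not self.labels:
            self.labels = tuple(f"m{i}" for i in range(p.shape[0]))


def _max_triangle_area(p: np.ndarray) -> float:
    n = len(p)
    best = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a = 0.5 * np.linalg.norm(np.cross(p[j] - p[i], p[k] - p[i]))
                best = max(best, a)
    return best


@dataclass
class RigidPose:
    """Proper rigid map x_lab = R x_body + t."""

    rotation: np.ndarray
    translation: np.ndarray
    frame_index: int = -1
    residual_rms: float = 0.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        err_orth = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err_orth > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is a reflection")

    @classmethod
    def identity(cls, frame_index: int = -1) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3), frame_index=frame_index)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            frame_index=self.frame_index,
        )

    def inverse(self) -> "RigidPose":
        rt = self.rotation.T
        return RigidPose(rt, -rt @ self.translation, frame_index=self.frame_index)


@dataclass
class DofTrace:
    """Per-frame 6-DOF trajectory (tx, ty, tz mm; rx, ry, rz deg)."""

    values: np.ndarray  # (n_frames, 6)
    frame_rate: float = 120.0
    gimbal_flags: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("DofTrace values must be (n, 6)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DofTrace must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GaitCycleSet:
    """Resampled cycles plus the retained subset and their mean cycle."""

    cycles: np.ndarray  # (n_cycles, n_samples, 6)
    retained_mask: np.ndarray
    representative: np.ndarray  # (n_samples, 6)
    band_mean: np.ndarray  # (n_samples, 6) over ALL cycles
    band_sd: np.ndarray

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())


# ---------------------------------------------------------------------------
# pose estimation


def estimate_rigid_pose(
    triad: MarkerTriad, observed: np.ndarray, frame_index: int = -1
) -> RigidPose:
    """Least-squares rigid fit of the triad to observed lab coordinates.

    Kabsch/umeyama solution via SVD of the cross-covariance; reflection
    branches are rejected by construction.
    """
    body = triad.body_frame_points
    obs = np.asarray(observed, dtype=np.float64)
    if obs.shape != body.shape:
        raise ValueError("observed shape mismatch with triad")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed coordinates must be finite")
    if _max_triangle_area(obs) < 1e-9:
        raise DegenerateConfigurationError("observed markers are collinear or duplicated")

    bc = body - body.mean(axis=0)
    oc = obs - obs.mean(axis=0)
    H = bc.T @ oc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = obs.mean(axis=0) - R @ body.mean(axis=0)
    resid = obs - (body @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidPose(R, t, frame_index=frame_index, residual_rms=rms)


def register_model_to_frame(surfaces, pose: RigidPose):
    """Transform model surfaces into the lab frame of one tracked frame.

    ``surfaces`` may be one :class:`TriSurface` or an iterable/dict of them.
    """
    if isinstance(surfaces, TriSurface):
        return surfaces.transformed(pose.rotation, pose.translation)
    if isinstance(surfaces, dict):
        return {k: register_model_to_frame(s, pose) for k, s in surfaces.items()}
    return [register_model_to_frame(s, pose) for s in surfaces]


class IcpConvergenceError(RuntimeError):
    def __init__(self, msg: str, last_rms: float):
        super().__init__(msg)
        self.last_rms = last_rms


def align_by_subchondral(
    profile_a: TriSurface,
    profile_b: TriSurface,
    init: RigidPose | None = None,
    max_iter: int = 600,
    tol: float = 1e-7,
) -> RigidPose:
    """Best-fit rigid alignment of profile_a onto profile_b.

    Iterative closest point with point-to-surface correspondences (nearest
    point on b's triangles, not nearest vertex, which avoids lattice local
    minima on structured meshes).  Returns the pose mapping a onto b;
    attributes ``converged`` and ``final_rms`` are attached to the pose.
    """
    from .mesh import closest_surface_points

    pose = init if init is not None else RigidPose.identity()
    src0 = profile_a.vertices
    prev_rms = np.inf
    converged = False
    rms = np.inf
    for _ in range(max_iter):
        src = pose.apply(src0)
        tgt, dist = closest_surface_points(profile_b, src)
        rms = float(np.sqrt(np.mean(dist**2)))
        pose_new = _fit_points(src0, tgt)
        # absolute floor for exact overlaps, relative floor for the plateau
        # set by mesh-resolution mismatch
        if abs(prev_rms - rms) < max(tol, 1e-4 * rms):
            pose = pose_new
            converged = True
            break
        prev_rms = rms
        pose = pose_new
    if not converged:
        raise IcpConvergenceError(f"ICP did not converge; last RMS {rms:.4g} mm", rms)
    pose.residual_rms = rms
    pose.converged = converged
    pose.final_rms = rms
    return pose


def _fit_points(src: np.ndarray, dst: np.ndarray) -> RigidPose:
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dc - R @ sc
    return RigidPose(R, t)


# ---------------------------------------------------------------------------
# anatomical frames and 6-DOF decomposition


@dataclass
class AnatomicalFrame:
    """Center + right-handed axes (columns of ``axes``) in the body frame."""

    center: np.ndarray
    axes: np.ndarray  # 3x3, columns = x, y, z

    def as_pose(self) -> RigidPose:
        return RigidPose(self.axes, self.center)


def anatomical_frame_from_cap(surface: TriSurface, reference_axes: np.ndarray | None = None) -> AnatomicalFrame:
    """Frame from a least-squares sphere fit to a (sub)spherical cap.

    Center = fitted sphere center; z = mean radial direction of the cap
    (pole axis); x, y = principal directions of the vertex cloud in the
    plane normal to z.  Signs are fixed deterministically (and optionally
    matched against ``reference_axes`` for session-to-session stability).
    """
    center, _, _ = fit_sphere(surface.vertices)
    radial = surface.vertices - center
    z = radial.mean(axis=0)
    z = z / np.linalg.norm(z)
    proj = radial - np.outer(radial @ z, z)
    cov = proj.T @ proj
    w, v = np.linalg.eigh(cov)
    x = v[:, np.argmax(w)]
    x = x - (x @ z) * z
    x = x / np.linalg.norm(x)
    # deterministic sign: largest-magnitude lab component positive
    if x[np.argmax(np.abs(x))] < 0:
        x = -x
    y = np.cross(z, x)
    axes = np.column_stack([x, y, z])
    if reference_axes is not None:
        # pick the in-plane flip that best matches the reference
        alt = np.column_stack([-x, -y, z])
        if np.trace(reference_axes.T @ alt) > np.trace(reference_axes.T @ axes):
            axes = alt
    return AnatomicalFrame(center, axes)


def relative_dof(
    scapula_pose: RigidPose,
    humerus_pose: RigidPose,
    glenoid_frame: AnatomicalFrame,
    head_frame: AnatomicalFrame,
    euler_seq: str = "ZYX",
) -> np.ndarray:
    """6-DOF of the humeral-head frame relative to the glenoid frame.

    Translations are the head center expressed in the glenoid frame (mm);
    rotations are intrinsic Euler angles of the relative rotation (deg),
    wrapped to (-180, 180].  A gimbal-proximity warning is issued when the
    middle angle is within 1 degree of +/-90.
    """
    lab_glenoid = scapula_pose.compose(glenoid_frame.as_pose())
    lab_head = humerus_pose.compose(head_frame.as_pose())
    rel = lab_glenoid.inverse().compose(lab_head)
    ang = Rotation.from_matrix(rel.rotation).as_euler(euler_seq, degrees=True)
    # scipy returns (first, middle, last) for the intrinsic sequence;
    # report as (rx, ry, rz) matching the axis names
    axis_order = [euler_seq.index(c) for c in "XYZ"]
    rot = np.array([ang[i] for i in axis_order])
    rot = np.where(rot <= -180.0, rot + 360.0, rot)
    rot = np.where(rot > 180.0, rot - 360.0, rot)
    if abs(abs(ang[1]) - 90.0) < 1.0:
        warnings.warn("gimbal proximity: middle Euler angle within 1 deg of +/-90", stacklevel=2)
    return np.concatenate([rel.translation, rot])


# ---------------------------------------------------------------------------
# gait cycles


def _lowpass(x: np.ndarray, frame_rate: float, cutoff_hz: float = 6.0) -> np.ndarray:
    nyq = 0.5 * frame_rate
    if cutoff_hz >= nyq:
        return x
    b, a = butter(2, cutoff_hz / nyq)
    # wrap-pad: gait traces are near-periodic, so this suppresses the
    # filtfilt edge transient that otherwise shifts boundary crossings
    p = min(len(x) // 4, 200)
    if p > 12:
        xp = np.concatenate([x[-p:], x, x[:p]])
        return filtfilt(b, a, xp)[p:-p]
    return filtfilt(b, a, x, padlen=min(12, len(x) - 1))


def segment_cycles(
    trace: DofTrace,
    reference_dof: int | str = "auto",
    n_samples: int = 101,
    lowpass_hz: float = 6.0,
):
    """Split a DOF trace into gait cycles and resample each to ``n_samples``.

    Boundaries are successive positive-going crossings of the mean level of
    the reference DOF (the one with the largest peak-to-peak amplitude when
    ``"auto"``) after low-pass smoothing.  Returns ``(cycles, boundaries)``
    where cycles is (n_cycles, n_samples, 6).
    """
    vals = trace.values
    if reference_dof == "auto":
        ref = int(np.argmax(vals.max(axis=0) - vals.min(axis=0)))
    else:
        ref = int(reference_dof)
    x = _lowpass(vals[:, ref], trace.frame_rate, lowpass_hz)
    if np.ptp(x) < 1e-12:
        raise ValueError("reference DOF is constant; no cycles detectable")
    level = x.mean()
    above = x > level
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    if len(crossings) < 3:
        raise ValueError("fewer than 2 full cycles detected")
    # refine against the raw trace: the low-pass transient near amplitude
    # changes can shift a smoothed crossing by a few frames
    # regularise to the median inter-crossing period: per-cycle level
    # offsets shift individual crossings by a few frames, and even small
    # boundary jitter misaligns the resampled cycles enough to corrupt the
    # outlier band, so crossings are snapped to a robust periodic grid
    p0 = float(np.median(np.diff(crossings)))
    if p0 < 4:
        raise ValueError("detected period too short")
    span = float(crossings[-1] - crossings[0])
    period = span / max(1, round(span / p0))
    ks = np.round((crossings - crossings[0]) / period)
    # Theil-Sen period: median of pairwise slopes is immune to the few
    # crossings displaced by abnormal cycles
    slopes = [
        (crossings[j] - crossings[i]) / (ks[j] - ks[i])
        for i in range(len(ks))
        for j in range(i + 1, len(ks))
        if ks[j] != ks[i]
    ]
    period = float(np.median(slopes)) if slopes else period
    start = float(np.median(crossings - ks * period))
    # extend the grid across the whole trace so edge cycles are kept;
    # boundaries stay fractional so resampling carries no rounding jitter
    k_lo = int(np.floor((0 - start) / period))
    k_hi = int(np.ceil((len(x) - 1 - start) / period))
    grid = np.asarray(
        sorted(
            start + k * period
            for k in range(k_lo, k_hi + 1)
            if 0.0 <= start + k * period <= len(x) - 1
        )
    )
    if len(grid) < 3:
        raise ValueError("fewer than 2 full cycles detected")
    frame_axis = np.arange(len(vals), dtype=np.float64)
    cycles = []
    bounds = []
    for s, e in zip(grid[:-1], grid[1:]):
        if e - s < 4:
            continue
        to = np.linspace(s, e, n_samples)
        cycles.append(
            np.column_stack([np.interp(to, frame_axis, vals[:, k]) for k in range(6)])
        )
        bounds.append((float(s), float(e)))
    if len(cycles) < 2:
        raise ValueError("fewer than 2 full cycles detected")
    return np.asarray(cycles), bounds


def reject_outlier_cycles(cycles: np.ndarray, band_tolerance: float = 0.05) -> GaitCycleSet:
    """Drop cycles leaving the pointwise mean +/- 1 SD band of any DOF.

    The band is computed once over all cycles (single pass).  A cycle is
    removed when, for at least one DOF, the fraction of its samples strictly
    outside that DOF's band exceeds ``band_tolerance``.  Remaining cycles
    are averaged pointwise into the representative cycle.
    """
    cycles = np.asarray(cycles, dtype=np.float64)
    if cycles.ndim != 3 or cycles.shape[2] != 6:
        raise ValueError("cycles must be (n_cycles, n_samples, 6)")
    if cycles.shape[0] < 3:
        raise ValueError("need at least 3 cycles for the outlier band")
    mean = cycles.mean(axis=0)
    sd = cycles.std(axis=0, ddof=0)
    lo, hi = mean - sd, mean + sd
    tol = 1e-12
    outside = (cycles < lo - tol) | (cycles > hi + tol)  # (c, s, 6)
    frac = outside.mean(axis=1)  # (c, 6) per-DOF fraction of samples outside
    retained = ~(frac > band_tolerance).any(axis=1)
    if not retained.any():
        raise ValueError("all cycles rejected; increase band_tolerance")
    representative = cycles[retained].mean(axis=0)
    return GaitCycleSet(
        cycles=cycles,
        retained_mask=retained,
        representative=representative,
        band_mean=mean,
        band_sd=sd,
    )
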