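"""Run configuration: every tunable in one validated, serialisable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Defaults follow the study protocol where it states a value
    (0.25 mm contact threshold, 50 ms T2* cutoff, 20 deg regions,
    mean +/- 1 SD cycle band)."""

    seed: int = 0

    # geometry / simulation scale
    humeral_head_radius_mm: float = 10.0
    cartilage_thickness_mean_mm: float = 0.819
    cartilage_thickness_sd_mm: float = 0.086
    cap_half_angle_deg: float = 55.0
    mesh_n_polar: int = 20
    mesh_n_azimuth: int = 40

    # gait
    n_cycles: int = 8
    frames_per_cycle: int = 60
    frame_rate_hz: float = 120.0
    marker_noise_sd_mm: float = 0.025
    cycle_noise_sd: tuple = (0.18, 0.18, 0.14, 0.5, 0.45, 0.4)
    gait_abnormal_fraction: float = 0.15
    dof_offsets_pre: tuple = (0.0, 0.0, 0.22, 0.0, 0.0, 0.0)
    dof_offsets_post: tuple = (0.15, 0.0, 0.16, 0.0, 0.0, 0.0)

    # kinematics
    euler_seq: str = "ZYX"
    band_tolerance: float = 0.05
    reference_dof: str = "auto"
    cycle_samples: int = 101

    # contact
    contact_threshold_mm: float = 0.25
    strain_denominator: str = "combined"
    cumulative_mode: str = "max"
    strain_frame_stride: int = 10

    # relaxometry
    t2star_cutoff_ms: float = 50.0
    fit_method: str = "nonlinear"
    r2_gate: float = 0.7
    voxel_size_mm: float = 0.8
    signal_noise_sd: float = 4.0
    cartilage_t2star_ms: tuple = (25.0, 0.8)
    fluid_t2star_ms: tuple = (55.0, 2.0)

    # regions / coupling
    region_span_deg: float = 20.0
    coupling_slope_ms_per_pct: float = 0.8

    # phantom
    phantom_angle_deg: float = 30.0
    phantom_frames: int = 200
    phantom_noise_sd_mm: float = 0.05
    precision_statistic: str = "1sd"
    propagation_samples: int = 12

    def __post_init__(self):
        if self.contact_threshold_mm < 0:
            raise ValueError("contact_threshold_mm must be >= 0")
        if self.t2star_cutoff_ms <= 0:
            raise ValueError("t2star_cutoff_ms must be positive")
        if not 0 < self.region_span_deg <= 180:
            raise ValueError("region_span_deg must be in (0, 180]")
        if not 0 <= self.band_tolerance <= 1:
            raise ValueError("band_tolerance must be in [0, 1]")
        if self.strain_denominator not in ("combined", "own-layer"):
            raise ValueError("strain_denominator must be 'combined' or 'own-layer'")
        if self.cumulative_mode not in ("max", "mean"):
            raise ValueError("cumulative_mode must be 'max' or 'mean'")
        if self.fit_method not in ("nonlinear", "loglinear"):
            raise ValueError("fit_method must be 'nonlinear' or 'loglinear'")
        if sorted(self.euler_seq) != ["X", "Y", "Z"]:
            raise ValueError("euler_seq must be a permutation of XYZ (intrinsic)")
        if self.strain_frame_stride < 1:
            raise ValueError("strain_frame_stride must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(cls.__dataclass_fields__[k].default, tuple) else v
            for k, v in d.items()
        }
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
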