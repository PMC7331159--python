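"""End-to-end study orchestration on synthetic inputs.

``run_study`` executes simulate -> track -> strain -> t2star -> regions ->
correlate -> phantom in dependency order for a pre and a post session,
writes every intermediate product as plain files, and emits a summary
report (per-session mean cumulative strain / T2*, per-region deltas, and
the pooled Pearson correlation).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import contact, io, kinematics, mesh, regional, relaxometry
from .config import RunConfig
from .phantom import bias_precision, measure_phantom, propagate_to_strain
from .synthetic import (
    EchoSpec,
    GaitSpec,
    ShoulderSpec,
    dof_to_pose,
    make_gait,
    make_multiecho_volume,
    make_phantom,
    make_shoulder,
)

log = logging.getLogger("cartstrain")

__all__ = ["run_study", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _seed_fan(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def _track_session(gait, shoulder, cfg: RunConfig):
    """Marker tracks -> poses -> relative DOF -> representative cycle."""
    triads = {s: kinematics.MarkerTriad(shoulder.marker_points(s)) for s in ("scapula", "humerus")}
    gle_frame = kinematics.anatomical_frame_from_cap(shoulder.surfaces["scapula"]["subchondral"])
    head_frame = kinematics.anatomical_frame_from_cap(shoulder.surfaces["humerus"]["subchondral"])
    n = gait.n_frames
    dof = np.empty((n, 6))
    for i in range(n):
        sp = kinematics.estimate_rigid_pose(triads["scapula"], gait.marker_tracks["scapula"][i], i)
        hp = kinematics.estimate_rigid_pose(triads["humerus"], gait.marker_tracks["humerus"][i], i)
        dof[i] = kinematics.relative_dof(sp, hp, gle_frame, head_frame, cfg.euler_seq)
    trace = kinematics.DofTrace(dof, frame_rate=cfg.frame_rate_hz)
    cycles, _ = kinematics.segment_cycles(
        trace, reference_dof=cfg.reference_dof, n_samples=cfg.cycle_samples
    )
    cycle_set = kinematics.reject_outlier_cycles(cycles, band_tolerance=cfg.band_tolerance)
    return trace, cycle_set, gle_frame, head_frame


def _session_strain(cycle_set, shoulder, cfg: RunConfig, geom):
    """Cumulative strain map over the representative cycle (frame stride applied)."""
    rep = cycle_set.representative
    frames = []
    for i in range(0, len(rep), cfg.strain_frame_stride):
        pose = dof_to_pose(rep[i], cfg.euler_seq)
        frames.append(
            contact.posed_frame_strain(
                geom["gle_cart"], geom["gle_thick"], geom["hum_cart"], geom["hum_thick"],
                geom["hum_solid"], pose,
                threshold=cfg.contact_threshold_mm,
                denominator=cfg.strain_denominator,
                normals=geom["normals"],
                frame_index=i,
            )
        )
    return contact.cumulate(frames, geom["gle_cart"], mode=cfg.cumulative_mode)


def run_study(config: RunConfig, out_dir) -> dict:
    """Run the full synthetic study; returns the summary report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = _seed_fan(config.seed, 8)
    report: dict = {"seed": config.seed}

    # ---- simulate: joint model ------------------------------------------
    stage = "simulate-shoulder"
    try:
        shoulder = make_shoulder(
            ShoulderSpec(
                humeral_head_radius=config.humeral_head_radius_mm,
                cartilage_thickness_mean=config.cartilage_thickness_mean_mm,
                cartilage_thickness_sd=config.cartilage_thickness_sd_mm,
                cap_half_angle=config.cap_half_angle_deg,
                n_polar=config.mesh_n_polar,
                n_azimuth=config.mesh_n_azimuth,
                seed=seeds[0],
            )
        )
        model_dir = out / "model"
        model_dir.mkdir(exist_ok=True)
        for side, surfs in shoulder.surfaces.items():
            for role, surf in surfs.items():
                mesh.write_ply(model_dir / f"{side}_{role}.ply", surf)
        io.write_json(
            model_dir / "ground_truth.json",
            {
                "mean_thickness_mm": shoulder.mean_thickness(),
                "clearance_mm": shoulder.clearance,
            },
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # measured (not ground-truth) thickness maps feed the strain denominator
    stage = "thickness"
    try:
        tm_gle = contact.thickness_map(
            shoulder.surfaces["scapula"]["subchondral"],
            shoulder.surfaces["scapula"]["cartilage"],
            side="scapular",
        )
        tm_hum = contact.thickness_map(
            shoulder.surfaces["humerus"]["subchondral"],
            shoulder.surfaces["humerus"]["cartilage"],
            side="humeral",
        )
        geom = {
            "gle_cart": shoulder.surfaces["scapula"]["cartilage"],
            "gle_thick": np.where(tm_gle.cartilage_mask, tm_gle.on_cartilage, 0.0),
            "hum_cart": shoulder.surfaces["humerus"]["cartilage"],
            "hum_thick": np.where(tm_hum.cartilage_mask, tm_hum.on_cartilage, 0.0),
            "hum_solid": shoulder.cartilage_solid("humerus"),
            "normals": shoulder.surfaces["scapula"]["cartilage"].vertex_normals(),
        }
        report["mean_thickness_mm"] = float(
            np.mean([tm_gle.mean(), tm_hum.mean()])
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- regions (shared binning for both sessions) ----------------------
    stage = "regions"
    try:
        gle_frame0 = kinematics.anatomical_frame_from_cap(
            shoulder.surfaces["scapula"]["subchondral"]
        )
        binning = regional.bin_regions(
            geom["gle_cart"],
            center=gle_frame0.center,
            medial_lateral_axis=gle_frame0.axes[:, 1],
            posterior_direction=-gle_frame0.axes[:, 0],
            span_deg=config.region_span_deg,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- per-session: gait -> track -> strain ---------------------------
    offsets = {"pre": config.dof_offsets_pre, "post": config.dof_offsets_post}
    gait_seeds = {"pre": seeds[1], "post": seeds[2]}
    session_data: dict = {}
    for session in ("pre", "post"):
        sdir = out / session
        sdir.mkdir(exist_ok=True)
        stage = f"simulate-gait[{session}]"
        try:
            gait = make_gait(
                GaitSpec(
                    n_cycles=config.n_cycles,
                    frames_per_cycle=config.frames_per_cycle,
                    dof_offsets=offsets[session],
                    cycle_noise_sd=config.cycle_noise_sd,
                    abnormal_fraction=config.gait_abnormal_fraction,
                    marker_noise_sd=config.marker_noise_sd_mm,
                    frame_rate=config.frame_rate_hz,
                    seed=gait_seeds[session],
                ),
                shoulder,
            )
            labels = [f"{s}_{i}" for s in ("scap", "hum") for i in range(6)]
            tracks = np.concatenate(
                [gait.marker_tracks["scapula"], gait.marker_tracks["humerus"]], axis=1
            )
            io.write_marker_tracks(sdir / "markers.csv", gait.times, tracks, labels)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = f"track[{session}]"
        try:
            trace, cycle_set, gle_frame, head_frame = _track_session(gait, shoulder, config)
            io.write_dof_csv(sdir / "dof_trace.csv", trace.values, config.frame_rate_hz)
            io.write_dof_csv(sdir / "representative_cycle.csv", cycle_set.representative)
            report[f"{session}_retained_cycles"] = int(cycle_set.n_retained)
            report[f"{session}_total_cycles"] = int(len(cycle_set.cycles))
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = f"strain[{session}]"
        try:
            cmap = _session_strain(cycle_set, shoulder, config, geom)
            surf = geom["gle_cart"].copy()
            surf.vertex_data = {
                "strain": cmap.strain_pct,
                "contact": cmap.contact_mask.astype(float),
            }
            mesh.write_ply(sdir / "cumulative_strain.ply", surf)
            pd.DataFrame(
                {
                    "vertex": np.arange(len(cmap.strain_pct)),
                    "strain_pct": cmap.strain_pct,
                    "contact": cmap.contact_mask.astype(int),
                }
            ).to_csv(sdir / "cumulative_strain.csv", index=False, float_format="%.8f")
            session_data[session] = {
                "cmap": cmap,
                "mean_strain": contact.mean_cumulative_strain(cmap),
                "area_ratio": cmap.contact_area_ratio_pct,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    # regional ground-truth coupling for the post T2* volume
    strain_means = {
        s: regional.regional_means(
            session_data[s]["cmap"].strain_pct, binning, geom["gle_cart"].vertex_areas()
        )
        for s in ("pre", "post")
    }
    strain_delta = regional.delta_table(strain_means["pre"], strain_means["post"], "strain")
    delta_by_region = dict(zip(strain_delta["region"], strain_delta["delta_strain"]))

    def post_offset_fn(points: np.ndarray) -> np.ndarray:
        ids = binning.region_of_points(points)
        out_ms = np.zeros(len(points))
        for rid, dv in delta_by_region.items():
            if np.isfinite(dv):
                out_ms[ids == rid] = config.coupling_slope_ms_per_pct * dv
        return out_ms

    # ---- per-session: volume -> t2star -----------------------------------
    vol_seeds = {"pre": seeds[3], "post": seeds[4]}
    for session in ("pre", "post"):
        sdir = out / session
        stage = f"simulate-volume[{session}]"
        try:
            espec = EchoSpec(
                voxel_size=(config.voxel_size_mm,) * 3,
                tissue_t2star={
                    "cartilage": tuple(config.cartilage_t2star_ms),
                    "fluid": tuple(config.fluid_t2star_ms),
                    "bone": (8.0, 1.0),
                },
                noise_sd=config.signal_noise_sd,
                seed=vol_seeds[session],
            )
            volume, _truth = make_multiecho_volume(
                espec, shoulder,
                t2star_offset_fn=post_offset_fn if session == "post" else None,
            )
            io.write_echo_volume(sdir / "multiecho", volume)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = f"t2star[{session}]"
        try:
            t2map = relaxometry.map_volume(
                volume,
                cutoff_ms=config.t2star_cutoff_ms,
                r2_gate=config.r2_gate,
                method=config.fit_method,
            )
            vals, vmask = relaxometry.project_to_surface(
                t2map, geom["gle_cart"], shoulder.surfaces["scapula"]["subchondral"]
            )
            pd.DataFrame(
                {
                    "vertex": np.arange(len(vals)),
                    "t2star_ms": np.where(vmask, vals, np.nan),
                    "valid": vmask.astype(int),
                }
            ).to_csv(sdir / "t2star_surface.csv", index=False, float_format="%.8f")
            session_data[session]["t2_vals"] = vals
            session_data[session]["t2_mask"] = vmask
            session_data[session]["mean_t2"] = float(np.nanmean(vals[vmask]))
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    # ---- correlate -------------------------------------------------------
    stage = "correlate"
    try:
        va = geom["gle_cart"].vertex_areas()
        t2_means = {
            s: regional.regional_means(
                session_data[s]["t2_vals"], binning, va, value_mask=session_data[s]["t2_mask"]
            )
            for s in ("pre", "post")
        }
        t2_delta = regional.delta_table(t2_means["pre"], t2_means["post"], "t2star")
        table = strain_delta[["region", "strain_pre", "strain_post", "delta_strain"]].merge(
            t2_delta[["region", "t2star_pre", "t2star_post", "delta_t2star", "defined"]],
            on="region",
        )
        table["area_mm2"] = strain_delta["area_mm2_pre"].to_numpy()
        table.to_csv(out / "regional_table.csv", index=False, float_format="%.8f")
        use = table["defined"] & np.isfinite(table["delta_strain"])
        r, p = regional.pearson(
            table.loc[use, "delta_strain"].to_numpy(),
            table.loc[use, "delta_t2star"].to_numpy(),
        )
        correlation = {"r": r, "p": p, "n": int(use.sum())}
        io.write_json(out / "correlation_report.json", correlation)
        report["correlation"] = correlation
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- phantom audit ---------------------------------------------------
    stage = "phantom"
    try:
        ph = make_phantom(
            config.phantom_angle_deg,
            noise_sd=config.phantom_noise_sd_mm,
            n_frames=config.phantom_frames,
            seed=seeds[5],
        )
        meas = measure_phantom(ph)
        bp = bias_precision(
            meas, statistic=config.precision_statistic,
            configuration=f"{config.phantom_angle_deg:g}deg",
        )
        base_pose = dof_to_pose(np.asarray(config.dof_offsets_pre), config.euler_seq)
        prop = propagate_to_strain(
            shoulder, base_pose, bp,
            threshold=config.contact_threshold_mm,
            n_samples=config.propagation_samples,
            seed=seeds[6],
        )
        phantom_report = {
            "configuration": f"{config.phantom_angle_deg:g}deg",
            "center_distance_mm": {
                "bias": bp["center_distance_mm"].bias,
                "precision": bp["center_distance_mm"].precision,
            },
            "block_angle_deg": {
                "bias": bp["block_angle_deg"].bias,
                "precision": bp["block_angle_deg"].precision,
            },
            "propagated": prop,
        }
        io.write_json(out / "phantom_report.json", phantom_report)
        report["phantom"] = phantom_report
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- summary ---------------------------------------------------------
    stage = "summary"
    try:
        for s in ("pre", "post"):
            report[f"{s}_mean_cumulative_strain_pct"] = session_data[s]["mean_strain"]
            report[f"{s}_contact_area_ratio_pct"] = session_data[s]["area_ratio"]
            report[f"{s}_mean_t2star_ms"] = session_data[s]["mean_t2"]
        report["delta_mean_strain_pct"] = (
            session_data["post"]["mean_strain"] - session_data["pre"]["mean_strain"]
        )
        report["delta_mean_t2star_ms"] = (
            session_data["post"]["mean_t2"] - session_data["pre"]["mean_t2"]
        )
        io.write_json(out / "summary.json", report)
        _write_manifest(out)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e
    return report


def _write_manifest(out: Path) -> None:
    entries = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    io.write_json(out / "manifest.json", entries)
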