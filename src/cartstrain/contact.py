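"""Cartilage thickness, overlap-based contact strain, and cumulative maps.

Thickness is the distance from each subchondral vertex along its outward
normal to the articular surface.  Contact strain at a vertex is the
interpenetration depth of the rigidly posed cartilage layers divided by
the undeformed thickness (combined two-layer thickness by default), and a
vertex is "in contact" when the overlap exceeds the 0.25 mm in-plane
resolution threshold.  Cumulative maps combine per-frame maps over a gait
cycle (per-vertex maximum by default, union of contact masks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriSurface, first_hit_distances, nearest_vertex_map, points_inside

__all__ = [
    "ThicknessMap",
    "StrainMap",
    "CumulativeMap",
    "thickness_map",
    "overlap_depth",
    "contact_strain",
    "cumulate",
    "mean_cumulative_strain",
]

CONTACT_THRESHOLD_MM = 0.25


@dataclass
class ThicknessMap:
    """Per-vertex cartilage thickness on both the subchondral and articular meshes."""

    values: np.ndarray  # mm, on subchondral vertices
    mask: np.ndarray  # False where the normal ray missed
    side: str
    on_cartilage: np.ndarray  # resampled onto the articular surface
    cartilage_mask: np.ndarray

    def mean(self) -> float:
        return float(self.values[self.mask].mean())


@dataclass
class StrainMap:
    """Single-frame contact strain on one articular surface."""

    strain_pct: np.ndarray  # %, 0 outside the contact mask
    overlap_mm: np.ndarray
    contact_mask: np.ndarray
    frame_index: int = -1


@dataclass
class CumulativeMap:
    """Cycle-level combination of per-frame strain maps."""

    strain_pct: np.ndarray
    contact_mask: np.ndarray
    contact_area_mm2: float
    contact_area_ratio_pct: float
    vertex_areas: np.ndarray
    mode: str = "max"


def _check_watertight(solid: TriSurface) -> None:
    edges = np.sort(
        np.vstack(
            [solid.faces[:, [0, 1]], solid.faces[:, [1, 2]], solid.faces[:, [2, 0]]]
        ),
        axis=1,
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts != 2):
        raise ValueError("mesh is open or non-orientable (boundary edges present)")


def thickness_map(subchondral: TriSurface, cartilage: TriSurface, side: str = "") -> ThicknessMap:
    """Perpendicular distance from the subchondral interface to the surface.

    Rays start at subchondral vertices along outward vertex normals; a miss
    masks the vertex.  More than 50% misses raises (surfaces are probably
    misaligned).  Values are also resampled onto the articular mesh
    (index-to-index when topologies match, else nearest vertex).
    """
    normals = subchondral.vertex_normals()
    t = first_hit_distances(cartilage, subchondral.vertices, normals)
    mask = np.isfinite(t)
    if mask.mean() < 0.5:
        raise ValueError(
            f"{(~mask).sum()} of {len(mask)} thickness rays missed the cartilage "
            "surface; surfaces are likely misaligned"
        )
    values = np.where(mask, t, np.nan)
    if cartilage.n_vertices == subchondral.n_vertices:
        on_cart, cart_mask = values.copy(), mask.copy()
    else:
        idx = nearest_vertex_map(subchondral, cartilage)
        on_cart, cart_mask = values[idx], mask[idx]
    return ThicknessMap(values, mask, side, on_cart, cart_mask)


def overlap_depth(
    surface: TriSurface,
    other_solid: TriSurface,
    normals: np.ndarray | None = None,
    check_watertight: bool = True,
) -> np.ndarray:
    """Interpenetration depth of ``surface`` vertices into ``other_solid`` (mm).

    A vertex inside the watertight solid gets the distance along the
    reversed contact normal to the solid's boundary (its depth below the
    opposing articular surface); disjoint vertices get 0.  ``normals``
    defaults to the surface's outward vertex normals.
    """
    if check_watertight:
        _check_watertight(other_solid)
    if normals is None:
        normals = surface.vertex_normals()
    depth = np.zeros(surface.n_vertices)
    inside = points_inside(other_solid, surface.vertices)
    if inside.any():
        t = first_hit_distances(other_solid, surface.vertices[inside], -normals[inside])
        t = np.where(np.isfinite(t), t, 0.0)
        depth[inside] = t
    return depth


def contact_strain(
    overlap: np.ndarray,
    scap_thickness: np.ndarray,
    hum_thickness: np.ndarray,
    threshold: float = CONTACT_THRESHOLD_MM,
    denominator: str = "combined",
    frame_index: int = -1,
) -> StrainMap:
    """Strain map from co-registered overlap and thickness values.

    ``denominator="combined"`` divides by the local scapular + humeral
    thickness; ``"own-layer"`` divides by the scapular layer only.  Strain
    is reported in percent and only inside the contact mask
    (overlap > threshold).
    """
    overlap = np.asarray(overlap, dtype=np.float64)
    if denominator == "combined":
        denom = np.asarray(scap_thickness, dtype=np.float64) + np.asarray(
            hum_thickness, dtype=np.float64
        )
    elif denominator == "own-layer":
        denom = np.asarray(scap_thickness, dtype=np.float64).copy()
    else:
        raise ValueError("denominator must be 'combined' or 'own-layer'")
    mask = overlap > threshold
    bad = mask & ~(denom > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} contacting vertices have zero thickness; masked")
        mask = mask & ~bad
    strain = np.zeros_like(overlap)
    strain[mask] = 100.0 * overlap[mask] / denom[mask]
    return StrainMap(strain, overlap, mask, frame_index=frame_index)


def cumulate(frames: list, surface: TriSurface, mode: str = "max") -> CumulativeMap:
    """Combine per-frame strain maps over a cycle on one parameterization.

    Per-vertex cumulative strain is the maximum over frames (``"max"``) or
    the mean over the frames in which the vertex is in contact (``"mean"``);
    the cumulative contact mask is the union of the per-frame masks.
    Contact area uses barycentric vertex areas of ``surface``.
    """
    if not frames:
        raise ValueError("empty frame list")
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    strain = np.stack([f.strain_pct for f in frames])
    masks = np.stack([f.contact_mask for f in frames])
    union = masks.any(axis=0)
    if mode == "max":
        cum = strain.max(axis=0)
    else:
        with np.errstate(invalid="ignore"):
            cum = np.where(union, strain.sum(axis=0) / np.maximum(masks.sum(axis=0), 1), 0.0)
    va = surface.vertex_areas()
    area = float(va[union].sum())
    total = float(va.sum())
    return CumulativeMap(
        strain_pct=cum,
        contact_mask=union,
        contact_area_mm2=area,
        contact_area_ratio_pct=100.0 * area / total if total > 0 else 0.0,
        vertex_areas=va,
        mode=mode,
    )


def posed_frame_strain(
    glenoid_cartilage: TriSurface,
    glenoid_thickness: np.ndarray,
    humeral_cartilage: TriSurface,
    humeral_thickness: np.ndarray,
    humeral_solid: TriSurface,
    relative_pose,
    threshold: float = CONTACT_THRESHOLD_MM,
    denominator: str = "combined",
    normals: np.ndarray | None = None,
    frame_index: int = -1,
) -> StrainMap:
    """Strain on the glenoid articular surface for one relative pose.

    The humeral layer is rigidly posed into the glenoid frame; the humeral
    thickness entering the denominator is taken from the nearest posed
    humeral articular vertex.
    """
    R, t = relative_pose.rotation, relative_pose.translation
    hum_cart = humeral_cartilage.transformed(R, t)
    hum_solid = humeral_solid.transformed(R, t)
    overlap = overlap_depth(glenoid_cartilage, hum_solid, normals, check_watertight=False)
    idx = cKDTree(hum_cart.vertices).query(glenoid_cartilage.vertices)[1]
    return contact_strain(
        overlap,
        np.asarray(glenoid_thickness, dtype=float),
        np.asarray(humeral_thickness, dtype=float)[idx],
        threshold=threshold,
        denominator=denominator,
        frame_index=frame_index,
    )


def mean_cumulative_strain(cmap: CumulativeMap) -> float:
    """Area-weighted mean cumulative strain (%) over the contact area."""
    if not cmap.contact_mask.any():
        warnings.warn("empty cumulative contact mask; mean strain defined as 0")
        return 0.0
    w = cmap.vertex_areas[cmap.contact_mask]
    return float(np.average(cmap.strain_pct[cmap.contact_mask], weights=w))
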