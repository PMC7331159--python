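"""Regional binning and the study's statistics.

Bins an articular surface into 20-degree posterior-to-anterior regions
about the medial-lateral axis, computes area-weighted regional means and
pre/post deltas, and implements Pearson correlation, two-way
intraclass-correlation reliability (ICC(2,1) by default, with an F-based
95% CI), and RMS differences of matched thickness samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import TriSurface

__all__ = [
    "RegionBinning",
    "ReliabilityResult",
    "bin_regions",
    "regional_means",
    "delta_table",
    "pearson",
    "icc",
    "rms_difference",
]

DEFAULT_SPAN_DEG = 20.0


@dataclass
class RegionBinning:
    """Region id per vertex (1 = posterior-most) plus the angular layout."""

    region_ids: np.ndarray  # int, 0 where masked out
    n_regions: int
    boundaries_deg: np.ndarray  # region edges from the posterior extreme
    center: np.ndarray
    medial_lateral_axis: np.ndarray
    posterior_direction: np.ndarray = None
    third_direction: np.ndarray = None  # in-plane axis of increasing angle
    ref_angle_deg: float = 0.0  # raw angle of the posterior extreme
    extent_deg: float = 0.0  # angular span of the binned surface
    span_deg: float = DEFAULT_SPAN_DEG

    def region_of_points(self, points: np.ndarray) -> np.ndarray:
        """Region id of arbitrary lab points under this binning (0 = outside)."""
        rel = np.atleast_2d(points) - self.center
        ang = (
            np.degrees(np.arctan2(rel @ self.third_direction, rel @ self.posterior_direction))
            - self.ref_angle_deg
        )
        ids = np.floor(ang / self.span_deg).astype(np.int64) + 1
        # the anterior extreme belongs to the last region, as in bin_regions
        ids[(ids == self.n_regions + 1) & (ang <= self.extent_deg + 1e-9)] = self.n_regions
        ids[(ids < 1) | (ids > self.n_regions)] = 0
        return ids


@dataclass
class ReliabilityResult:
    icc: float
    ci95: tuple
    design: str  # "intra" | "inter"
    form: str  # "ICC(2,1)" | "ICC(3,1)"
    n_subjects: int
    n_raters: int


def bin_regions(
    surface: TriSurface,
    center: np.ndarray,
    medial_lateral_axis: np.ndarray,
    posterior_direction: np.ndarray,
    span_deg: float = DEFAULT_SPAN_DEG,
    mask: np.ndarray | None = None,
) -> RegionBinning:
    """Partition a surface into equal angular spans about the ML axis.

    Vertex angle is the atan2 angle of its position projected into the
    plane normal to ``medial_lateral_axis``, measured from the posterior
    extreme of the (unmasked) surface; region id = floor(angle/span) + 1.
    """
    ml = np.asarray(medial_lateral_axis, dtype=float)
    ml = ml / np.linalg.norm(ml)
    post = np.asarray(posterior_direction, dtype=float)
    post = post - (post @ ml) * ml
    if np.linalg.norm(post) < 1e-9:
        raise ValueError("posterior direction is degenerate (parallel to the ML axis)")
    post /= np.linalg.norm(post)
    third = np.cross(ml, post)

    rel = surface.vertices - np.asarray(center, dtype=float)
    a = rel @ post
    b = rel @ third

    keep = np.ones(surface.n_vertices, dtype=bool) if mask is None else np.asarray(mask, bool)
    if not keep.any():
        raise ValueError("no unmasked vertices to bin")
    # orient the angle axis so the surface lies at positive angles and the
    # posterior extreme is the angular origin (region 1)
    if b[keep].mean() < 0:
        third = -third
        b = -b
    ang = np.degrees(np.arctan2(b, a))
    ang0 = ang - ang[keep].min()  # 0 at the posterior extreme
    extent = float(ang0[keep].max())
    if extent < span_deg:
        import warnings

        warnings.warn("surface angular extent below one span; single region")
    n_regions = max(int(np.ceil((extent - 1e-9) / span_deg)), 1)
    ids = np.zeros(surface.n_vertices, dtype=np.int64)
    ids[keep] = np.minimum((ang0[keep] // span_deg).astype(np.int64), n_regions - 1) + 1
    return RegionBinning(
        region_ids=ids,
        n_regions=n_regions,
        boundaries_deg=np.arange(n_regions + 1) * span_deg,
        center=np.asarray(center, dtype=float),
        medial_lateral_axis=ml,
        posterior_direction=post,
        third_direction=third,
        ref_angle_deg=float(ang[keep].min()),
        extent_deg=extent,
        span_deg=float(span_deg),
    )


def regional_means(
    values: np.ndarray,
    binning: RegionBinning,
    area_weights: np.ndarray,
    value_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Area-weighted mean of a per-vertex map in each region.

    Regions with no unmasked coverage are flagged (``empty=True``) rather
    than dropped.
    """
    values = np.asarray(values, dtype=float)
    w = np.asarray(area_weights, dtype=float)
    ok = binning.region_ids > 0
    if value_mask is not None:
        ok = ok & np.asarray(value_mask, bool)
    ok = ok & np.isfinite(values)
    rows = []
    for rid in range(1, binning.n_regions + 1):
        sel = ok & (binning.region_ids == rid)
        if sel.any():
            mean = float(np.average(values[sel], weights=w[sel]))
            area = float(w[sel].sum())
            rows.append({"region": rid, "mean": mean, "area_mm2": area, "empty": False})
        else:
            rows.append({"region": rid, "mean": np.nan, "area_mm2": 0.0, "empty": True})
    return pd.DataFrame(rows)


def delta_table(pre: pd.DataFrame, post: pd.DataFrame, label: str) -> pd.DataFrame:
    """Join per-region pre/post means into a delta (= post - pre) table."""
    t = pre.merge(post, on="region", suffixes=("_pre", "_post"))
    t[f"delta_{label}"] = t["mean_post"] - t["mean_pre"]
    t["defined"] = ~(t["empty_pre"] | t["empty_post"])
    return t.rename(columns={"mean_pre": f"{label}_pre", "mean_post": f"{label}_post"})


# ---------------------------------------------------------------------------
# statistics


def pearson(x: np.ndarray, y: np.ndarray):
    """Sample Pearson r with the two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _anova_mean_squares(data: np.ndarray):
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(
    measurements: np.ndarray,
    design: str = "inter",
    form: str = "ICC(2,1)",
    alpha: float = 0.05,
) -> ReliabilityResult:
    """Intraclass correlation of a complete subjects x raters table.

    ``ICC(2,1)``: two-way random effects, absolute agreement, single
    measure (Shrout & Fleiss), with the F-based 95% CI.  ``ICC(3,1)``
    (consistency) is also available.
    """
    data = np.asarray(measurements, dtype=float)
    if data.ndim != 2:
        raise ValueError("measurements must be subjects x raters")
    n, k = data.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(data)):
        raise ValueError("complete design required (missing cells)")
    msr, msc, mse = _anova_mean_squares(data)

    if form == "ICC(3,1)":
        est = (msr - mse) / (msr + (k - 1) * mse)
        fl = (msr / mse) / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = (msr / mse) * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif form == "ICC(2,1)":
        est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        # Shrout & Fleiss F-based interval
        a = k * est / (n * (1 - est)) if est < 1 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
        if np.isfinite(a) and mse > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_star * mse) / (
                f_star * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_star2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_star2 * msr
            )
        else:
            lo = hi = 1.0
    else:
        raise ValueError("form must be 'ICC(2,1)' or 'ICC(3,1)'")
    lo, hi = float(min(lo, est)), float(max(hi, est))
    return ReliabilityResult(
        icc=float(est), ci95=(lo, hi), design=design, form=form, n_subjects=n, n_raters=k
    )


def rms_difference(pairs: list):
    """RMS of paired differences per comparison; mean +/- SD across comparisons.

    ``pairs`` is a list of ``(a, b)`` matched sample arrays.  Returns
    ``(mean_rms, sd_rms, per_comparison)``.
    """
    values = []
    for a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("matched sample length mismatch")
        values.append(float(np.sqrt(np.mean((a - b) ** 2))))
    values = np.asarray(values)
    return float(values.mean()), float(values.std(ddof=1)) if len(values) > 1 else 0.0, values
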