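"""Team-shape features: stretch index, convex hull, hull-clipped Voronoi
cells, length/width ratio, spatial exploration, cross-period consistency.

The Voronoi construction clips each member's nearest-member region with the
group convex hull, giving a per-member "dominated area" whose sum equals the
hull area by construction.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance
from shapely.geometry import MultiPoint, Polygon

from .pacs import PacsSeries
from .segmentation import MovementPeriod
from .regularity import series_entropy


@dataclass
class ShapeFrame:
    t: float
    centroid: np.ndarray
    dist_to_centroid: np.ndarray      # (n,)
    hull_area: float
    voronoi_area: np.ndarray | None   # (n,) or None when degenerate


def stretch_index(period: MovementPeriod) -> dict:
    """Mean member-to-centroid distance per frame, plus summary and entropy."""
    traj = period.traj
    if traj.n_members < 2:
        raise ValueError("need at least 2 members")
    c = traj.centroid()
    d = np.linalg.norm(traj.pos - c[None, :, :], axis=2)   # (n, T)
    si = d.mean(axis=0)
    return {"series": si, "mean": float(si.mean()),
            "entropy": series_entropy(si)}


def _halfplane(center: np.ndarray, other: np.ndarray, bound: float) -> Polygon:
    """Polygon approximating the half-plane of points closer to center than other."""
    mid = 0.5 * (center + other)
    d = other - center
    nrm = np.linalg.norm(d)
    d = d / nrm
    perp = np.array([-d[1], d[0]])
    a = mid + perp * bound
    b = mid - perp * bound
    back = -d * 2 * bound
    return Polygon([a, b, b + back, a + back])


def hull_and_voronoi(points: np.ndarray) -> tuple[float, np.ndarray | None]:
    """Convex hull area and hull-clipped Voronoi cell area per member.

    Each cell is the intersection of the hull with the half-planes closer to
    that member than to any other, so the cell areas always sum to the hull
    area. Fewer than 3 members, or collinear members, give hull area 0 and
    ``None`` cells (to be masked by the caller).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        return 0.0, None
    span = 10.0 * (np.ptp(points, axis=0).max() + 1.0)
    areas = np.empty(n)
    for i in range(n):
        cell = hull
        for j in range(n):
            if j == i or np.allclose(points[i], points[j]):
                continue
            cell = cell.intersection(_halfplane(points[i], points[j], span))
            if cell.is_empty:
                break
        areas[i] = 0.0 if cell.is_empty else cell.area
    return float(hull.area), areas


def shape_frames(period: MovementPeriod) -> list[ShapeFrame]:
    traj = period.traj
    c = traj.centroid()
    frames = []
    for k in range(traj.t_grid.size):
        pts = traj.pos[:, k, :]
        hull_area, vor = hull_and_voronoi(pts)
        frames.append(ShapeFrame(
            t=float(traj.t_grid[k]), centroid=c[k],
            dist_to_centroid=np.linalg.norm(pts - c[k], axis=1),
            hull_area=hull_area, voronoi_area=vor))
    return frames


def hull_voronoi_features(period: MovementPeriod) -> dict:
    """Hull-area summaries and Voronoi mean / coefficient of variation.

    The CV is computed per member over time, then averaged over members.
    Degenerate frames (collinear or < 3 members) are masked out.
    """
    frames = shape_frames(period)
    hull = np.array([f.hull_area for f in frames])
    ok = np.array([f.voronoi_area is not None for f in frames])
    feats = {
        "spa.hull.max": float(hull[ok].max()) if ok.any() else np.nan,
        "spa.hull.min": float(hull[ok].min()) if ok.any() else np.nan,
        "spa.hull.mean": float(hull[ok].mean()) if ok.any() else np.nan,
        "spa.hull.var": float(hull[ok].var()) if ok.any() else np.nan,
        "spa.hull.entropy": series_entropy(hull[ok]) if ok.any() else np.nan,
    }
    if ok.any():
        vor = np.stack([f.voronoi_area for f in frames if f.voronoi_area is not None],
                       axis=1)  # (n, T_ok)
        mean_t = vor.mean(axis=1)
        sd_t = vor.std(axis=1)
        cv = np.where(mean_t > 0, sd_t / np.where(mean_t == 0, 1, mean_t), 0.0)
        feats["spa.voronoi.mean"] = float(mean_t.mean())
        feats["spa.voronoi.var"] = float(vor.var(axis=0).mean())
        feats["spa.voronoi.cv"] = float(cv.mean())
    else:
        feats["spa.voronoi.mean"] = np.nan
        feats["spa.voronoi.var"] = np.nan
        feats["spa.voronoi.cv"] = np.nan
    return feats


def length_width_ratio(pacs: PacsSeries) -> dict:
    """Along-path extent over cross-path extent, per frame (masked at zero width)."""
    length = np.nanmax(pacs.y, axis=0) - np.nanmin(pacs.y, axis=0)
    width = np.nanmax(pacs.x, axis=0) - np.nanmin(pacs.x, axis=0)
    ratio = np.where(width > 0, length / np.where(width == 0, 1, width), np.nan)
    finite = ratio[np.isfinite(ratio)]
    return {"series": ratio,
            "mean": float(finite.mean()) if finite.size else np.nan,
            "entropy": series_entropy(finite) if finite.size else np.nan}


def spatial_exploration_index(xy: np.ndarray) -> float:
    """Mean distance of a member from their own average location (m)."""
    xy = np.asarray(xy, dtype=float)
    xy = xy[np.all(np.isfinite(xy), axis=1)]
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    return float(np.linalg.norm(xy - xy.mean(axis=0), axis=1).mean())


def distribution_consistency(per_period_xy: list[np.ndarray]) -> dict | None:
    """Cross-period agreement of one member's coordinate distributions.

    For every pair of movement periods and each axis: the variance-ratio
    F statistic (larger variance over smaller, orientation-free) and the 1-D
    Wasserstein distance between the empirical distributions. Values are
    averaged over period pairs. Returns ``None`` with a single period.
    """
    if len(per_period_xy) < 2:
        return None
    fx, fy, wx, wy = [], [], [], []
    for a, b in itertools.combinations(per_period_xy, 2):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        for axis, (fs, ws) in zip((0, 1), ((fx, wx), (fy, wy))):
            va, vb = a[:, axis].var(ddof=1), b[:, axis].var(ddof=1)
            lo, hi = min(va, vb), max(va, vb)
            fs.append(hi / lo if lo > 0 else (1.0 if hi == 0 else np.inf))
            ws.append(wasserstein_distance(a[:, axis], b[:, axis]))
    return {"spa.consistency.f_x": float(np.mean(fx)),
            "spa.consistency.f_y": float(np.mean(fy)),
            "spa.consistency.w_x": float(np.mean(wx)),
            "spa.consistency.w_y": float(np.mean(wy))}
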