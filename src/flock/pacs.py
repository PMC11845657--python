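"""Path-adapted coordinates: positions relative to the group's smoothed path.

Each member's planar position is re-expressed as a lateral distance from the
path (x: negative left of travel, positive right) and a signed arc-length
offset along the path from the centroid's foot point (y: positive ahead).
Because the full path is used rather than the centroid's instantaneous
heading, members far ahead of or behind the centroid keep sensible
coordinates through turns. The instantaneous-heading variant is provided as
the baseline it replaces, for artifact comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.spatial import cKDTree

from .segmentation import MovementPeriod

DEFAULT_DENSE_SPACING = 0.1  # m between pre-sampled path points
DEFAULT_MAX_OFFSET = 500.0   # m; members farther from the path are flagged
MIN_HEADING_SPEED = 0.05     # m/s; below this the heading frame is undefined


@dataclass
class PathSpline:
    """A smooth planar curve with an arc-length lookup table."""

    _splines: tuple  # (CubicSpline x(u), CubicSpline y(u))
    u_dense: np.ndarray = field(repr=False)
    points_dense: np.ndarray = field(repr=False)   # (N, 2)
    s_dense: np.ndarray = field(repr=False)        # cumulative arc length, m

    @property
    def total_length(self) -> float:
        return float(self.s_dense[-1])

    def point(self, u):
        return np.stack([self._splines[0](u), self._splines[1](u)], axis=-1)

    def tangent(self, u):
        d = np.stack([self._splines[0](u, 1), self._splines[1](u, 1)], axis=-1)
        norm = np.linalg.norm(d, axis=-1, keepdims=True)
        return d / np.where(norm == 0, 1.0, norm)

    def arc_length_at(self, u):
        return np.interp(u, self.u_dense, self.s_dense)


@dataclass
class PacsSeries:
    """Path-adapted coordinates of all members over one movement period."""

    t: np.ndarray                   # (T,)
    member_ids: list[str]
    x: np.ndarray                   # (n, T) lateral, +right/-left of path
    y: np.ndarray                   # (n, T) along-path offset from centroid foot
    far_flags: np.ndarray           # (n, T) True where member beyond max_offset
    valid: np.ndarray | None = None  # (T,) False where frame undefined (baseline only)

    def member(self, mid: str) -> np.ndarray:
        """(T, 2) x/y series of one member."""
        m = self.member_ids.index(mid)
        return np.column_stack([self.x[m], self.y[m]])


def fit_centroid_path(period: MovementPeriod | None = None,
                      waypoints: np.ndarray | None = None,
                      smoothing: float | None = None,
                      dense_spacing: float = DEFAULT_DENSE_SPACING) -> PathSpline:
    """Fit a smooth spline path through centroid positions (or waypoints).

    With a period, the curve is parameterized by time and smoothed per
    coordinate (generalized cross-validation picks the penalty unless
    ``smoothing`` is given; 0 interpolates). With explicit ``waypoints``
    (k, 2), chord-length parameterization with an interpolating spline is
    used. The dense arc-length table targets ``dense_spacing`` metres.
    """
    if (period is None) == (waypoints is None):
        raise ValueError("pass exactly one of period or waypoints")
    if period is not None:
        cpos = period.traj.centroid()
        u = period.traj.t_grid.astype(float)
        if cpos.shape[0] < 4:
            raise ValueError("need at least 4 centroid points")
        if np.ptp(cpos[:, 0]) < 1e-9 and np.ptp(cpos[:, 1]) < 1e-9:
            raise ValueError("degenerate path: all centroid positions coincide")
        sx, sy = [], []
        for d in range(2):
            if smoothing is None:
                spl = make_smoothing_spline(u, cpos[:, d])
            elif smoothing == 0:
                spl = CubicSpline(u, cpos[:, d])
            else:
                spl = make_smoothing_spline(u, cpos[:, d], lam=float(smoothing))
            (sx if d == 0 else sy).append(spl)
        splines = (_as_cubic(sx[0], u), _as_cubic(sy[0], u))
    else:
        waypoints = np.asarray(waypoints, dtype=float)
        if waypoints.shape[0] < 2:
            raise ValueError("need at least 2 waypoints")
        chord = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(waypoints, axis=0), axis=1))])
        if chord[-1] < 1e-9:
            raise ValueError("degenerate path: all waypoints coincide")
        u = chord
        kind = "cubic" if waypoints.shape[0] >= 4 else "linear"
        if kind == "cubic":
            splines = (CubicSpline(u, waypoints[:, 0]), CubicSpline(u, waypoints[:, 1]))
        else:
            splines = (_LinearCurve(u, waypoints[:, 0]), _LinearCurve(u, waypoints[:, 1]))

    # arc-length table: iterate once so sampling roughly matches dense_spacing
    u0, u1 = float(u[0]), float(u[-1])
    probe = np.linspace(u0, u1, 4 * len(u))
    pts = np.column_stack([splines[0](probe), splines[1](probe)])
    length_est = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    n_dense = int(min(max(len(u) * 4, length_est / dense_spacing), 2_000_000)) + 1
    u_dense = np.linspace(u0, u1, n_dense)
    p_dense = np.column_stack([splines[0](u_dense), splines[1](u_dense)])
    s_dense = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(p_dense, axis=0), axis=1))])
    return PathSpline(splines, u_dense, p_dense, s_dense)


class _LinearCurve:
    """Piecewise-linear fallback for very short waypoint lists."""

    def __init__(self, u, v):
        self.u = np.asarray(u, float)
        self.v = np.asarray(v, float)

    def __call__(self, u, nu=0):
        if nu == 0:
            return np.interp(u, self.u, self.v)
        slopes = np.diff(self.v) / np.diff(self.u)
        idx = np.clip(np.searchsorted(self.u, u, side="right") - 1, 0, slopes.size - 1)
        return slopes[idx]


def _as_cubic(spl, u):
    # make_smoothing_spline returns a BSpline; CubicSpline passes through
    return spl


def _project_points(path: PathSpline, points: np.ndarray,
                    prev_s: np.ndarray | None = None,
                    continuity_tol: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Foot points of ``points`` (m, 2) on the path.

    Returns (u_star, s_star). Global nearest dense sample, refined by a
    parabolic fit of squared distance over the neighbouring samples. When
    several dense candidates are nearly as close (within ``continuity_tol``
    metres, e.g. on a hairpin), the one whose arc length is closest to
    ``prev_s`` wins, keeping foot points temporally continuous.
    """
    tree = getattr(path, "_tree", None)
    if tree is None:
        tree = cKDTree(path.points_dense)
        path._tree = tree
    k = min(24, len(path.points_dense))
    dists, idx = tree.query(points, k=k)
    if k == 1:
        dists = dists[:, None]
        idx = idx[:, None]

    n = points.shape[0]
    chosen = idx[:, 0].copy()
    if prev_s is not None:
        branch_sep = 5.0  # m of arc separating distinct branches
        near = dists <= (dists[:, :1] + continuity_tol)
        for i in range(n):
            if np.isnan(prev_s[i]):
                continue
            cand = idx[i][near[i]]
            if cand.size < 2:
                continue
            s_cand = path.s_dense[cand]
            if s_cand.max() - s_cand.min() <= branch_sep:
                continue  # all on one branch: keep the global nearest
            # cluster candidates by arc gaps; pick the branch nearest prev_s,
            # then the closest point within it
            order = np.argsort(s_cand)
            cand, s_cand = cand[order], s_cand[order]
            d_cand = dists[i][near[i]][order]
            splits = np.nonzero(np.diff(s_cand) > branch_sep)[0] + 1
            best_pick, best_gap = None, np.inf
            for cluster in np.split(np.arange(cand.size), splits):
                k_best = cluster[np.argmin(d_cand[cluster])]
                gap = abs(s_cand[k_best] - prev_s[i])
                if gap < best_gap:
                    best_gap, best_pick = gap, cand[k_best]
            chosen[i] = best_pick

    # parabolic refinement of squared distance around the chosen sample
    i0 = np.clip(chosen, 1, len(path.u_dense) - 2)
    du = path.u_dense[1] - path.u_dense[0]
    d2 = np.empty((n, 3))
    for off in (-1, 0, 1):
        p = path.points_dense[i0 + off]
        d2[:, off + 1] = np.sum((p - points) ** 2, axis=1)
    denom = d2[:, 0] - 2 * d2[:, 1] + d2[:, 2]
    shift = np.where(np.abs(denom) > 1e-300,
                     0.5 * (d2[:, 0] - d2[:, 2]) / np.where(denom == 0, 1, denom),
                     0.0)
    shift = np.clip(shift, -1.0, 1.0)
    u_star = path.u_dense[i0] + shift * du
    u_star = np.clip(u_star, path.u_dense[0], path.u_dense[-1])
    return u_star, path.arc_length_at(u_star)


def pacs_transform(period: MovementPeriod, path: PathSpline | None = None,
                   max_offset: float = DEFAULT_MAX_OFFSET,
                   smoothing: float | None = None) -> PacsSeries:
    """Path-adapted coordinates for every member and timepoint of a period.

    x is the signed lateral offset from the foot point (negative = left of
    the direction of travel), y the signed arc length from the centroid's
    foot point to the member's foot point (positive = ahead).
    """
    if path is None:
        path = fit_centroid_path(period, smoothing=smoothing)
    traj = period.traj
    n, T = traj.n_members, traj.t_grid.size
    x = np.empty((n, T))
    y = np.empty((n, T))
    far = np.zeros((n, T), dtype=bool)

    cpos = traj.centroid()
    prev_sc = np.full(1, np.nan)
    prev_sm = np.full(n, np.nan)
    s_cent = np.empty(T)
    for k in range(T):
        uc, sc = _project_points(path, cpos[k][None, :], prev_s=prev_sc)
        s_cent[k] = sc[0]
        prev_sc = sc
        um, sm = _project_points(path, traj.pos[:, k, :], prev_s=prev_sm)
        prev_sm = sm
        feet = path.point(um)
        tang = path.tangent(um)
        off = traj.pos[:, k, :] - feet
        right = np.column_stack([tang[:, 1], -tang[:, 0]])
        x[:, k] = np.sum(off * right, axis=1)
        y[:, k] = sm - sc[0]
        far[:, k] = np.linalg.norm(off, axis=1) > max_offset
    return PacsSeries(t=traj.t_grid.copy(), member_ids=list(traj.member_ids),
                      x=x, y=y, far_flags=far)


def centroid_heading_transform(period: MovementPeriod,
                               min_speed: float = MIN_HEADING_SPEED) -> PacsSeries:
    """Baseline transform using the centroid's instantaneous heading.

    Members are expressed in the frame whose +y axis is the centroid's
    current heading and whose origin is the centroid. Frames where the
    centroid is (nearly) stationary are marked invalid. Kept only for
    artifact comparison against the path-adapted transform.
    """
    traj = period.traj
    cpos = traj.centroid()
    vel = np.gradient(cpos, traj.t_grid, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    valid = speed >= min_speed
    forward = np.zeros_like(vel)
    forward[valid] = vel[valid] / speed[valid, None]
    right = np.column_stack([forward[:, 1], -forward[:, 0]])

    off = traj.pos - cpos[None, :, :]        # (n, T, 2)
    x = np.einsum("ntd,td->nt", off, right)
    y = np.einsum("ntd,td->nt", off, forward)
    x[:, ~valid] = np.nan
    y[:, ~valid] = np.nan
    return PacsSeries(t=traj.t_grid.copy(), member_ids=list(traj.member_ids),
                      x=x, y=y, far_flags=np.zeros_like(x, dtype=bool),
                      valid=valid)
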