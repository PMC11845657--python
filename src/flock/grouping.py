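"""Density-based clustering features: outliers, consistency, confidence,
nearest-neighbour metrics.

Members are clustered frame by frame with DBSCAN or HDBSCAN; anybody farther
than the distance threshold from every cluster is an outlier. Consistency is
the chance-corrected partition agreement between consecutive frames.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN, HDBSCAN
from sklearn.metrics import adjusted_rand_score

from .pacs import PacsSeries
from .segmentation import MovementPeriod
from .regularity import series_entropy

OUTLIER = -1


@dataclass
class ClusterFrame:
    t: float
    labels: np.ndarray                  # (n,), OUTLIER for outliers
    confidence: np.ndarray | None       # (n,), hierarchical method only


def cluster_frames(period: MovementPeriod, method: str = "dbscan",
                   min_cluster_size: int = 2,
                   distance_threshold: float = 5.0) -> list[ClusterFrame]:
    """Per-frame density clustering of member positions."""
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    traj = period.traj
    if traj.n_members < min_cluster_size:
        warnings.warn("fewer members than min_cluster_size; everyone is an outlier")
        return [ClusterFrame(float(t), np.full(traj.n_members, OUTLIER), None)
                for t in traj.t_grid]
    frames = []
    for k in range(traj.t_grid.size):
        pts = traj.pos[:, k, :]
        conf = None
        if method == "dbscan":
            labels = DBSCAN(eps=distance_threshold,
                            min_samples=min_cluster_size).fit_predict(pts)
        elif method == "hdbscan":
            model = HDBSCAN(min_cluster_size=min_cluster_size,
                            cluster_selection_epsilon=distance_threshold,
                            allow_single_cluster=True, copy=True).fit(pts)
            labels = model.labels_
            conf = model.probabilities_
        else:
            raise ValueError(f"unknown method {method!r}")
        frames.append(ClusterFrame(float(traj.t_grid[k]), labels, conf))
    return frames


def outlier_metrics(frames: list[ClusterFrame], member_ids: list[str],
                    dt: float) -> dict:
    """Per-member time spent as outlier and the count of distinct outlier members."""
    if not frames:
        raise ValueError("no frames")
    labels = np.stack([f.labels for f in frames], axis=1)   # (n, T)
    out = labels == OUTLIER
    times = out.sum(axis=1) * dt
    return {
        "per_member_outlier_time": {mid: float(times[m])
                                    for m, mid in enumerate(member_ids)},
        "n_outlier_members": int((out.any(axis=1)).sum()),
        "total_outlier_time": float(times.sum()),
    }


def _with_singleton_outliers(labels: np.ndarray) -> np.ndarray:
    """Replace OUTLIER labels with unique singleton cluster ids."""
    labels = labels.copy()
    nxt = labels.max() + 1 if labels.size else 0
    for i in np.nonzero(labels == OUTLIER)[0]:
        labels[i] = nxt
        nxt += 1
    return labels


def cluster_consistency(frames: list[ClusterFrame]) -> float:
    """Mean adjusted Rand agreement between consecutive frame partitions.

    Outliers count as their own singleton clusters; identical partitions in
    every frame give 1.0.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    scores = []
    for a, b in zip(frames[:-1], frames[1:]):
        la = _with_singleton_outliers(a.labels)
        lb = _with_singleton_outliers(b.labels)
        if np.array_equal(la, lb) or (
                len(set(la)) == 1 and len(set(lb)) == 1):
            scores.append(1.0)
        else:
            scores.append(adjusted_rand_score(la, lb))
    return float(np.mean(scores))


def membership_confidence(frames: list[ClusterFrame],
                          member_ids: list[str]) -> dict[str, float]:
    """Mean HDBSCAN membership probability per member, over frames where clustered."""
    conf = {mid: [] for mid in member_ids}
    for f in frames:
        if f.confidence is None:
            raise ValueError("confidence requires the hierarchical method")
        for m, mid in enumerate(member_ids):
            if f.labels[m] != OUTLIER:
                conf[mid].append(f.confidence[m])
    return {mid: (float(np.mean(v)) if v else np.nan) for mid, v in conf.items()}


def nearest_neighbor_features(period: MovementPeriod,
                              pacs: PacsSeries | None = None) -> dict:
    """Each member's nearest-neighbour distance per frame.

    Euclidean NN in raw planar coordinates, plus |dx| and |dy| to the
    per-axis nearest neighbour in path-adapted coordinates when available.
    Returns series (n, T) plus per-member means and entropies.
    """
    traj = period.traj
    n, T = traj.n_members, traj.t_grid.size
    if n < 2:
        raise ValueError("need at least 2 members")
    diff = traj.pos[:, None, :, :] - traj.pos[None, :, :, :]
    dist = np.linalg.norm(diff, axis=3)                     # (n, n, T)
    eye = np.eye(n, dtype=bool)
    dist[eye] = np.inf
    nn = dist.min(axis=1)                                   # (n, T)
    out = {"nn": nn}
    if pacs is not None:
        for name, coords in (("nn_x", pacs.x), ("nn_y", pacs.y)):
            d = np.abs(coords[:, None, :] - coords[None, :, :])
            d[eye] = np.inf
            out[name] = d.min(axis=1)
    summaries = {}
    for key, series in out.items():
        summaries[f"clu.{key}.mean"] = {
            mid: float(np.nanmean(series[m])) for m, mid in enumerate(traj.member_ids)}
        summaries[f"clu.{key}.entropy"] = {
            mid: series_entropy(series[m][np.isfinite(series[m])])
            for m, mid in enumerate(traj.member_ids)}
    out["summaries"] = summaries
    return out
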