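"""Velocity-based features.

Speeds and accelerations come from central differences on the smoothed,
regularly gridded positions (one-sided at the ends). Group-level series are
the spread (fastest minus slowest member) and the across-member population
variance of speed at each timepoint.

Acceleration features are flagged low-confidence in metadata: consumer GPS
is generally too noisy to characterize acceleration precisely.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import MovementPeriod
from .regularity import series_entropy

LOW_CONFIDENCE_FEATURES = ("kin.accel.mean", "kin.accel.max")


@dataclass
class KinematicSeries:
    t: np.ndarray                  # (T,)
    member_ids: list[str]
    speed: np.ndarray              # (n, T), m/s
    accel: np.ndarray              # (n, T), m/s^2 magnitude
    spread: np.ndarray             # (T,) max-min member speed
    speed_var: np.ndarray          # (T,) population variance across members
    mask: np.ndarray = field(default=None)  # (n, T) True where sample unusable

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.zeros_like(self.speed, dtype=bool)


def compute_kinematics(period: MovementPeriod) -> KinematicSeries:
    """Per-member speed/acceleration and group spread/variance series."""
    traj = period.traj
    if traj.t_grid.size < 3:
        raise ValueError("need at least 3 samples for central differences")
    vel = np.gradient(traj.pos, traj.t_grid, axis=1)      # (n, T, 2)
    speed = np.linalg.norm(vel, axis=2)
    acc = np.gradient(vel, traj.t_grid, axis=1)
    accel = np.linalg.norm(acc, axis=2)
    spread = speed.max(axis=0) - speed.min(axis=0)
    speed_var = speed.var(axis=0)                          # population variance
    return KinematicSeries(t=traj.t_grid.copy(), member_ids=list(traj.member_ids),
                           speed=speed, accel=accel, spread=spread,
                           speed_var=speed_var, mask=traj.gap_mask.copy())


def summarize_kinematics(series: KinematicSeries,
                         entropy_bins: int = 20,
                         bin_edges: dict[str, np.ndarray] | None = None) -> dict:
    """Member- and group-level summary features.

    Returns ``{"members": {id: {...}}, "group": {...}, "meta": {...}}``.
    Gap-masked samples are excluded from the member summaries. The starred
    time series (speed spread / variance across members) get entropies via
    ``regularity.series_entropy``; pass ``bin_edges`` to share histogram
    edges across a whole dataset.
    """
    if series.t.size == 0:
        raise ValueError("empty series")
    bin_edges = bin_edges or {}
    members = {}
    for m, mid in enumerate(series.member_ids):
        ok = ~series.mask[m]
        sp = series.speed[m, ok]
        ac = series.accel[m, ok]
        members[mid] = {
            "kin.speed.mean": float(sp.mean()),
            "kin.speed.max": float(sp.max()),
            "kin.speed.var": float(sp.var()),
            "kin.speed.entropy": series_entropy(
                sp, bins=entropy_bins, edges=bin_edges.get("kin.speed")),
            "kin.accel.mean": float(ac.mean()),
            "kin.accel.max": float(ac.max()),
        }
    group = {
        "kin.spread.mean": float(series.spread.mean()),
        "kin.spread.entropy": series_entropy(
            series.spread, bins=entropy_bins, edges=bin_edges.get("kin.spread")),
        "kin.speed_var.mean": float(series.speed_var.mean()),
        "kin.speed_var.entropy": series_entropy(
            series.speed_var, bins=entropy_bins, edges=bin_edges.get("kin.speed_var")),
    }
    for key in ("kin.speed.mean", "kin.speed.max", "kin.speed.var",
                "kin.accel.mean", "kin.accel.max"):
        group[key] = float(np.mean([v[key] for v in members.values()]))
    return {"members": members, "group": group,
            "meta": {"low_confidence": list(LOW_CONFIDENCE_FEATURES)}}
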