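"""Seeded synthetic group marches with ground truth for every feature family.

The leader walks a waypoint route at a base speed with an AR(1) heading
wiggle; each follower copies its influencer's commanded heading after a
configured delay (bounded turn rate, small private noise) while a weak
restoring term keeps it near its formation slot expressed in path
coordinates. Everyone halts during scheduled rests. i.i.d. Gaussian GPS
noise is added last. A fixed seed reproduces the output bit for bit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pacs import PathSpline, fit_centroid_path
from .trajectory_io import GroupTrajectory


@dataclass
class SimConfig:
    n_members: int = 6
    waypoints: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0], [2000.0, 0.0]]))
    base_speed: float = 1.3                      # m/s
    formation: np.ndarray | None = None          # (n, 2) = (along, lateral) m
    influencers: dict[int, tuple[int, float]] | None = None
    # follower index -> (influencer index, delay s); member 0 has none
    heading_noise_sd: float = 0.15               # rad, leader wiggle
    follower_noise_sd: float = 0.02              # rad, private follower noise
    gps_noise_sd: float = 0.0                    # m
    rest_schedule: tuple[tuple[float, float], ...] = ()  # (onset s, duration s)
    dt: float = 1.0
    duration_s: float | None = None
    restore_rate: float = 0.05                   # 1/s formation pull
    max_turn_rate: float = 1.0                   # rad/s
    wiggle_timescale: float = 5.0                # s, AR(1) correlation time
    seed: int = 0

    def __post_init__(self):
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        if self.formation is None:
            # single-file column, 3 m spacing, leader in front
            self.formation = np.column_stack([
                -3.0 * np.arange(self.n_members), np.zeros(self.n_members)])
        self.formation = np.asarray(self.formation, dtype=float)
        if self.formation.shape != (self.n_members, 2):
            raise ValueError("formation must be (n_members, 2)")
        uniq = {tuple(o) for o in np.round(self.formation, 9)}
        if len(uniq) != self.n_members:
            raise ValueError("impossible formation: duplicate member offsets")
        if self.influencers is None:
            self.influencers = {m: (0, 2.0) for m in range(1, self.n_members)}
        for m, (inf, d) in self.influencers.items():
            if d < 0:
                raise ValueError("delays must be non-negative")
            if inf == m:
                raise ValueError("member cannot influence itself")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be positive")


@dataclass
class SimResult:
    traj: GroupTrajectory
    rests: list[tuple[float, float]]             # ground-truth (start, end)
    formation_pacs: np.ndarray                   # (n, 2) = (x, y) truth offsets
    delays: dict[int, tuple[int, float]]         # follower -> (influencer, delay)
    path: PathSpline


def _wrap(angle):
    return (angle + math.pi) % (2 * math.pi) - math.pi


def simulate_march(cfg: SimConfig) -> SimResult:
    """Simulate one group march; see module docstring for the dynamics."""
    rng = np.random.default_rng(cfg.seed)
    path = fit_centroid_path(waypoints=cfg.waypoints)
    n = cfg.n_members
    along = cfg.formation[:, 0]
    lateral = cfg.formation[:, 1]

    s0 = max(0.0, -float(along.min())) + 1.0
    s_max = path.total_length - max(0.0, float(along.max())) - 1.0
    move_time = (s_max - s0) / cfg.base_speed
    rest_total = sum(d for _, d in cfg.rest_schedule)
    duration = cfg.duration_s if cfg.duration_s is not None else move_time + rest_total
    T = int(math.floor(duration / cfg.dt)) + 1
    t_grid = cfg.dt * np.arange(T)

    resting = np.zeros(T, dtype=bool)
    for onset, dur in cfg.rest_schedule:
        resting |= (t_grid >= onset) & (t_grid < onset + dur)

    def anchor(s, m):
        s_m = np.clip(s + along[m], 0.0, path.total_length)
        u = np.interp(s_m, path.s_dense, path.u_dense)
        p = path.point(u)
        tang = path.tangent(u)
        right = np.array([tang[1], -tang[0]])
        return p + lateral[m] * right, math.atan2(tang[1], tang[0])

    pos = np.empty((n, T, 2))
    theta_cmd = np.empty((n, T))
    s_l = s0
    wiggle = 0.0
    rho = math.exp(-cfg.dt / cfg.wiggle_timescale)
    innov_sd = cfg.heading_noise_sd * math.sqrt(max(1.0 - rho * rho, 1e-12))

    # initial placement at formation anchors
    for m in range(n):
        pos[m, 0], tang0 = anchor(s_l, m)
    theta_cmd[:, 0] = tang0

    for k in range(T):
        _, tang_angle = anchor(s_l, 0)
        # leader commanded heading: path tangent + AR(1) wiggle
        if cfg.heading_noise_sd > 0:
            wiggle = rho * wiggle + innov_sd * rng.standard_normal()
        target = _wrap(tang_angle + wiggle)
        if k > 0:
            prev = theta_cmd[0, k - 1]
            step = np.clip(_wrap(target - prev),
                           -cfg.max_turn_rate * cfg.dt, cfg.max_turn_rate * cfg.dt)
            theta_cmd[0, k] = _wrap(prev + step)
        else:
            theta_cmd[0, k] = target

        for m in range(1, n):
            inf, delay = cfg.influencers.get(m, (0, 0.0))
            src_idx = max(0, k - int(round(delay / cfg.dt)))
            target = theta_cmd[inf, src_idx]
            if cfg.follower_noise_sd > 0:
                target = _wrap(target + cfg.follower_noise_sd * rng.standard_normal())
            if k > 0:
                prev = theta_cmd[m, k - 1]
                step = np.clip(_wrap(target - prev),
                               -cfg.max_turn_rate * cfg.dt, cfg.max_turn_rate * cfg.dt)
                theta_cmd[m, k] = _wrap(prev + step)
            else:
                theta_cmd[m, k] = target

        if k + 1 >= T:
            break
        if resting[k]:
            pos[:, k + 1] = pos[:, k]
            continue
        for m in range(n):
            a_m, _ = anchor(s_l, m)
            head = np.array([math.cos(theta_cmd[m, k]), math.sin(theta_cmd[m, k])])
            vel = cfg.base_speed * head + cfg.restore_rate * (a_m - pos[m, k])
            pos[m, k + 1] = pos[m, k] + vel * cfg.dt
        s_l = min(s_l + cfg.base_speed * cfg.dt, s_max)

    if cfg.gps_noise_sd > 0:
        pos = pos + rng.normal(0.0, cfg.gps_noise_sd, size=pos.shape)

    traj = GroupTrajectory(
        member_ids=[f"m{m:02d}" for m in range(n)],
        t_grid=t_grid, pos=pos)
    truth_rests = [(onset, onset + dur) for onset, dur in cfg.rest_schedule]
    formation_pacs = np.column_stack([lateral - lateral.mean(),
                                      along - along.mean()])
    return SimResult(traj=traj, rests=truth_rests, formation_pacs=formation_pacs,
                     delays=dict(cfg.influencers), path=path)


def simulate_feature_outcome_dataset(n_groups: int, k_features: int,
                                     informative: dict[int, float],
                                     noise_sd: float, seed: int = 0):
    """Synthetic group-feature table with a linear outcome.

    Features are i.i.d. standard normal; the outcome is the configured
    linear combination of the informative columns plus Gaussian noise.
    Returns (X, y, support) where support is the sorted informative index list.
    """
    if any(i < 0 or i >= k_features for i in informative):
        raise ValueError("informative indices out of range")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_groups, k_features))
    y = np.zeros(n_groups)
    for idx, coef in informative.items():
        y = y + coef * X[:, idx]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_groups)
    return X, y, sorted(informative)
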