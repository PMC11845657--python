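import numpy as np
import pytest

from flock.segmentation import MovementPeriod
from flock.synthetic import SimConfig, simulate_march
from flock.trajectory_io import GroupTrajectory


def full_period(traj: GroupTrajectory, index: int = 0) -> MovementPeriod:
    """Wrap a whole trajectory as a single movement period."""
    return MovementPeriod(index, float(traj.t_grid[0]), float(traj.t_grid[-1]), traj)


def make_traj(pos: np.ndarray, dt: float = 1.0) -> GroupTrajectory:
    """GroupTrajectory from a raw (n_members, T, 2) position array."""
    pos = np.asarray(pos, dtype=float)
    n, T, _ = pos.shape
    return GroupTrajectory(member_ids=[f"m{i:02d}" for i in range(n)],
                           t_grid=dt * np.arange(T), pos=pos)


@pytest.fixture(scope="session")
def straight_march():
    """Noise-free straight-line march with a 4-member single-file column."""
    cfg = SimConfig(n_members=4, heading_noise_sd=0.0, follower_noise_sd=0.0,
                    gps_noise_sd=0.0, duration_s=600, seed=1)
    return simulate_march(cfg)


def turn_scenario(trail_m: float = 60.0, speed: float = 1.3):
    """Right-turn route with one member trailing the knot by ``trail_m`` of arc.

    Members ride the route exactly (fixed arc/lateral offsets), so any
    apparent intra-group motion after a transform is a transform artifact.
    Returns (traj, route, trail_index, turn_time_index).
    """
    from flock.pacs import fit_centroid_path

    # straight leg, quarter-circle right turn (radius 20 m), straight leg
    leg1 = np.column_stack([np.linspace(0, 100, 51), np.zeros(51)])
    ang = np.linspace(0, np.pi / 2, 40)
    arc = np.column_stack([100 + 20 * np.sin(ang), -20 + 20 * np.cos(ang)])
    leg2 = np.column_stack([120 * np.ones(50), np.linspace(-20, -120, 50)])
    route = fit_centroid_path(waypoints=np.vstack([leg1, arc[1:], leg2[1:]]))

    offsets_along = np.array([0.0, -3.0, -6.0, -9.0, -trail_m])
    offsets_lat = np.array([0.0, 1.5, -1.5, 0.0, 0.0])
    t = np.arange(0.0, (route.total_length - 5.0 - trail_m) / speed)
    s_head = trail_m + 1.0 + speed * t
    pos = np.empty((5, t.size, 2))
    for m in range(5):
        s_m = s_head + offsets_along[m]
        u = np.interp(s_m, route.s_dense, route.u_dense)
        p = route.point(u)
        tang = route.tangent(u)
        right = np.column_stack([tang[:, 1], -tang[:, 0]])
        pos[m] = p + offsets_lat[m] * right
    traj = make_traj(pos)
    # timepoint where the group centroid sits mid-turn
    s_cent = s_head + offsets_along.mean()
    k_turn = int(np.argmin(np.abs(s_cent - (100.0 + 20 * np.pi / 4))))
    return traj, route, 4, k_turn


@pytest.fixture(scope="session")
def noisy_march():
    """Wiggly march with GPS noise and one scheduled rest."""
    cfg = SimConfig(n_members=5, heading_noise_sd=0.15, gps_noise_sd=0.3,
                    rest_schedule=((600.0, 300.0),), duration_s=1800, seed=7)
    return simulate_march(cfg)
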